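"""Typed in-memory containers for the mini core schema.

A :class:`Container` pairs a neurodata type with user data: a unique
``object_id``, a name, and a ``fields`` mapping whose keys correspond to
entries of the type's resolved spec (attributes, named datasets/groups,
typed anonymous children, links).  Specializations enforce the invariants
the schema language cannot express — the timing XOR of
:class:`TimeSeries`, ragged-index integrity of :class:`DynamicTable`,
channel/row agreement of :class:`ElectricalSeries` — at construction time
so an invalid container cannot be persisted.

Times are float64 seconds on the common session clock whose origin is
``session_start_time`` (0 s at session start).
"""

from __future__ import annotations

import re
import uuid

import numpy as np

from .errors import InvariantError, NamingError

__all__ = [
    "Container",
    "Data",
    "VectorData",
    "VectorIndex",
    "DynamicTableRegion",
    "TimeSeries",
    "ElectricalSeries",
    "DynamicTable",
    "Units",
    "PlaneSegmentation",
    "RoiResponseSeries",
    "SpatialSeries",
    "Position",
    "ProcessingModule",
    "SessionRoot",
    "PROCESSING_MODULES",
    "get_timestamps",
    "add_ragged_column",
    "create_electrical_series",
    "add_to_session",
    "CONTAINER_CLASSES",
]

#: Allowed processing-module labels, one per analysis domain.
PROCESSING_MODULES = ("ecephys", "icephys", "ophys", "behavior")

CORE_NAMESPACE = "mini-core"


def _new_object_id():
    return str(uuid.uuid4())


def _values_equal(a, b):
    if isinstance(a, Container) or isinstance(b, Container):
        return a == b
    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)) or a.keys() != b.keys():
            return False
        return all(_values_equal(a[k], b[k]) for k in a)
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a, b = np.asarray(a), np.asarray(b)
        return a.dtype == b.dtype and a.shape == b.shape and np.array_equal(a, b)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(_values_equal(x, y) for x, y in zip(a, b))
    return type(a) is type(b) and a == b


class Container:
    """A typed node of user data.

    Parameters
    ----------
    name : str
        Node name within its parent.
    neurodata_type, namespace : str
        The resolved type this container instantiates.
    object_id : str, optional
        Stable unique identifier; a fresh UUID4 string by default.
    fields : dict, optional
        Field name -> scalar | array | Container | dict of Containers.
    """

    neurodata_type = None
    namespace = CORE_NAMESPACE

    def __init__(self, name, neurodata_type=None, namespace=None, object_id=None,
                 fields=None):
        if not name:
            raise NamingError("container name must be nonempty")
        self.name = name
        if neurodata_type is not None:
            self.neurodata_type = neurodata_type
        if namespace is not None:
            self.namespace = namespace
        if self.neurodata_type is None:
            raise InvariantError("container requires a neurodata type")
        self.object_id = object_id or _new_object_id()
        self.fields = dict(fields or {})
        #: unknown nodes/attributes preserved through read (escape hatch)
        self.extras = {}

    def __eq__(self, other):
        if not isinstance(other, Container):
            return NotImplemented
        if (self.neurodata_type, self.namespace, self.name, self.object_id) != (
            other.neurodata_type, other.namespace, other.name, other.object_id
        ):
            return False
        mine = {k: v for k, v in self.fields.items() if v is not None}
        theirs = {k: v for k, v in other.fields.items() if v is not None}
        if mine.keys() != theirs.keys():
            return False
        if not all(_values_equal(mine[k], theirs[k]) for k in mine):
            return False
        if self.extras.keys() != other.extras.keys():
            return False
        return all(self.extras[k] == other.extras[k] for k in self.extras)

    __hash__ = None

    def __repr__(self):
        return (
            f"<{type(self).__name__} {self.name!r} ({self.namespace}:"
            f"{self.neurodata_type}) fields={sorted(self.fields)}>"
        )

    @classmethod
    def _from_fields(cls, name, neurodata_type, namespace, object_id, fields):
        """Rehydrate a container from storage without re-running constructor
        checks (the validator is the arbiter for on-disk data)."""
        obj = cls.__new__(cls)
        obj.name = name
        obj.neurodata_type = neurodata_type
        obj.namespace = namespace
        obj.object_id = object_id
        obj.fields = dict(fields)
        obj.extras = {}
        return obj


class Data(Container):
    """A container backed by a dataset node: the payload lives in ``data``
    and the remaining fields map to attributes."""

    def __init__(self, name, data, **kw):
        fields = kw.pop("fields", {})
        super().__init__(name, fields=fields, **kw)
        self.fields["data"] = data

    @property
    def data(self):
        return self.fields["data"]

    def __len__(self):
        return len(self.fields["data"])


class VectorData(Data):
    neurodata_type = "VectorData"

    def __init__(self, name, data, description="", **kw):
        super().__init__(name, data, **kw)
        self.fields["description"] = description


class VectorIndex(VectorData):
    """Cumulative end-offsets into a target :class:`VectorData`."""

    neurodata_type = "VectorIndex"

    def __init__(self, name, data, target, description="", **kw):
        data = np.asarray(data, dtype=np.int64)
        if len(data) and np.any(np.diff(data) < 0):
            raise InvariantError(f"ragged index {name!r} must be non-decreasing")
        if len(data) and target is not None and data[-1] != len(target.data):
            raise InvariantError(
                f"ragged index {name!r} last offset {data[-1]} != "
                f"target length {len(target.data)}"
            )
        super().__init__(name, data, description, **kw)
        self.fields["target"] = target


class DynamicTableRegion(VectorData):
    """Row-region pointer into a :class:`DynamicTable`, stored portably as
    explicit row indices plus the table reference."""

    neurodata_type = "DynamicTableRegion"

    def __init__(self, name, data, table, description="", **kw):
        data = np.asarray(data, dtype=np.int64)
        nrows = table.n_rows
        if len(data) and (data.min() < 0 or data.max() >= nrows):
            raise InvariantError(
                f"region {name!r} references rows outside 0..{nrows - 1}"
            )
        super().__init__(name, data, description, **kw)
        self.fields["table"] = table


class TimeSeries(Container):
    """Measurement sampled over time on the common session clock.

    Exactly one timing representation must be given: explicit per-sample
    ``timestamps`` (seconds, non-decreasing, one per time point) or a
    sampling ``rate`` in Hz with a ``starting_time`` in seconds.
    """

    neurodata_type = "TimeSeries"

    def __init__(self, name, data, unit, timestamps=None, rate=None,
                 starting_time=None, description=None, **kw):
        super().__init__(name, **kw)
        data = np.asarray(data)
        has_ts = timestamps is not None
        has_rate = rate is not None
        if has_ts == has_rate:
            raise InvariantError(
                f"{name!r}: exactly one of timestamps or rate must be given"
            )
        if has_ts:
            timestamps = np.asarray(timestamps, dtype=np.float64)
            if len(timestamps) != data.shape[0]:
                raise InvariantError(
                    f"{name!r}: {len(timestamps)} timestamps for "
                    f"{data.shape[0]} samples"
                )
            if np.any(np.diff(timestamps) < 0):
                raise InvariantError(f"{name!r}: timestamps must be non-decreasing")
            self.fields["timestamps"] = timestamps
        else:
            rate = float(rate)
            if rate <= 0:
                raise InvariantError(f"{name!r}: rate must be positive")
            self.fields["rate"] = rate
            self.fields["starting_time"] = float(
                0.0 if starting_time is None else starting_time
            )
        self.fields["data"] = data
        self.fields["unit"] = str(unit)
        if description is not None:
            self.fields["description"] = str(description)

    @property
    def data(self):
        return self.fields["data"]


class ElectricalSeries(TimeSeries):
    """Extracellular voltage traces (time x channel) with an electrode-table
    region describing the recorded channels."""

    neurodata_type = "ElectricalSeries"

    def __init__(self, name, data, electrodes, unit="volts", **kw):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise InvariantError(f"{name!r}: data must be 2-d (time x channel)")
        if not isinstance(electrodes, DynamicTableRegion):
            raise InvariantError(f"{name!r}: electrodes must be a table region")
        if data.shape[1] != len(electrodes.data):
            raise InvariantError(
                f"{name!r}: {data.shape[1]} channels but "
                f"{len(electrodes.data)} referenced electrode rows"
            )
        super().__init__(name, data, unit, **kw)
        self.fields["electrodes"] = electrodes


class DynamicTable(Container):
    """Column-oriented table of aligned arrays with optional ragged columns.

    Columns live in ``fields`` as :class:`VectorData` children (plus a
    :class:`VectorIndex` companion named ``<col>_index`` when ragged);
    ``colnames`` keeps user-column order and ``id`` the row identifiers.
    """

    neurodata_type = "DynamicTable"

    def __init__(self, name, description="", **kw):
        super().__init__(name, **kw)
        self.fields.setdefault("description", str(description))
        self.fields.setdefault("colnames", [])
        self.fields.setdefault("id", np.empty(0, dtype=np.int64))

    @property
    def n_rows(self):
        return len(self.fields["id"])

    @property
    def colnames(self):
        return self.fields["colnames"]

    def column(self, name):
        return self.fields[name]

    def add_column(self, name, values, description=""):
        """Append a flat (non-ragged) column; sets row ids on first column."""
        values = np.asarray(values)
        self._admit_rows(len(values))
        if name in self.fields:
            raise NamingError(f"column {name!r} already present")
        self.fields[name] = VectorData(name, values, description)
        self.fields["colnames"] = list(self.colnames) + [name]
        return self

    def _admit_rows(self, n):
        if self.n_rows == 0 and not self.colnames:
            self.fields["id"] = np.arange(n, dtype=np.int64)
        elif n != self.n_rows:
            raise InvariantError(
                f"table {self.name!r} has {self.n_rows} rows; column has {n}"
            )

    def ragged_rows(self, name):
        """Recover the per-row arrays of a ragged column."""
        idx = self.fields[f"{name}_index"].data
        data = self.fields[name].data
        starts = np.concatenate(([0], idx[:-1]))
        return [data[s:e] for s, e in zip(starts, idx)]


class Units(DynamicTable):
    neurodata_type = "Units"

    def add_unit_spike_times(self, spike_times_per_unit):
        """Populate the ragged spike_times column, one row per unit."""
        return add_ragged_column(self, "spike_times", spike_times_per_unit,
                                 description="Spike times per unit, seconds.")


class PlaneSegmentation(DynamicTable):
    neurodata_type = "PlaneSegmentation"


class RoiResponseSeries(TimeSeries):
    neurodata_type = "RoiResponseSeries"

    def __init__(self, name, data, rois, unit="n.a.", **kw):
        if not isinstance(rois, DynamicTableRegion):
            raise InvariantError(f"{name!r}: rois must be a table region")
        super().__init__(name, np.asarray(data, dtype=np.float64), unit, **kw)
        self.fields["rois"] = rois


class SpatialSeries(TimeSeries):
    neurodata_type = "SpatialSeries"

    def __init__(self, name, data, reference_frame, unit="meters", **kw):
        super().__init__(name, np.asarray(data, dtype=np.float64), unit, **kw)
        self.fields["reference_frame"] = str(reference_frame)


class Position(Container):
    neurodata_type = "Position"

    def __init__(self, name="Position", spatial_series=(), **kw):
        super().__init__(name, **kw)
        for s in spatial_series:
            self.add_spatial_series(s)

    def add_spatial_series(self, series):
        if series.name in self.fields:
            raise NamingError(f"duplicate spatial series {series.name!r}")
        self.fields[series.name] = series
        return self


class ProcessingModule(Container):
    neurodata_type = "ProcessingModule"

    def __init__(self, name, description="", **kw):
        super().__init__(name, **kw)
        self.fields.setdefault("description", str(description))

    def add(self, container):
        if container.name in self.fields:
            raise NamingError(f"duplicate name {container.name!r} in module")
        self.fields[container.name] = container
        return self


class SessionRoot(Container):
    """Root of one experimental session; all measurements hang off it."""

    neurodata_type = "SessionRoot"

    def __init__(self, session_description, identifier, session_start_time,
                 name="root", **kw):
        if not identifier:
            raise InvariantError("session identifier must be nonempty")
        super().__init__(name, **kw)
        self.fields.update(
            session_description=str(session_description),
            identifier=str(identifier),
            session_start_time=str(session_start_time),
            acquisition={},
            processing={},
            stimulus={},
        )

    @property
    def acquisition(self):
        return self.fields["acquisition"]

    @property
    def processing(self):
        return self.fields["processing"]

    @property
    def stimulus(self):
        return self.fields["stimulus"]

    def all_containers(self):
        """Every member container reachable from the root (excluding the
        root itself), depth-first."""
        out, seen = [], set()

        def walk(value):
            if isinstance(value, Container):
                if id(value) in seen:
                    return
                seen.add(id(value))
                out.append(value)
                for v in value.fields.values():
                    walk(v)
            elif isinstance(value, dict):
                for v in value.values():
                    walk(v)

        for v in self.fields.values():
            walk(v)
        return out


CONTAINER_CLASSES = {
    cls.neurodata_type: cls
    for cls in (
        VectorData, VectorIndex, DynamicTableRegion, TimeSeries,
        ElectricalSeries, DynamicTable, Units, PlaneSegmentation,
        RoiResponseSeries, SpatialSeries, Position, ProcessingModule,
        SessionRoot,
    )
}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def get_timestamps(ts):
    """Sample times of a time series in float64 seconds on the session clock.

    Explicit timestamps are returned as stored; the rate form expands to
    ``starting_time + i / rate`` for ``i = 0 .. n-1``.
    """
    has_ts = "timestamps" in ts.fields
    has_rate = "rate" in ts.fields
    if has_ts == has_rate:
        raise InvariantError(
            f"{ts.name!r}: exactly one timing representation required"
        )
    if has_ts:
        return np.asarray(ts.fields["timestamps"], dtype=np.float64)
    n = np.asarray(ts.fields["data"]).shape[0]
    return ts.fields["starting_time"] + np.arange(n, dtype=np.float64) / ts.fields["rate"]


def add_ragged_column(table, name, values_per_row, description=""):
    """Add a ragged column: the flat data array is the concatenation of the
    per-row arrays and the index array holds cumulative end offsets, so row
    ``i`` is ``data[index[i-1]:index[i]]``."""
    table._admit_rows(len(values_per_row))
    if name in table.fields:
        raise NamingError(f"column {name!r} already present")
    arrays = [np.atleast_1d(np.asarray(v)) for v in values_per_row]
    lengths = np.array([a.shape[0] for a in arrays], dtype=np.int64)
    if arrays:
        data = np.concatenate([a for a in arrays]) if lengths.sum() else (
            np.empty((0,) + arrays[0].shape[1:], dtype=arrays[0].dtype)
        )
    else:
        data = np.empty(0, dtype=np.float64)
    index = np.cumsum(lengths, dtype=np.int64)
    col = VectorData(name, data, description)
    table.fields[name] = col
    table.fields[f"{name}_index"] = VectorIndex(
        f"{name}_index", index, col,
        description=f"End offsets into {name!r} per row.",
    )
    table.fields["colnames"] = list(table.colnames) + [name]
    return table


def create_electrical_series(name, data, electrode_rows, table, *,
                             timestamps=None, rate=None, starting_time=None,
                             description=None, object_id=None):
    """Build a validated :class:`ElectricalSeries` over rows of an electrode
    table.  ``data`` is time x channel and the channel extent must equal
    ``len(electrode_rows)``."""
    region = DynamicTableRegion(
        "electrodes", np.asarray(electrode_rows, dtype=np.int64), table,
        description="Recorded channels.",
    )
    return ElectricalSeries(
        name, data, region, timestamps=timestamps, rate=rate,
        starting_time=starting_time, description=description,
        object_id=object_id,
    )


_SLOT_RE = re.compile(r"^(acquisition|stimulus|units|electrodes|processing\.([a-z]+))$")


def add_to_session(root, slot, container):
    """Place a container in a session slot.

    ``slot`` is ``acquisition``, ``stimulus``, ``units``, ``electrodes`` or
    ``processing.<module>`` with module one of ``ecephys``, ``icephys``,
    ``ophys``, ``behavior``.  Names must be unique within a slot; the
    container keeps its identity (object_id) when placed.
    """
    m = _SLOT_RE.match(slot)
    if not m:
        raise NamingError(f"unknown slot {slot!r}")
    if m.group(2) is not None:
        module = m.group(2)
        if module not in PROCESSING_MODULES:
            raise NamingError(
                f"unknown processing module {module!r}; allowed: "
                f"{', '.join(PROCESSING_MODULES)}"
            )
        modules = root.fields["processing"]
        if module not in modules:
            modules[module] = ProcessingModule(
                module, description=f"{module} processing"
            )
        modules[module].add(container)
        return root
    if slot in ("units", "electrodes"):
        if root.fields.get(slot) is not None:
            raise NamingError(f"session already has a {slot} table")
        root.fields[slot] = container
        return root
    bucket = root.fields[slot]
    if container.name in bucket:
        raise NamingError(f"duplicate name {container.name!r} in {slot}")
    bucket[container.name] = container
    return root
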