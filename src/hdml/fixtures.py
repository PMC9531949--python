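"""Deterministic synthetic multimodal sessions.

:func:`generate_session` emulates a session in which raw extracellular
voltage, spike-sorting output, ROI fluorescence and behavioral position are
all acquired against one common clock and stored together:

* an electrode table and a raw :class:`~hdml.containers.ElectricalSeries`
  of Gaussian noise with spike-triggered exponential transients,
* a Units table whose ragged ``spike_times`` column is drawn from
  independent homogeneous Poisson processes (``unit_rate_hz`` per unit),
* a PlaneSegmentation with per-ROI pixel masks and an
  RoiResponseSeries of event-convolved exponential dF/F kernels
  (amplitude 1, decay tau = 0.5 s),
* a behavioral Position random walk, and a stimulus pulse train.

Each modality draws from its own child stream of the recipe seed, spawned
in a fixed order (ids, electrodes, units, ephys, ophys, behavior,
stimulus), so sessions are bit-reproducible and adding one modality never
perturbs another's draws.  No biophysical realism is intended: amplitudes,
kernels and geometry are fixed conventions chosen to exercise every core
type.

:func:`corrupt_session` injects exactly one targeted violation per
validator rule, driving the mutation-detection completeness tests.
"""

from __future__ import annotations

import copy
import uuid
from dataclasses import dataclass

import numpy as np

from .builders import DatasetBuilder, LinkBuilder, iter_nodes
from .containers import (
    DynamicTable,
    DynamicTableRegion,
    PlaneSegmentation,
    Position,
    RoiResponseSeries,
    SessionRoot,
    SpatialSeries,
    TimeSeries,
    Units,
    add_ragged_column,
    add_to_session,
    create_electrical_series,
)
from .errors import HdmlError
from .validation import RULES

__all__ = ["SessionRecipe", "generate_session", "corrupt_session", "RECIPE_GRID"]

_DFF_TAU_S = 0.5      # exponential decay of the dF/F kernel
_DFF_AMPLITUDE = 1.0
_TRANSIENT_TAU_S = 0.003
_ROI_EVENT_RATE_HZ = 0.2


@dataclass(frozen=True)
class SessionRecipe:
    """Parameters of one synthetic session; all rates in Hz, durations in
    seconds."""

    seed: int = 0
    n_channels: int = 4
    sampling_rate_hz: float = 250.0
    duration_s: float = 10.0
    n_units: int = 5
    unit_rate_hz: float = 5.0
    n_rois: int = 3
    ophys_rate_hz: float = 20.0
    behavior_dims: int = 2
    behavior_rate_hz: float = 50.0

    def __post_init__(self):
        if min(self.n_channels, self.n_units, self.n_rois, self.behavior_dims) < 0:
            raise HdmlError("recipe counts must be >= 0")
        if min(self.sampling_rate_hz, self.ophys_rate_hz, self.behavior_rate_hz,
               self.unit_rate_hz) <= 0 or self.duration_s <= 0:
            raise HdmlError("recipe rates and duration must be > 0")


#: the 5 seeds x 3 sizes test grid
RECIPE_GRID = [
    SessionRecipe(seed=seed, **size)
    for size in (
        dict(n_channels=2, sampling_rate_hz=100.0, duration_s=5.0, n_units=3,
             n_rois=2),
        dict(),  # defaults
        dict(n_channels=8, sampling_rate_hz=500.0, duration_s=12.0, n_units=10,
             n_rois=6),
    )
    for seed in (1, 2, 3, 4, 5)
]


def _ids(stream):
    """Deterministic object-id factory from a child RNG stream."""
    def next_id():
        return str(uuid.UUID(bytes=stream.bytes(16), version=4))
    return next_id


def _poisson_spike_trains(stream, n_units, rate_hz, duration_s):
    trains = []
    for _ in range(n_units):
        n = stream.poisson(rate_hz * duration_s)
        trains.append(np.sort(stream.uniform(0.0, duration_s, size=n)))
    return trains


def generate_session(recipe):
    """Generate one synthetic multimodal session; deterministic in
    ``recipe.seed``."""
    streams = np.random.SeedSequence(recipe.seed).spawn(7)
    (ids_ss, elec_ss, units_ss, ephys_ss, ophys_ss, behav_ss, stim_ss) = streams
    next_id = _ids(np.random.default_rng(ids_ss))

    root = SessionRoot(
        session_description="Synthetic multimodal session: raw extracellular "
        "voltage, sorted units, ROI fluorescence, behavior and stimulus on a "
        "common clock.",
        identifier=f"hdml-demo-{recipe.seed}",
        session_start_time="2022-06-01T12:00:00+00:00",
        object_id=next_id(),
    )

    # electrode table --------------------------------------------------
    elec_rng = np.random.default_rng(elec_ss)
    electrodes = DynamicTable(
        "electrodes", description="Recording channels.", object_id=next_id()
    )
    n_ch = recipe.n_channels
    for axis in "xyz":
        electrodes.add_column(
            axis, elec_rng.uniform(-1e-3, 1e-3, n_ch),
            description=f"{axis} position in meters.",
        )
    electrodes.add_column(
        "impedance", elec_rng.uniform(0.5e6, 2e6, n_ch),
        description="Impedance in ohms.",
    )
    electrodes.add_column(
        "location", ["CA1"] * n_ch, description="Anatomical location label."
    )
    electrodes.add_column(
        "group", [f"shank{i // 4}" for i in range(n_ch)],
        description="Electrode group label.",
    )
    for col in ("x", "y", "z", "impedance", "location", "group"):
        electrodes.fields[col].object_id = next_id()
    add_to_session(root, "electrodes", electrodes)

    # sorted units ------------------------------------------------------
    units_rng = np.random.default_rng(units_ss)
    trains = _poisson_spike_trains(
        units_rng, recipe.n_units, recipe.unit_rate_hz, recipe.duration_s
    )
    units = Units("units", description="Sorted single units.", object_id=next_id())
    units.add_unit_spike_times(trains)
    units.fields["spike_times"].object_id = next_id()
    units.fields["spike_times_index"].object_id = next_id()
    add_to_session(root, "units", units)

    # raw + filtered ephys ---------------------------------------------
    ephys_rng = np.random.default_rng(ephys_ss)
    n_samples = int(round(recipe.sampling_rate_hz * recipe.duration_s))
    raw = ephys_rng.standard_normal((n_samples, n_ch)) * 20e-6
    kernel_n = max(1, int(5 * _TRANSIENT_TAU_S * recipe.sampling_rate_hz))
    kernel = -80e-6 * np.exp(
        -np.arange(kernel_n) / (_TRANSIENT_TAU_S * recipe.sampling_rate_hz)
    )
    for train in trains:
        if n_ch == 0:
            break
        channel = int(ephys_rng.integers(0, n_ch))
        for t in train:
            i = int(t * recipe.sampling_rate_hz)
            seg = raw[i : i + kernel_n, channel]
            seg += kernel[: len(seg)]
    raw_es = create_electrical_series(
        "raw_ephys", raw, list(range(n_ch)), electrodes,
        rate=recipe.sampling_rate_hz, starting_time=0.0,
        description="Raw wideband voltage.", object_id=next_id(),
    )
    raw_es.fields["electrodes"].object_id = next_id()
    add_to_session(root, "acquisition", raw_es)

    decim = 10
    lfp = create_electrical_series(
        "lfp", raw[::decim].copy(), list(range(n_ch)), electrodes,
        rate=recipe.sampling_rate_hz / decim, starting_time=0.0,
        description="Decimated low-frequency voltage.", object_id=next_id(),
    )
    lfp.fields["electrodes"].object_id = next_id()
    add_to_session(root, "processing.ecephys", lfp)
    root.processing["ecephys"].object_id = next_id()

    # ophys -------------------------------------------------------------
    ophys_rng = np.random.default_rng(ophys_ss)
    plane = PlaneSegmentation(
        "rois", description="Imaging ROIs.", object_id=next_id()
    )
    masks = []
    for _ in range(recipe.n_rois):
        k = int(ophys_rng.integers(4, 10))
        xy = ophys_rng.integers(0, 64, size=(k, 2)).astype(np.float64)
        w = ophys_rng.uniform(0.2, 1.0, size=(k, 1))
        masks.append(np.hstack([xy, w]))
    if not masks:
        masks = []
    add_ragged_column(
        plane, "pixel_mask",
        masks if masks else [],
        description="(x, y, weight) pixel triples per ROI.",
    )
    if recipe.n_rois == 0:  # keep dtype/shape contract for the empty case
        plane.fields["pixel_mask"].fields["data"] = np.empty((0, 3), np.float64)
    plane.fields["pixel_mask"].object_id = next_id()
    plane.fields["pixel_mask_index"].object_id = next_id()
    add_to_session(root, "processing.ophys", plane)
    root.processing["ophys"].object_id = next_id()

    n_frames = int(round(recipe.ophys_rate_hz * recipe.duration_s))
    dff = np.zeros((n_frames, recipe.n_rois))
    frame_t = np.arange(n_frames) / recipe.ophys_rate_hz
    for r in range(recipe.n_rois):
        n_events = ophys_rng.poisson(_ROI_EVENT_RATE_HZ * recipe.duration_s) + 1
        events = np.sort(ophys_rng.uniform(0.0, recipe.duration_s, n_events))
        for t0 in events:
            active = frame_t >= t0
            dff[active, r] += _DFF_AMPLITUDE * np.exp(
                -(frame_t[active] - t0) / _DFF_TAU_S
            )
    dff += ophys_rng.standard_normal(dff.shape) * 0.02
    rois_region = DynamicTableRegion(
        "rois", np.arange(recipe.n_rois, dtype=np.int64), plane,
        description="All ROIs in trace order.", object_id=next_id(),
    )
    fluor = RoiResponseSeries(
        "dff", dff, rois_region, unit="n.a.",
        rate=recipe.ophys_rate_hz, starting_time=0.0,
        description="Event-convolved dF/F traces.", object_id=next_id(),
    )
    add_to_session(root, "processing.ophys", fluor)

    # behavior ----------------------------------------------------------
    behav_rng = np.random.default_rng(behav_ss)
    n_pos = int(round(recipe.behavior_rate_hz * recipe.duration_s))
    steps = behav_rng.standard_normal((n_pos, recipe.behavior_dims)) * 0.01
    pos_data = np.cumsum(steps, axis=0)
    pos_t = np.arange(n_pos, dtype=np.float64) / recipe.behavior_rate_hz
    spatial = SpatialSeries(
        "position", pos_data, reference_frame="arena south-west corner",
        timestamps=pos_t, description="Random-walk position.",
        object_id=next_id(),
    )
    position = Position("Position", [spatial], object_id=next_id())
    add_to_session(root, "processing.behavior", position)
    root.processing["behavior"].object_id = next_id()

    # stimulus ----------------------------------------------------------
    stim_rng = np.random.default_rng(stim_ss)
    n_stim = int(round(10 * recipe.duration_s))
    stim = TimeSeries(
        "opto_pulses",
        (stim_rng.uniform(size=n_stim) < 0.2).astype(np.float64),
        unit="watts", rate=10.0, starting_time=0.0,
        description="Optogenetic pulse train.", object_id=next_id(),
    )
    add_to_session(root, "stimulus", stim)
    return root


# ---------------------------------------------------------------------------
# targeted corruption
# ---------------------------------------------------------------------------

def _find_typed(root, neurodata_type, prefix="/"):
    for path, node in iter_nodes(root):
        if not path.startswith(prefix):
            continue
        if getattr(node, "attributes", {}).get("neurodata_type") == neurodata_type:
            return path, node
    raise HdmlError(f"no {neurodata_type!r} node under {prefix}")


def _parent_of(root, path):
    parts = [p for p in path.split("/") if p]
    node = root
    for part in parts[:-1]:
        node = node.get(part)
    return node, parts[-1]


def corrupt_session(root, rule_id):
    """Return a deep copy of a session builder tree with exactly one
    violation of ``rule_id`` injected; everything else untouched."""
    if rule_id not in RULES:
        raise HdmlError(f"unknown rule id {rule_id!r}; known: {', '.join(RULES)}")
    root = copy.deepcopy(root)

    if rule_id == "required-presence":
        _, es = _find_typed(root, "ElectricalSeries", "/acquisition")
        del es.datasets["electrodes"]
    elif rule_id == "dtype-compat":
        _, es = _find_typed(root, "ElectricalSeries", "/acquisition")
        es.attributes["unit"] = 5
    elif rule_id == "shape-conform":
        _, es = _find_typed(root, "ElectricalSeries", "/acquisition")
        flat = es.datasets["data"].data.ravel()
        es.datasets["data"] = DatasetBuilder("data", flat, dtype="float64")
    elif rule_id == "quantity-bounds":
        _, pos = _find_typed(root, "Position")
        name = sorted(pos.groups)[0]
        del pos.groups[name]
    elif rule_id == "timestamps-nondecreasing":
        _, sp = _find_typed(root, "SpatialSeries")
        ts = sp.datasets["timestamps"]
        ts.data = ts.data[::-1].copy()
        if len(ts.data) < 2:
            ts.data = np.array([1.0, 0.0])
    elif rule_id == "ragged-index":
        _, units = _find_typed(root, "Units")
        idx = units.datasets["spike_times_index"]
        data = idx.data[::-1].copy()
        if len(data) < 2 or data[0] <= data[-1]:
            data = np.array([5, 2], dtype=np.int64)
        idx.data = data
    elif rule_id == "link-target":
        acq = root.groups["acquisition"]
        acq.add(LinkBuilder("dangling_series", "/acquisition/does_not_exist"))
    elif rule_id == "unknown-typed-child":
        rogue = DatasetBuilder(
            "rogue_column", np.array([1.0, 2.0]), dtype="float64",
            attributes={
                "neurodata_type": "VectorData",
                "namespace": "mini-core",
                "object_id": "00000000-0000-4000-8000-000000000000",
                "description": "a column where no table is",
            },
        )
        root.groups["stimulus"].add(rogue)
    elif rule_id == "missing-recommended":
        _, es = _find_typed(root, "ElectricalSeries", "/acquisition")
        del es.attributes["description"]
    return root
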