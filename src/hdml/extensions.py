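"""Creation, packaging and cataloguing of extension namespaces (NDX).

An extension is an ordinary namespace — written in the same specification
language as the core schema — whose name is prefixed ``ndx-`` and whose
new types build on core types (or other extensions) through inheritance
and composition.  Extension types participate in subtype queries, object
mapping, storage and validation with no extension-specific code paths.

The shipped worked example, :func:`build_compartments_extension`, stores
the output of multi-compartment network simulations: a ``Compartments``
table (a DynamicTable subtype whose ragged columns give each cell's
compartment numbers and positions) and a ``CompartmentSeries`` (a
TimeSeries subtype with a link to a Compartments table associating each
column of its data array with one compartment).

A local, append-only catalog file records published extensions
(name, version, summary, dependencies, review status); duplicate
(name, version) entries are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import yaml

from .containers import DynamicTable, SessionRoot, TimeSeries, add_ragged_column, add_to_session
from .errors import ConflictError, NamingError
from .spec_language import (
    AttributeSpec,
    DatasetSpec,
    GroupSpec,
    LinkSpec,
    Namespace,
    SchemaSource,
    serialize_spec_document,
)
from .type_system import register_namespace

__all__ = [
    "ExtensionPackage",
    "new_extension",
    "build_compartments_extension",
    "register_extension",
    "publish_record",
    "load_catalog",
    "search_catalog",
    "example_compartments_session",
]

_NDX_NAME_RE = re.compile(r"^ndx-[a-z0-9-]+$")

REVIEW_STATUSES = ("draft", "proposed", "accepted")


@dataclass
class ExtensionPackage:
    """An extension namespace plus its type specs and catalog metadata."""

    namespace: Namespace
    specs: list = dataclass_field(default_factory=list)
    catalog_record: dict = dataclass_field(default_factory=dict)

    def documents(self):
        """Serialized specification documents ``[(doc name, text), ...]``."""
        name = self.namespace.name
        return [
            (f"{name}.namespace.yaml", serialize_spec_document(self.namespace, [])),
            (f"{name}.yaml", serialize_spec_document(None, self.specs)),
        ]


def new_extension(name, core_dependency="mini-core", version="0.1.0",
                  summary="", authors=()):
    """Skeleton extension package: empty spec list, a dependency on the core
    namespace and a catalog record stub in ``draft`` status."""
    if not _NDX_NAME_RE.match(name):
        raise NamingError(
            f"extension name {name!r} must match ndx-[a-z0-9-]+"
        )
    ns = Namespace(
        name=name,
        version=version,
        doc=summary or f"Extension namespace {name}.",
        authors=list(authors),
        schema_sources=[
            SchemaSource(namespace=core_dependency),
            SchemaSource(source=f"{name}.yaml"),
        ],
    )
    record = {
        "name": name,
        "version": version,
        "summary": summary,
        "authors": list(authors),
        "dependencies": [core_dependency],
        "status": "draft",
    }
    return ExtensionPackage(namespace=ns, specs=[], catalog_record=record)


def build_compartments_extension():
    """The simulation-output worked example (``ndx-simulation-output``)."""
    pkg = new_extension(
        "ndx-simulation-output",
        summary="Storage of multi-compartment simulation output: a "
        "Compartments table describing each cell's compartments and a "
        "CompartmentSeries of per-compartment state variables.",
        authors=["hdml developers"],
    )
    compartments = GroupSpec(
        type_def="Compartments",
        type_inc="DynamicTable",
        doc="Metadata about each cell and each compartment within it; rows "
        "are cells, ragged columns give per-compartment values.",
        datasets=[
            DatasetSpec(
                name="number",
                type_inc="VectorData",
                dtype="int32",
                shape=((None,),),
                doc="Compartment numbers of each cell, flattened.",
            ),
            DatasetSpec(
                name="number_index",
                type_inc="VectorIndex",
                doc="Per-cell end offsets into number.",
            ),
            DatasetSpec(
                name="position",
                type_inc="VectorData",
                dtype="float64",
                shape=((None,),),
                doc="Normalized position of each compartment, flattened.",
            ),
            DatasetSpec(
                name="position_index",
                type_inc="VectorIndex",
                doc="Per-cell end offsets into position.",
            ),
            DatasetSpec(
                name="label",
                type_inc="VectorData",
                dtype="text",
                quantity="?",
                doc="Optional per-cell label.",
            ),
        ],
    )
    series = GroupSpec(
        type_def="CompartmentSeries",
        type_inc="TimeSeries",
        doc="State variable sampled over time for many compartments; column "
        "j of data belongs to the compartment described by row-expansion "
        "position j of the linked Compartments table.",
        links=[
            LinkSpec(
                name="compartments",
                target_type="Compartments",
                doc="The Compartments table describing the data columns.",
            )
        ],
    )
    pkg.specs = [compartments, series]
    return pkg


def register_extension(reg, pkg):
    """Register an extension package (core/dependencies must already be in
    the registry); the serialized documents are cached for embedding."""
    register_namespace(reg, pkg.namespace, pkg.specs,
                       source_documents=pkg.documents())
    return reg


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def load_catalog(path):
    path = Path(path)
    if not path.exists():
        return []
    return yaml.safe_load(path.read_text()) or []


def publish_record(pkg, catalog_path):
    """Append a package's catalog record to the local catalog file.

    Entries are append-only and immutable: re-publishing an existing
    (name, version) pair is a conflict.
    """
    record = dict(pkg.catalog_record)
    if record.get("status") not in REVIEW_STATUSES:
        record["status"] = "draft"
    entries = load_catalog(catalog_path)
    for e in entries:
        if (e["name"], e["version"]) == (record["name"], record["version"]):
            raise ConflictError(
                f"{record['name']} {record['version']} is already published"
            )
    entries.append(record)
    Path(catalog_path).write_text(
        yaml.safe_dump(entries, sort_keys=False, default_flow_style=False)
    )
    return record


def search_catalog(catalog_path, keyword):
    """Case-insensitive substring search over name and summary."""
    kw = keyword.lower()
    return [
        e for e in load_catalog(catalog_path)
        if kw in e.get("name", "").lower() or kw in e.get("summary", "").lower()
    ]


# ---------------------------------------------------------------------------
# worked-example data
# ---------------------------------------------------------------------------

def example_compartments_session(compartments_per_cell=(2, 1, 3), n_samples=50,
                                 rate_hz=100.0, seed=0):
    """A small simulated session using the compartments extension: one
    membrane-potential CompartmentSeries over all compartments of a few
    cells."""
    rng = np.random.default_rng(seed)
    root = SessionRoot(
        session_description="Simulated multi-compartment network output.",
        identifier=f"compartments-demo-{seed}",
        session_start_time="2022-06-01T12:00:00+00:00",
    )
    table = DynamicTable(
        "compartments",
        description="Cells and their compartments.",
        neurodata_type="Compartments",
        namespace="ndx-simulation-output",
    )
    numbers = [np.arange(k, dtype=np.int32) for k in compartments_per_cell]
    positions = [
        np.linspace(0.0, 1.0, k, dtype=np.float64) for k in compartments_per_cell
    ]
    add_ragged_column(table, "number", numbers,
                      description="Compartment numbers per cell.")
    add_ragged_column(table, "position", positions,
                      description="Normalized compartment positions per cell.")
    add_to_session(root, "processing.ecephys", table)

    total = int(sum(compartments_per_cell))
    vm = -65.0 + rng.standard_normal((n_samples, total))
    series = TimeSeries(
        "membrane_potential", vm, unit="millivolts", rate=rate_hz,
        starting_time=0.0, description="Per-compartment membrane potential.",
        neurodata_type="CompartmentSeries", namespace="ndx-simulation-output",
    )
    series.fields["compartments"] = table
    add_to_session(root, "acquisition", series)
    return root
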