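# hdml — a miniature hierarchical data-modeling language

Neurophysiology experiments produce deeply heterogeneous data: raw
extracellular voltage, spike-sorting output, ROI fluorescence, behavior and
stimuli, all recorded against one clock and all needing enough metadata to be
reanalyzed by someone who was not in the room. `hdml` is a small but complete
data-language stack for that problem, built for people who want to study or
prototype the *architecture* of such standards — schema authors, tool
developers, and students of scientific data modeling — at a scale where every
layer is readable.

The stack has the four classic components, each insulated from the next:

1. **Specification language** (`hdml.spec_language`) — a YAML dialect with
   exactly four primitive structures: *groups*, *datasets*, *attributes* and
   *links*. Group and dataset specs can introduce named, class-like
   *neurodata types* that are reused through inheritance (`type_inc` at the
   root of a definition) and composition (typed children). Shapes support
   wildcards and alternatives; quantities use a `? * + n` grammar; the dtype
   vocabulary is a closed set of fixed-width scalars plus text, timestamps,
   references and compounds.
2. **Schema + type system** (`hdml.type_system`, `hdml.core_schema`) — a
   registry of versioned namespaces that flattens a type over its ancestor
   chain (root ancestor first, name-keyed override, *narrowing-only*
   refinements: `int32` may refine `int64`, optional may become required,
   never the reverse). A curated mini core schema ships as ordinary
   specification documents: `TimeSeries`, `ElectricalSeries`,
   `DynamicTable`/`VectorData`/`VectorIndex`/`DynamicTableRegion`, `Units`,
   `PlaneSegmentation`, `RoiResponseSeries`, `Position`, `ProcessingModule`
   and a session root.
3. **Translation layer** (`hdml.builders`) — storage-agnostic builder trees
   mirroring the four primitives, plus a spec-driven object mapper:
   `build(container, registry)` places each container field where the
   resolved spec says it belongs, and `construct(builder, registry)` inverts
   it. A container referenced twice is written once and linked thereafter;
   unknown on-disk data is preserved in an escape-hatch bag, never dropped.
4. **Storage backends** (`hdml.storage`) — an HDF5 backend (groups/datasets/
   attributes/soft links) and a byte-deterministic plain-directory backend
   (raw little-endian arrays + JSON sidecars). Both embed the registered
   specification documents under `/specifications`, so files validate and
   reconstruct from an empty registry — they are self-describing.

Around the core: schema-driven **validation** with a nine-rule graded
catalogue (`hdml.validation`), an **extension mechanism** with an `ndx-`
namespace convention, local catalog and a worked simulation-output example
(`hdml.extensions`), a deterministic **synthetic-session generator**
(`hdml.fixtures`), and a `hdml` **CLI** (`validate`, `inspect`, `convert`,
`demo`, `ndx`).

All times are float64 seconds on the common session clock (0 s at
`session_start_time`); a time series carries either explicit `timestamps` or
`rate` + `starting_time`, never both.

## Worked example

Generate a synthetic multimodal session, write it to HDF5 with embedded
schema, read it back and validate it:

```python
import numpy as np
from hdml import (core_registry, build, validate_builders, format_report,
                  get_timestamps, SessionRecipe, generate_session)
from hdml.storage import hdf5

reg = core_registry()
session = generate_session(SessionRecipe(seed=1))   # 4 ch x 10 s @ 250 Hz, 5 units, 3 ROIs
tree = build(session, reg)
hdf5.write(tree, "demo.h5", registry=reg)

back = hdf5.read("demo.h5")
print(format_report(validate_builders(back, reg)))

units = session.fields["units"]
counts = np.diff(np.concatenate(([0], units.fields["spike_times_index"].data)))
print("spike counts per unit:", counts.tolist())
raw = session.acquisition["raw_ephys"]
t = get_timestamps(raw)
print("raw ephys:", raw.data.shape, "first/last sample times:", t[0], t[-1])
```

prints

```
PASS: no issues found

spike counts per unit: [44, 55, 47, 47, 50]
raw ephys: (2500, 4) first/last sample times: 0.0 9.996
```

The validator found no violations; the five units' spike counts scatter
around the 50 expected from a 5 Hz Poisson process over 10 s; the raw
voltage block is 2500 samples x 4 channels whose rate-form timing expands to
a uniform grid on the session clock. The same file from the shell:

```
$ hdml inspect demo.h5
/  [group] SessionRoot
/acquisition  [group]
/acquisition/raw_ephys  [group] ElectricalSeries
/acquisition/raw_ephys/data  [dataset]  float64 [2500, 4]
/acquisition/raw_ephys/electrodes  [dataset] DynamicTableRegion int64 [4]
/acquisition/raw_ephys/starting_time  [dataset]  float64 None
/electrodes  [group] DynamicTable
...
$ hdml validate demo.h5          # exit code 0; uses the embedded schema
PASS: no issues found
$ hdml convert demo.h5 demo.store   # hdf5 -> directory backend
```

`ElectricalSeries.electrodes` is a region reference: an explicit row-index
array into the session electrode table plus the table's path, portable
across backends. The `Units.spike_times` column is ragged — a flat data
array paired with a cumulative index, so unit *i* owns
`data[index[i-1]:index[i]]`.

### Extensions

```python
from hdml import core_registry, build
from hdml.extensions import (build_compartments_extension, register_extension,
                             example_compartments_session)
from hdml.storage import hdf5

reg = core_registry()
register_extension(reg, build_compartments_extension())  # ndx-simulation-output
hdf5.write(build(example_compartments_session(), reg), "sim.h5", registry=reg)
```

`Compartments` extends `DynamicTable` (ragged per-cell compartment numbers
and positions; 3 cells with (2, 1, 3) compartments give index arrays
`[2, 3, 6]`), and `CompartmentSeries` extends `TimeSeries` with a link to the
table, so column *j* of its data belongs to compartment *j* of the flattened
table. A fresh process can read, validate and reconstruct `sim.h5` using
only the specifications embedded in the file. `hdml ndx init/publish/list`
manage extension skeletons and the local catalog.

## Directory-backend layout

Groups are directories; each group's attributes and links live in
`_node.json`; each dataset is a `<name>.dataset.json` sidecar (dtype token,
shape, attributes) plus a raw little-endian C-order `<name>.bin` for numeric
data (text and scalars are inlined). JSON keys are sorted and floats
round-trip via `repr`, so writing the same tree twice is byte-identical.

## Limitations

The directory backend is a pluggability demonstrator, not a cloud-store
format; there is no chunking, compression, lazy reading or iterative
writing; compound dtypes are expressible in the language but not written by
the shipped backends; one version per namespace per registry. See
`docs/methods.md` for the full design notes.
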