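# Design and methods notes

This note records the package's model, conventions and deliberately made
design choices, in the spirit of a maintainer's methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The data-language model

A *data language* here is four separable components: a specification
language, a schema written in it, a translation layer, and storage
backends. The package keeps them insulated: the schema never names a
storage primitive, the backends never see a neurodata type (they move
builder trees), and user code touches typed containers only. The payoff is
testable: the same builder tree written through both backends reads back
equal, and a schema change (an extension) requires no backend or mapper
changes.

### Specification language

Exactly four node kinds exist — groups, datasets, attributes, links — and
the parser can produce no other. Decisions the grammar needed that a schema
document cannot express:

- **dtype vocabulary** (closed): `int8..int64`, `uint8..uint64`,
  `float32/64`, `bool`, `text`, `isodatetime`, object/region references to
  a named type, and compound (name, dtype) lists. Chosen to be what an
  HDF5-class backend can store losslessly; anything outside it is a parse
  error, not a warning.
- **shape grammar**: a list of extents where `null` is a wildcard; a list
  of lists declares alternatives; *absent shape means scalar*. `dims`
  labels must match the rank of at least one declared shape.
- **quantity grammar**: `'?'` -> (0,1), `'*'` -> (0,inf), `'+'` -> (1,inf),
  positive integer n -> (n,n); default exactly-one.
- **unknown keys warn, never fail** (`SpecWarning`), so documents written
  by a future dialect still load; unknown *data* on read is likewise
  preserved (see escape hatch below). Both are forward-compatibility
  choices.
- Type names match `[A-Za-z][A-Za-z0-9]*`; namespace names may add `-`
  (extensions use the `ndx-` prefix).

Serialization emits keys in a fixed order and `parse(serialize(x)) == x`
structurally; this is property-tested on seeded random spec trees.

### Type resolution

`resolve_type` flattens a type over its ancestor chain: the root ancestor
is laid down first, each descendant overlays it, children and attributes
are keyed by name (anonymous children by their type), and matching entries
merge recursively — "latest definition wins" as in class inheritance.
Refinements may only **narrow**: a dtype may move down the widening table
(`int32` under `int64`, `uint8` under `int16`, `float32` under `float64`,
`isodatetime` under `text`), a wildcard extent may be pinned, an optional
attribute may become required, a link target may move to a subtype. The
reverse directions raise `RefinementError`. The narrowing-only rule is this
package's decision (the upstream practice it mirrors does not pin one
down); it guarantees that any instance valid for a subtype satisfies every
ancestor constraint, which is what makes substituting a subtype into an
ancestor-typed slot sound.

Where an instance of a subtype occupies a slot declared for an ancestor
(e.g. an `ElectricalSeries` in a `TimeSeries` slot), validation resolves
the node's *actual* type and overlays the slot's inline refinements on it.
Composition is resolved two-phase: the included type first, the inline
overrides second.

One version per namespace per registry; re-registering the identical
(name, version) is a no-op, a different version is a conflict.
Multi-version registries are out of scope.

### Object mapping

The mapper is table-free: placement is driven entirely by the resolved
spec (named children at spec names, typed anonymous children at
container-supplied names, link specs from container fields holding shared
containers). Exactly two documented mappings go beyond the generic rule:

1. **Timing**: the rate form is stored as a scalar `starting_time` dataset
   carrying a `rate` attribute; explicit `timestamps` are an ordinary named
   dataset. The two forms are mutually exclusive by container invariant,
   so an invalid combination cannot be persisted.
2. **References**: ragged-column indexes (`VectorIndex.target`) and row
   regions (`DynamicTableRegion.table`) are stored as explicit index
   arrays plus a target-path attribute rather than backend-native
   references — portable across backends and diff-able on disk.

Shared containers follow first-encounter-owns: field iteration is sorted,
so the first (alphabetical) slot materializes the node and later
references become links; reconstruction restores reference identity.
Unknown nodes and attributes met on `construct` go into the container's
`extras` bag with a warning and are re-emitted on the next `build`
(preserved, never dropped).

### Storage

The backend contract is `read(write(t)) == t` structurally — dtype-,
attribute- and data-preserving. HDF5 maps primitives one-to-one; `bool`
(stored uint8) and `isodatetime` (stored text) record their declared token
in a reserved `_hdml_dtype` attribute so reads restore it. The directory
backend writes raw little-endian C-order arrays with JSON sidecars, sorted
keys and no timestamps, so identical trees produce byte-identical output;
this is the determinism contract the fixtures test exercises. Reserved
names: the `/specifications` group, the `neurodata_type` / `namespace` /
`object_id` attributes, and the `_node.json` / `*.dataset.json` / `*.bin`
sidecar names (collisions are storage errors).

Written files embed every registered namespace's specification documents
under `/specifications/<namespace>/<version>/<document>` — verbatim source
text when known, deterministically regenerated otherwise. That makes files
self-describing: validation and reconstruction need nothing but the file.
Compound dtypes, chunking, compression, lazy read and iterative write are
deliberately not implemented; the directory backend is a pluggability
demonstrator, not a cloud-store dialect.

### Validation

Nine rule classes with stable ids (see the table in
`hdml/validation.py`); severity defaults are error for structural rules,
warning for unmatched nodes/attributes, best-practice for absent optional
metadata, and a single `untyped-tree` warning for trees with no
annotations. The severity map is caller-configurable
(`severity_overrides`) because severity grading is policy, not schema.
dtype compatibility for stored data reuses the same widening table as
refinement (int32 data against an int64 spec passes; the reverse fails).
When several anonymous slots admit a node's type, the most specific
(deepest subtype) wins; a tie is reported rather than guessed.

### The mini core schema

The curated type set (TimeSeries, ElectricalSeries, DynamicTable family,
Units, PlaneSegmentation, RoiResponseSeries, SpatialSeries/Position,
ProcessingModule, SessionRoot) is this package's choice of a minimal set
that exercises every language feature: inheritance (ElectricalSeries <:
TimeSeries), composition (tables of typed columns), ragged columns,
region references, links, anonymous quantities and module grouping.
Required-versus-optional metadata per type follows the shipped schema
documents; the only optional-recommended attribute is
`TimeSeries.description`, which keeps the best-practice rule meaningful
without flooding reports. Processing modules are restricted to the labels
`ecephys`, `icephys`, `ophys`, `behavior`. All times are float64 seconds
relative to `session_start_time`; channel is the second axis of
`ElectricalSeries.data` (time-major).

## Synthetic sessions

`generate_session` emulates simultaneous acquisition of raw voltage,
sorted units, ROI fluorescence, behavior and a stimulus train on one
clock. Defaults: 4 channels at 250 Hz for 10 s, 5 units at 5 Hz Poisson,
3 ROIs at 20 Hz, 2-D position at 50 Hz — small enough that the full
5-seed x 3-size grid builds, writes, reads and validates in seconds, large
enough that every container type and both timing forms appear. Sizes are
the package's choice of a teaching-scale workload.

What it emulates and what it does not: spike trains are homogeneous
Poisson (the generator's one statistical contract, tested by rate
recovery); raw voltage is white Gaussian noise with spike-triggered
exponential transients (tau = 3 ms, -80 uV); dF/F is events convolved with
an exponential kernel (amplitude 1, tau = 0.5 s — fixed, arbitrary);
position is a Gaussian random walk. There is no biophysical realism — no
refractoriness, no 1/f noise, no imaging artifacts — so passing tests
demonstrate correctness of the *data-language machinery* on realistic
structure, not fidelity to any real recording.

Determinism: one seed per recipe, spawned into per-modality child streams
in a fixed order (ids, electrodes, units, ephys, ophys, behavior,
stimulus), so adding one modality never perturbs another's draws and the
directory backend writes bit-identical files for equal seeds. Object ids
come from the dedicated id stream, so they too are reproducible.

`corrupt_session` injects exactly one targeted violation per validator
rule (removing a required region, mis-typing an attribute, flattening a
2-D block, emptying a required-once slot, unsorting timestamps or a ragged
index, adding a dangling link, planting a mislocated typed node, dropping
a recommended description). The differential contract — corrupted trees
report the rule, clean trees do not, and no collateral errors appear away
from the injection site — is what the completeness tests assert.

## Numerical and degenerate-input choices

- Rate-form timestamps expand as `start + arange(n)/rate` in float64; the
  test oracle accumulates `dt` stepwise and agreement is required within
  1e-12 relative (the closed form is the more accurate of the two).
- Ragged columns: the index stores cumulative *end* offsets
  (`data[index[i-1]:index[i]]` is row i); empty rows and all-empty columns
  are legal and tested; index arrays are int64.
- Zero-count recipes (0 units, 0 ROIs, 0 channels) produce empty but
  schema-valid structures.
- JSON sidecars rely on `repr`-exact float round-tripping; NaN is not used
  by the generator and not special-cased.
- Equality is strict: arrays compare bit-exact including dtype, metadata
  string-exact, object ids exact.

## Known limitations

- No compound-dtype storage, no multi-version registries, no lazy/chunked
  I/O (all deliberate scope cuts).
- The catalog models review status (`draft`/`proposed`/`accepted`) as a
  record field; it does not enforce a review workflow.
- The extension worked example reconstructs the simulation-output column
  set from its published description; exact upstream column naming may
  differ.
- Severity assignments and the recommended-metadata list are conventions
  of this package, documented above and configurable at call time.
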