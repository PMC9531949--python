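datasets:
- type_def: VectorData
  shape:
  - [null]
  - [null, null]
  - [null, null, null]
  attributes:
  - name: description
    dtype: text
    doc: Description of what this column/vector stores.
  doc: A one-or-more-dimensional vector whose first axis is the row axis of
    an owning dynamic table.

- type_def: VectorIndex
  type_inc: VectorData
  dtype: int64
  shape:
  - [null]
  attributes:
  - name: target
    dtype: text
    doc: Path of the VectorData this index ranges into.
  doc: Cumulative end-offsets into a target VectorData, making that column
    ragged. Row i of the column is target[index[i-1]:index[i]].

- type_def: DynamicTableRegion
  type_inc: VectorData
  dtype: int64
  shape:
  - [null]
  attributes:
  - name: table
    dtype: text
    doc: Path of the DynamicTable this region selects rows from.
  doc: A region reference, a pointer to a subset of rows of a dynamic
    table, stored portably as an explicit row-index array plus the table
    path.

groups:
- type_def: TimeSeries
  attributes:
  - name: unit
    dtype: text
    doc: Base unit of measurement of the stored data.
  - name: description
    dtype: text
    required: false
    doc: Human description of this series. Recommended.
  datasets:
  - name: data
    shape:
    - [null]
    - [null, null]
    - [null, null, null]
    dims: [time]
    doc: The recorded values; the first axis is always time.
  - name: timestamps
    dtype: float64
    shape:
    - [null]
    quantity: '?'
    doc: Per-sample times in seconds on the session clock; non-decreasing.
  - name: starting_time
    dtype: float64
    quantity: '?'
    attributes:
    - name: rate
      dtype: float64
      doc: Sampling rate in Hz.
    doc: Start time in seconds on the session clock for regularly sampled
      data; carries the sampling rate as an attribute. Exactly one of
      timestamps or starting_time must be present.
  doc: Generic measurement sampled over time, registered to the common
    session clock either with explicit timestamps or with a sampling rate
    and starting time.

- type_def: ElectricalSeries
  type_inc: TimeSeries
  datasets:
  - name: data
    dtype: float64
    shape:
    - [null, null]
    dims: [time, channel]
    doc: Voltage traces, time by channel.
  - name: electrodes
    type_inc: DynamicTableRegion
    doc: Region reference into the session electrode table selecting the
      recorded channels, in channel order.
  doc: Extracellularly recorded voltage time series; requires an electrodes
    region reference describing the recording channels.

- type_def: DynamicTable
  attributes:
  - name: description
    dtype: text
    doc: Description of what this table holds.
  - name: colnames
    dtype: text
    shape:
    - [null]
    doc: Ordered names of the user columns.
  datasets:
  - name: id
    dtype: int64
    shape:
    - [null]
    doc: Unique row identifiers.
  - type_inc: VectorData
    quantity: '*'
    doc: The table columns; all share the row count of id.
  - type_inc: VectorIndex
    quantity: '*'
    doc: Index arrays making their target columns ragged.
  doc: Column-oriented table whose columns are aligned VectorData arrays;
    ragged columns pair a flat data array with a cumulative index array.

- type_def: Units
  type_inc: DynamicTable
  datasets:
  - name: spike_times
    type_inc: VectorData
    dtype: float64
    shape:
    - [null]
    doc: Flattened spike times of all units, seconds on the session clock.
  - name: spike_times_index
    type_inc: VectorIndex
    doc: Per-unit end offsets into spike_times.
  doc: Table of sorted units with a ragged spike_times column.

- type_def: PlaneSegmentation
  type_inc: DynamicTable
  datasets:
  - name: pixel_mask
    type_inc: VectorData
    dtype: float64
    shape:
    - [null, 3]
    doc: Flattened (x, y, weight) pixel triples of all ROI masks.
  - name: pixel_mask_index
    type_inc: VectorIndex
    doc: Per-ROI end offsets into pixel_mask.
  doc: Table of imaging regions of interest with ragged pixel masks.

- type_def: RoiResponseSeries
  type_inc: TimeSeries
  datasets:
  - name: data
    dtype: float64
    shape:
    - [null]
    - [null, null]
    doc: Fluorescence or dF/F traces, time by ROI.
  - name: rois
    type_inc: DynamicTableRegion
    doc: Region reference into a PlaneSegmentation table selecting the
      ROIs, in trace order.
  doc: Fluorescence response of imaging ROIs over time.

- type_def: SpatialSeries
  type_inc: TimeSeries
  attributes:
  - name: reference_frame
    dtype: text
    doc: Description of the zero position of the coordinate frame.
  datasets:
  - name: data
    dtype: float64
    shape:
    - [null]
    - [null, null]
    doc: Position samples, time by spatial dimension.
  doc: Position of the subject over time in an experimenter-defined frame.

- type_def: Position
  groups:
  - type_inc: SpatialSeries
    quantity: '+'
    doc: One or more position series.
  doc: Behavioral position data holding one or more SpatialSeries.

- type_def: ProcessingModule
  attributes:
  - name: description
    dtype: text
    doc: What processing this module holds.
  groups:
  - type_inc: TimeSeries
    quantity: '*'
    doc: Processed time series.
  - type_inc: DynamicTable
    quantity: '*'
    doc: Processed tabular results.
  - type_inc: Position
    quantity: '*'
    doc: Behavioral interfaces.
  doc: A named collection of processed data for one analysis domain
    (ecephys, icephys, ophys, behavior).

- type_def: SessionRoot
  attributes:
  - name: session_description
    dtype: text
    doc: One-sentence description of the experimental session.
  - name: identifier
    dtype: text
    doc: Globally unique session identifier.
  - name: session_start_time
    dtype: isodatetime
    doc: Wall-clock session start; the origin of the common clock.
  groups:
  - name: acquisition
    groups:
    - type_inc: TimeSeries
      quantity: '*'
      doc: Raw acquired streams.
    doc: Raw acquired data streams.
  - name: processing
    groups:
    - type_inc: ProcessingModule
      quantity: '*'
      doc: Processing modules keyed by analysis domain.
    doc: Processed data organized in modules.
  - name: stimulus
    groups:
    - type_inc: TimeSeries
      quantity: '*'
      doc: Stimulus presentation streams.
    doc: Stimulus data.
  - name: electrodes
    type_inc: DynamicTable
    quantity: '?'
    doc: Session electrode table; rows are channels with position,
      impedance, location and group columns.
  - name: units
    type_inc: Units
    quantity: '?'
    doc: Sorted units with spike times.
  doc: Root container of one experimental session holding all measurements
    and metadata; every stream is registered to the common clock starting
    at session_start_time.
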