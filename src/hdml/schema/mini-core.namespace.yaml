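namespaces:
- name: mini-core
  version: 0.1.0
  doc: Miniature core schema for multimodal neurophysiology sessions, built
    from the four specification-language primitives. Curated types cover
    regularly and irregularly sampled time series, extracellular recordings
    with an electrode table, column-oriented dynamic tables with ragged
    columns, sorted units, ROI fluorescence, and behavioral position.
  authors:
  - hdml developers
  schema:
  - source: mini-core.yaml
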