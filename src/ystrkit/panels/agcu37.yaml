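# AGCU Y37 six-dye multiplex: 34 marker columns, 3 of them multi-copy
# (DYS527a/b, DYS385a/b, DYF387S1), for 37 amplified locus copies in total.
# Marker order follows the kit's published locus list.
name: AGCU37
markers:
  - [DYS392, 1]
  - [DYS389I, 1]
  - [DYS447, 1]
  - [DYS389II, 1]
  - [DYS438, 1]
  - [DYS527a/b, 2]
  - [DYS645, 1]
  - [DYS596, 1]
  - [DYS391, 1]
  - [DYS456, 1]
  - [DYS19, 1]
  - [DYS593, 1]
  - [DYS448, 1]
  - [DYS449, 1]
  - [DYS385a/b, 2]
  - [DYS549, 1]
  - [DYS437, 1]
  - [DYS481, 1]
  - [DYS533, 1]
  - [DYS390, 1]
  - [DYS627, 1]
  - [DYS458, 1]
  - [DYS460, 1]
  - [DYS393, 1]
  - [Y_GATA_H4, 1]
  - [DYS439, 1]
  - [DYS635, 1]
  - [DYS444, 1]
  - [DYS643, 1]
  - [DYS557, 1]
  - [DYS576, 1]
  - [DYS570, 1]
  - [DYF387S1, 2]
  - [DYS518, 1]
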