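# Yfiler 17-locus panel: 16 marker columns, DYS385a/b multi-copy.
# Membership follows the commercial kit's documented locus list; edit to
# match a local convention if it differs.
name: YFILER17
markers:
  - [DYS456, 1]
  - [DYS389I, 1]
  - [DYS390, 1]
  - [DYS389II, 1]
  - [DYS458, 1]
  - [DYS19, 1]
  - [DYS385a/b, 2]
  - [DYS393, 1]
  - [DYS391, 1]
  - [DYS439, 1]
  - [DYS635, 1]
  - [DYS392, 1]
  - [Y_GATA_H4, 1]
  - [DYS437, 1]
  - [DYS438, 1]
  - [DYS448, 1]
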