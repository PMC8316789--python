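# Yfiler Plus 27-locus panel: 25 marker columns, DYS385a/b and DYF387S1
# multi-copy. Membership follows the commercial kit's documented locus list.
name: YFILERPLUS27
markers:
  - [DYS576, 1]
  - [DYS389I, 1]
  - [DYS635, 1]
  - [DYS389II, 1]
  - [DYS627, 1]
  - [DYS460, 1]
  - [DYS458, 1]
  - [DYS19, 1]
  - [Y_GATA_H4, 1]
  - [DYS448, 1]
  - [DYS391, 1]
  - [DYS456, 1]
  - [DYS390, 1]
  - [DYS438, 1]
  - [DYS392, 1]
  - [DYS518, 1]
  - [DYS570, 1]
  - [DYS437, 1]
  - [DYS385a/b, 2]
  - [DYS449, 1]
  - [DYS393, 1]
  - [DYS439, 1]
  - [DYS481, 1]
  - [DYF387S1, 2]
  - [DYS533, 1]
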