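name: nw-us-source
description: Native source determination for the northwestern US (Oregon and Washington)
  population.
populations:
  China:
    size: N1
    role: native
    sample_size: 158
  Japan:
    size: N2
    role: native
    sample_size: 44
  Korea:
    size: N3
    role: native
    sample_size: 12
  NWUS:
    size: N4
    role: introduced
    sample_size: 25
groups:
  China:
  - China
  Japan:
  - Japan
  Korea:
  - Republic of Korea
  NWUS:
  - Oregon
  - Washington
scenarios:
- id: 1
  description: China source
  events:
  - time: t1
    kind: merge
    child: NWUS
    parent: China
  - time: t2
    kind: merge
    child: Korea
    parent: Japan
  - time: t3
    kind: merge
    child: Japan
    parent: China
  conditions:
  - N4 < min(N1, N2, N3)
- id: 2
  description: Japan source
  events:
  - time: t1
    kind: merge
    child: NWUS
    parent: Japan
  - time: t2
    kind: merge
    child: Korea
    parent: Japan
  - time: t3
    kind: merge
    child: Japan
    parent: China
  conditions:
  - N4 < min(N1, N2, N3)
- id: 3
  description: Korea source
  events:
  - time: t1
    kind: merge
    child: NWUS
    parent: Korea
  - time: t2
    kind: merge
    child: Korea
    parent: Japan
  - time: t3
    kind: merge
    child: Japan
    parent: China
  conditions:
  - N4 < min(N1, N2, N3)
abc:
  n_rows: 1000000
  tolerance: 0.01
  n_pods: 500
  length: 685
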