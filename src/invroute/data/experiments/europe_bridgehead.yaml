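name: europe-bridgehead
description: Was early Europe sourced from China or a bridgehead from the eastern
  or western US?
populations:
  China:
    size: N1
    role: native
    sample_size: 158
  EastUS:
    size: N2
    role: introduced
    sample_size: 70
  WestUS:
    size: N3
    role: introduced
    sample_size: 38
  Europe:
    size: N4
    role: introduced
    sample_size: 486
groups:
  China:
  - China
  EastUS:
  - New Jersey
  - Maryland
  - Georgia
  - Delaware
  - Massachusetts
  - Mississippi
  - New York
  - Pennsylvania
  - Virginia
  - West Virginia
  - Ohio
  - Michigan
  WestUS:
  - California
  - Oregon
  - Washington
  Europe:
  - North Switzerland
  - Lugano
  - Ticino
  - Emilia-Romagna
  - Lombardy
  - Schiltigheim
  - Budapest
scenarios:
- id: 1
  description: China source
  events:
  - time: t1
    kind: merge
    child: Europe
    parent: China
  - time: t2
    kind: merge
    child: WestUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions:
  - N2 < N1
  - N3 < N1
  - N4 < N1
- id: 2
  description: Bridgehead from Eastern US
  events:
  - time: t1
    kind: merge
    child: Europe
    parent: EastUS
  - time: t2
    kind: merge
    child: WestUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions:
  - N2 < N1
  - N3 < N1
  - N4 < N1
- id: 3
  description: Bridgehead from Western US
  events:
  - time: t1
    kind: merge
    child: Europe
    parent: WestUS
  - time: t2
    kind: merge
    child: WestUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions:
  - N2 < N1
  - N3 < N1
  - N4 < N1
abc:
  n_rows: 1000000
  tolerance: 0.01
  n_pods: 500
  length: 685
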