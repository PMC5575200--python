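name: emilia-romagna-bridgehead
description: Is the Emilia-Romagna (Italy) population a dispersal from broader Europe,
  a bridgehead from the eastern US, or a separate introduction from China?
populations:
  China:
    size: N1
    role: native
    sample_size: 158
  EastUS:
    size: N2
    role: introduced
    sample_size: 70
  Europe:
    size: N3
    role: introduced
    sample_size: 455
  EmiliaRomagna:
    size: N4
    role: introduced
    sample_size: 31
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
  Europe:
  - North Switzerland
  - Lugano
  - Ticino
  - Lombardy
  - Schiltigheim
  - Budapest
  EmiliaRomagna:
  - Emilia-Romagna
scenarios:
- id: 1
  description: Dispersal from Europe
  events:
  - time: t1
    kind: merge
    child: EmiliaRomagna
    parent: Europe
  - time: t2
    kind: merge
    child: Europe
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
  description: Bridgehead from US
  events:
  - time: t1
    kind: merge
    child: EmiliaRomagna
    parent: EastUS
  - time: t2
    kind: merge
    child: Europe
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
  description: Separate introduction from China
  events:
  - time: t1
    kind: merge
    child: EmiliaRomagna
    parent: China
  - time: t2
    kind: merge
    child: Europe
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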