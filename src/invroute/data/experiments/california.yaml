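name: california
description: Seven hypotheses for the introduction to California, given separate eastern-US
  and northwestern-US introductions from China.
populations:
  China:
    size: N1
    role: native
    sample_size: 158
  EastUS:
    size: N2
    role: introduced
    sample_size: 70
  NWUS:
    size: N3
    role: introduced
    sample_size: 25
  California:
    size: N4
    role: introduced
    sample_size: 13
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
  NWUS:
  - Oregon
  - Washington
  California:
  - California
scenarios:
- id: 1
  description: Separate introduction from China
  events:
  - time: t1
    kind: merge
    child: California
    parent: China
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions: &id001
  - N2 < N1
  - N3 < N1
  - N4 < N1
- id: 2
  description: Dispersal from Northwestern US
  events:
  - time: t1
    kind: merge
    child: California
    parent: NWUS
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions: *id001
- id: 3
  description: Dispersal from Eastern US
  events:
  - time: t1
    kind: merge
    child: California
    parent: EastUS
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions: *id001
- id: 4
  description: Introduced to California then spread to Eastern US
  events:
  - time: t1
    kind: merge
    child: EastUS
    parent: California
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: California
    parent: China
  conditions: *id001
- id: 5
  description: Mixture of Northwestern and East US
  events:
  - time: t1
    kind: admixture
    child: California
    parent_a: NWUS
    parent_b: EastUS
    rate: r1
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions: *id001
- id: 6
  description: Mixture of separate China introduction and Eastern US
  events:
  - time: t1
    kind: admixture
    child: California
    parent_a: China
    parent_b: EastUS
    rate: r1
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions: *id001
- id: 7
  description: Mixture of separate China introduction and Northwestern US
  events:
  - time: t1
    kind: admixture
    child: California
    parent_a: China
    parent_b: NWUS
    rate: r1
  - time: t2
    kind: merge
    child: NWUS
    parent: China
  - time: t3
    kind: merge
    child: EastUS
    parent: China
  conditions: *id001
abc:
  n_rows: 1000000
  tolerance: 0.01
  n_pods: 500
  length: 685
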