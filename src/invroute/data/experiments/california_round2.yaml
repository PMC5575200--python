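abc:
  length: 685
  n_pods: 500
  n_rows: 1000000
  tolerance: 0.01
description: Second-round California analysis on the scenarios surviving the 0.10
  posterior-probability cutoff.
groups:
  California:
  - California
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
name: california-round2
populations:
  California:
    role: introduced
    sample_size: 13
    size: N4
  China:
    role: native
    sample_size: 158
    size: N1
  EastUS:
    role: introduced
    sample_size: 70
    size: N2
  NWUS:
    role: introduced
    sample_size: 25
    size: N3
scenarios:
- conditions: &id001
  - N2 < N1
  - N3 < N1
  - N4 < N1
  description: Dispersal from Eastern US
  events:
  - child: California
    kind: merge
    parent: EastUS
    time: t1
  - child: NWUS
    kind: merge
    parent: China
    time: t2
  - child: EastUS
    kind: merge
    parent: China
    time: t3
  id: 3
- conditions: *id001
  description: Mixture of Northwestern and East US
  events:
  - child: California
    kind: admixture
    parent_a: NWUS
    parent_b: EastUS
    rate: r1
    time: t1
  - child: NWUS
    kind: merge
    parent: China
    time: t2
  - child: EastUS
    kind: merge
    parent: China
    time: t3
  id: 5
- conditions: *id001
  description: Mixture of separate China introduction and Eastern US
  events:
  - child: California
    kind: admixture
    parent_a: China
    parent_b: EastUS
    rate: r1
    time: t1
  - child: NWUS
    kind: merge
    parent: China
    time: t2
  - child: EastUS
    kind: merge
    parent: China
    time: t3
  id: 6
- conditions: *id001
  description: Mixture of separate China introduction and Northwestern US
  events:
  - child: California
    kind: admixture
    parent_a: China
    parent_b: NWUS
    rate: r1
    time: t1
  - child: NWUS
    kind: merge
    parent: China
    time: t2
  - child: EastUS
    kind: merge
    parent: China
    time: t3
  id: 7
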