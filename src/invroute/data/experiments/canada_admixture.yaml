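name: canada-admixture
description: Did Canada come from China alone, the US alone, or a mixture of China
  with the eastern or northwestern US?
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
  Canada:
    size: N4
    role: introduced
    sample_size: 51
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
  Canada:
  - Canada
scenarios:
- id: 1
  description: China only source
  events:
  - time: t1
    kind: merge
    child: Canada
    parent: China
  - time: t2
    kind: merge
    child: NWUS
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
  description: US only source
  events:
  - time: t1
    kind: merge
    child: Canada
    parent: EastUS
  - time: t2
    kind: merge
    child: NWUS
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
  description: China + East US mixture
  events:
  - time: t1
    kind: admixture
    child: Canada
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
  conditions:
  - N2 < N1
  - N3 < N1
  - N4 < N1
- id: 4
  description: China + Northwest US mixture
  events:
  - time: t1
    kind: admixture
    child: Canada
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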