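name: greece-hungary
description: Was Greece a separate introduction from China, a mixture of Hungary and
  China, or a China introduction that then spread to Hungary?
populations:
  China:
    size: N1
    role: native
    sample_size: 158
  Hungary:
    size: N2
    role: introduced
    sample_size: 84
  Greece:
    size: N3
    role: introduced
    sample_size: 57
groups:
  China:
  - China
  Hungary:
  - Budapest
  Greece:
  - Athens
scenarios:
- id: 1
  description: Greece from China only
  events:
  - time: t1
    kind: merge
    child: Greece
    parent: China
  - time: t2
    kind: merge
    child: Hungary
    parent: China
  conditions:
  - N2 < N1
  - N3 < N1
- id: 2
  description: Mixture from Hungary and China
  events:
  - time: t1
    kind: admixture
    child: Greece
    parent_a: China
    parent_b: Hungary
    rate: r1
  - time: t2
    kind: merge
    child: Hungary
    parent: China
  conditions:
  - N2 < N1
  - N3 < N1
- id: 3
  description: China source that spread to Hungary
  events:
  - time: t1
    kind: merge
    child: Hungary
    parent: Greece
  - time: t2
    kind: merge
    child: Greece
    parent: China
  conditions:
  - N2 < N1
  - N3 < N1
abc:
  n_rows: 1000000
  tolerance: 0.01
  n_pods: 500
  length: 685
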