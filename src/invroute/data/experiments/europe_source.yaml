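name: europe-source
description: Native source of the initial European introduction (all European populations
  except Greece, pooled).
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
  Europe:
    size: N4
    role: introduced
    sample_size: 486
groups:
  China:
  - China
  Japan:
  - Japan
  Korea:
  - Republic of Korea
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
    child: Europe
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
    child: Europe
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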