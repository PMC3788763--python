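schema: coalabc-scenario-v1
id: Sc6
description: South-first divergence with expansions coincident with the divergence events.
populations: [SAG, NAG, NC]
initial_sizes: {SAG: N_SAG, NAG: N_NAG, NC: N_NC}
priors:
  N_anc: [1000, 60000]
  N_SAG: [100000, 3600000]
  N_NAG: [150000, 800000]
  N_NC: [40000, 150000]
  Mu: [1.0e-11, 1.0e-07]
  t_2: [50000, 350000]
  t_3: [100000, 1000000]
  N4: [100, 200000]
constraints: [N_anc < N_NC, N_NC <= N_NAG, N_NAG <= N_SAG, t_2 < t_3, N_anc < N4]
events:
- {time: t_2, kind: merge, source: NC, dest: NAG}
- {time: t_2, kind: resize, population: NAG, size: N4}
- {time: t_3, kind: merge, source: NAG, dest: SAG}
- {time: t_3, kind: resize, population: SAG, size: N_anc}
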