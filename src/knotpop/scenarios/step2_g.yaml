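# Reconstructed divergence/admixture scenario for the eight red knot
# breeding populations. Topology and admixture events follow the
# published prose descriptions; numeric prior ranges bracket the
# published posterior 95% CIs and are NOT the original supplementary
# prior tables (non-canonical reconstruction). Times in generations,
# sizes in diploids.
name: step2_g
description: 'Alternative: islandica diverges from rufa before the pulse from roselaariE into rufa; admixed
  origins of rogersi (canutus x roselaariE) and roselaariW (roselaariE x rogersi).'
populations:
- {label: rufa, samples: 10, size: N_rufa}
- {label: islandica, samples: 10, size: N_islandica}
- {label: canutus, samples: 10, size: N_canutus}
- {label: piersmai, samples: 10, size: N_piersmai}
- {label: rogersi1, samples: 10, size: N_rogersi1}
- {label: rogersi2, samples: 10, size: N_rogersi2}
- {label: roselaariW, samples: 10, size: N_roselaariW}
- {label: roselaariE, samples: 10, size: N_roselaariE}
events:
- {kind: merge, time: t_rogersi, source: rogersi2, dest: rogersi1, new_dest_size: N_anc_rogersi}
- {kind: merge, time: t_piersmai, source: piersmai, dest: canutus, new_dest_size: N_anc_canutus}
- {kind: merge, time: t_inner, source: canutus, dest: roselaariE, new_dest_size: N_anc_inner}
- {kind: merge, time: t_root, source: roselaariE, dest: rufa, new_dest_size: N_anc_root}
- {kind: merge, time: t_islandica, source: islandica, dest: rufa, new_dest_size: N_anc_rufa}
- {kind: admix, time: t_adm_roselaari, target: rufa, source1: roselaariE, source2: rufa, rate: r_roselaari}
- {kind: admix, time: t_adm_roselaariW, target: roselaariW, source1: roselaariE, source2: rogersi1, rate: r_roselaariW}
- {kind: admix, time: t_adm_rogersi, target: rogersi1, source1: canutus, source2: roselaariE, rate: r_rogersi}
priors:
  N_rufa: {dist: uniform, low: 2000, high: 60000}
  N_islandica: {dist: uniform, low: 2000, high: 60000}
  N_canutus: {dist: uniform, low: 2000, high: 60000}
  N_piersmai: {dist: uniform, low: 2000, high: 60000}
  N_rogersi1: {dist: uniform, low: 2000, high: 60000}
  N_rogersi2: {dist: uniform, low: 2000, high: 60000}
  N_roselaariW: {dist: uniform, low: 2000, high: 60000}
  N_roselaariE: {dist: uniform, low: 2000, high: 60000}
  t_rogersi: {dist: uniform, low: 80, high: 1100}
  N_anc_rogersi: {dist: uniform, low: 2000, high: 60000}
  t_piersmai: {dist: uniform, low: 300, high: 2000}
  N_anc_canutus: {dist: uniform, low: 2000, high: 60000}
  t_inner: {dist: uniform, low: 800, high: 4000}
  N_anc_inner: {dist: uniform, low: 2000, high: 60000}
  t_root: {dist: uniform, low: 1500, high: 10000}
  N_anc_root: {dist: uniform, low: 2000, high: 60000}
  t_islandica: {dist: uniform, low: 100, high: 1500}
  N_anc_rufa: {dist: uniform, low: 2000, high: 60000}
  t_adm_roselaari: {dist: uniform, low: 300, high: 1800}
  r_roselaari: {dist: uniform, low: 0.05, high: 0.95}
  t_adm_roselaariW: {dist: uniform, low: 300, high: 2000}
  r_roselaariW: {dist: uniform, low: 0.05, high: 0.95}
  t_adm_rogersi: {dist: uniform, low: 300, high: 2000}
  r_rogersi: {dist: uniform, low: 0.05, high: 0.95}
constraints:
- [t_piersmai, <, t_inner]
- [t_inner, <, t_root]
- [t_adm_roselaari, <, t_islandica]
- [t_islandica, <, t_root]
- [t_rogersi, <, t_adm_rogersi]
- [t_adm_rogersi, <, t_inner]
- [t_adm_roselaariW, <, t_adm_rogersi]
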