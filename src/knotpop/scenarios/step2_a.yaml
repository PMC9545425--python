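# Reconstructed divergence/admixture scenario for the eight red knot
# breeding populations. Topology and admixture events follow the
# published prose descriptions; numeric prior ranges bracket the
# published posterior 95% CIs and are NOT the original supplementary
# prior tables (non-canonical reconstruction). Times in generations,
# sizes in diploids.
name: step2_a
description: Step-1 winner with a young admixed origin of piersmai; islandica is a plain split from rufa.
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
- {kind: merge, time: t_roselaari, source: roselaariW, dest: roselaariE, new_dest_size: N_anc_roselaari}
- {kind: admix, time: t_adm_roselaari, target: rufa, source1: roselaariE, source2: rufa, rate: r_roselaari}
- {kind: merge, time: t_beringia, source: roselaariE, dest: rogersi1, new_dest_size: N_anc_beringia}
- {kind: merge, time: t_canutus, source: canutus, dest: rogersi1, new_dest_size: N_anc_palearctic}
- {kind: merge, time: t_root, source: rufa, dest: rogersi1, new_dest_size: N_anc_root}
- {kind: admix, time: t_adm_piersmai, target: piersmai, source1: rogersi1, source2: canutus, rate: r_piersmai}
- {kind: merge, time: t_islandica, source: islandica, dest: rufa, new_dest_size: N_anc_rufa}
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
  t_roselaari: {dist: uniform, low: 300, high: 2200}
  N_anc_roselaari: {dist: uniform, low: 2000, high: 60000}
  t_adm_roselaari: {dist: uniform, low: 300, high: 1800}
  r_roselaari: {dist: uniform, low: 0.05, high: 0.95}
  t_beringia: {dist: uniform, low: 600, high: 3000}
  N_anc_beringia: {dist: uniform, low: 2000, high: 60000}
  t_canutus: {dist: uniform, low: 800, high: 4000}
  N_anc_palearctic: {dist: uniform, low: 2000, high: 60000}
  t_root: {dist: uniform, low: 1500, high: 10000}
  N_anc_root: {dist: uniform, low: 2000, high: 60000}
  t_adm_piersmai: {dist: uniform, low: 100, high: 900}
  r_piersmai: {dist: uniform, low: 0.05, high: 0.95}
  t_islandica: {dist: uniform, low: 100, high: 1500}
  N_anc_rufa: {dist: uniform, low: 2000, high: 60000}
constraints:
- [t_roselaari, <, t_beringia]
- [t_rogersi, <, t_beringia]
- [t_adm_roselaari, <, t_beringia]
- [t_beringia, <, t_canutus]
- [t_canutus, <, t_root]
- [t_adm_piersmai, <, t_canutus]
- [t_islandica, <, t_root]
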