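# Default farming-practice set and effectiveness matrix.
#
# ILLUSTRATIVE VALUES ONLY: the effectiveness entries are plausible
# expert-style judgements (0 = no effect, 1 = highly effective), not an
# evidence-synthesized matrix. Override this file for real use.
#
# Practice codes M4, M5 and M9 are conventional mappings chosen here
# (tagetes/deep-rooting crops, leguminous crops, straw residues).

practices:
  - {practice_id: M1, label: liming, land_uses: ["*"], soil_types: ["*"]}
  - {practice_id: M2, label: compost application, land_uses: ["*"], soil_types: ["*"]}
  - {practice_id: M3, label: non-till practices, land_uses: [arable, maize], soil_types: ["*"]}
  - {practice_id: M4, label: tagetes or deep-rooting crops, land_uses: [arable], soil_types: ["*"]}
  - {practice_id: M5, label: leguminous crops, land_uses: [arable, grassland], soil_types: ["*"]}
  - {practice_id: M6, label: use of catch crops, land_uses: [arable, maize], soil_types: ["*"]}
  - {practice_id: M7, label: increasing grassland age, land_uses: [grassland], soil_types: ["*"]}
  - {practice_id: M8, label: fertilization conform maintenance-and-build-up approach, land_uses: ["*"], soil_types: ["*"]}
  - {practice_id: M9, label: straw residue incorporation, land_uses: [arable], soil_types: ["*"]}
  - {practice_id: M10, label: improve botanical composition of grassland, land_uses: [grassland], soil_types: ["*"]}
  - {practice_id: M11, label: repairing subsoil compaction, land_uses: ["*"], soil_types: ["*"]}

effectiveness:
  M1: {i_c_ph: 1.0, i_c_cec: 0.3, i_c_mg: 0.2}
  M2: {i_p_aggstability: 0.7, i_p_water: 0.6, i_b_disease: 0.6, i_b_pmn: 0.5, i_c_n: 0.3}
  M3: {i_p_aggstability: 0.5, i_p_sealing: 0.4, i_b_pmn: 0.3}
  M4: {i_b_disease: 0.8, i_p_compaction: 0.3}
  M5: {i_c_n: 0.7, i_b_pmn: 0.3}
  M6: {i_e_ngw: 0.8, i_b_pmn: 0.4, i_p_aggstability: 0.3}
  M7: {i_b_pmn: 0.6, i_p_aggstability: 0.5, i_c_n: 0.3}
  M8: {i_c_n: 0.8, i_c_p: 0.8, i_c_k: 0.8, i_c_mg: 0.7, i_c_cu: 0.6, i_c_s: 0.7, i_c_zn: 0.6}
  M9: {i_p_aggstability: 0.4, i_b_pmn: 0.3, i_p_sealing: 0.3}
  M10: {i_b_disease: 0.5, i_b_pmn: 0.4, i_p_aggstability: 0.3}
  M11: {i_p_compaction: 1.0, i_p_water: 0.3}
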