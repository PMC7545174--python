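# Fibrillin-1 (FBN1) domain map, SYNTHETIC completion.
#
# Only cbEGF12 and cbEGF13 are annotated in detail. Their residue ranges
# (D1070-M1112, D1113-I1154) and the mutation->disulfide-bond assignments
# (C1074 and C1081 open bonds 1 and 2; C1086 -> bond 1, C1111 -> bond 3 in
# cbEGF12; C1117 -> bond 1, C1138 -> bond 2 in cbEGF13) are literature
# anchored. The remaining cysteine ordinals and the N-terminal-loop calcium
# ligands are representative completions consistent with the conserved cbEGF
# C1-C3 / C2-C4 / C5-C6 disulfide pattern and the reported beta-hairpin
# calcium ligands (cbEGF12: N1088, T1089, D1092; cbEGF13: N1131, T1132,
# S1135) -- they are NOT authoritative residue assignments.
name: fbn1_synthetic
protein_length: 2871
ligand_residues: []
domains:
  - name: cbEGF12
    type: cbEGF
    start: 1070
    end: 1112
    cysteines: {1: 1074, 2: 1081, 3: 1086, 4: 1097, 5: 1099, 6: 1111}
    calcium_binding: {1070: D, 1073: E, 1088: N, 1089: T, 1092: D}
  - name: cbEGF13
    type: cbEGF
    start: 1113
    end: 1154
    cysteines: {1: 1117, 2: 1124, 3: 1129, 4: 1138, 5: 1142, 6: 1153}
    calcium_binding: {1113: D, 1116: E, 1131: N, 1132: T, 1135: S}
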