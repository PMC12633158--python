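"""Ligand-receptor fold-change contrast between the two conditions.

Scores four candidate LR pairs (two mechanistic pairs riding the cascade,
two false controls among highly expressed but uncoupled genes) in both the
interacting (case1) and control (case2) simulations with a shared Hill
saturation constant, then tabulates fold changes.  Only the mechanistic
pairs should respond to switching the cascade on.
"""

from qsimcells import contrast_cases
from qsimcells.presets import case1_config, case2_config

table = contrast_cases(
    case2_config(seed=1, shots=2000),   # control: no cell-cell communication
    case1_config(seed=1, shots=2000),   # interacting: cascade active
    n_perm=99,
)

cols = ["interaction_name", "annotation", "score_control",
        "score_interacting", "fold_change", "pval_interacting"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))

print("\nTrue pairs (g3->g5, g7->g0) gain several-fold when the cascade is")
print("active; false pairs (g8->g4, g9->g4) stay near fold change 1 even")
print("though their permutation p-values are 'significant' in both")
print("conditions — the contrast, not the absolute score, is the reliable")
print("readout of mechanistic coupling.")
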