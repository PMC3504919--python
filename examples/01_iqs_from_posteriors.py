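"""Score one imputed SNP: observed agreement, chance agreement, IQS.

Builds the 3x3 imputed-vs-true cross-classification for a SNP imputed in ten
individuals and prints the agreement scores. Po is the (posterior-weighted)
fraction of correct genotypes; Pc is what agreement the margins alone would
produce; IQS = (Po - Pc) / (1 - Pc) is Cohen's kappa, the chance-corrected
quality of this imputation.
"""

import numpy as np

from iqspred import build_contingency, iqs

# ten individuals: truth codes 0=AA, 1=AB, 2=BB
truth = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2]
# imputation posteriors P(AA), P(AB), P(BB); one individual with true AB
# is confidently (and wrongly) called AA
posteriors = np.array(
    [[1, 0, 0]] * 4 + [[1, 0, 0]] + [[0, 1, 0]] * 3 + [[0, 0, 1]] * 2, float
)

table = build_contingency(truth, posteriors, mode="soft")
print("cross-classification (rows imputed, cols truth):")
print(table.n)

s = iqs(table)
print(f"Po  = {s.po:.4f}   (raw concordance: 9 of 10 correct)")
print(f"Pc  = {s.pc:.4f}   (agreement expected from the margins alone)")
print(f"IQS = {s.iqs:.5f}  (kappa: quality after removing chance agreement)")
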