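"""Volume agreement and group-comparison statistics on simulated series.

Shows the intraclass correlation coefficient (two-way, absolute
agreement, single measurement) with its qualitative category, why a
constant bias separates absolute agreement from consistency, and the
Benjamini-Hochberg step-up over a family of Wilcoxon tests.
"""

import numpy as np

from adiposeg.metrics import (benjamini_hochberg, icc_agreement,
                              wilcoxon_signed_rank)

rng = np.random.default_rng(3)
ref = rng.normal(3000, 400, 30)                # reference SAT volumes, mL
pred = ref + rng.normal(0, 40, 30)             # accurate method
biased = ref + 250                             # constant 250 mL bias

print("accurate method: ", icc_agreement(ref, pred))
print("biased, absolute:", icc_agreement(ref, biased, "ICC2"))
print("biased, consist.:", icc_agreement(ref, biased, "ICC3"))
print()

p_values = [wilcoxon_signed_rank(ref, ref + rng.normal(mu, 60, 30))
            for mu in (0.0, 0.0, 30.0, 60.0)]
reject, p_adj = benjamini_hochberg(p_values, q=0.05)
for p, pa, r in zip(p_values, p_adj, reject):
    print(f"raw p = {p:.4f}  adjusted = {pa:.4f}  reject: {bool(r)}")
print()
print("The constant-bias series keeps perfect consistency (ICC3 = 1) but")
print("loses absolute agreement; BH controls the false discovery rate at")
print("5% across the paired comparisons.")
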