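"""Crude vs cell-type-adjusted logistic association, Bonferroni control, and
the prevalence chi-square."""

import numpy as np
import pandas as pd

from ewasrf import bonferroni_alpha, crude_vs_adjusted, prevalence_chi2

# a CpG whose M-values are confounded by a cell proportion
rng = np.random.default_rng(4)
n = 400
gran = rng.beta(20, 15, n)                      # granulocyte proportion
y = rng.binomial(1, 1 / (1 + np.exp(-(3 * (gran - gran.mean())))))
m_values = pd.Series(2.0 * gran + rng.normal(0, 0.5, n))  # tracks cell type
cov = pd.DataFrame({"Gran": gran})

res = crude_vs_adjusted(y, m_values, cov, probe_id="cg_demo",
                        outcome_name="atopy")
print(f"crude beta {res.crude_beta:.3f} (p={res.crude_p:.2e}) -> "
      f"adjusted beta {res.adjusted_beta:.3f} (p={res.wald_p:.2e})")
print(f"percent change on adjustment: {res.pct_diff_beta:+.1f}%")
# A large %diff means the crude association was carried by cell composition,
# the confounding the stage-2 adjustment exists to remove.

print(f"\nBonferroni alpha for 62 tests: {bonferroni_alpha(62):.2E}")
stat, p = prevalence_chi2([[24, 77], [18, 25]])
print(f"high-IgE prevalence 2x2 (Yates): chi2={stat:.3f}, p={p:.3f}")
# 0.05/62 = 8.06E-04 is the per-test threshold; the chi-square compares
# high-IgE prevalence between two subsamples (24/101 vs 18/43 positive).
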