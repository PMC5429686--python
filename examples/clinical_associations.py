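"""Clinical association tests for subtype labelings.

Contingency tables of subtype vs a categorical characteristic get a
chi-square test (Yates-corrected only when the table is 2x2); ordinal and
continuous characteristics get Kruskal-Wallis; survival gets Kaplan-Meier
curves with a log-rank test.
"""

import numpy as np

import netstrat as ns

# a 3-subtype vs nodal-stage count table (counts from a published prostate cohort)
res = ns.chi_square([[145, 94, 107], [40, 26, 13]], yates_2x2=False)
print(f"3 subtypes vs N stage: chi2 = {res.statistic:.3f}, p = {res.p_value:.3g}")
res = ns.chi_square([[145, 40], [107, 13]], yates_2x2=True)
print(f"subtype 1 vs 3 (2x2, Yates): chi2 = {res.statistic:.3f}, p = {res.p_value:.3g}")

# full battery on a synthetic cohort whose grade/nodal/marker distributions
# shift by subtype while survival does not
labels = np.random.default_rng(0).integers(0, 3, size=200)
clinical = ns.generate_clinical(labels, ns.ClinicalEffectSpec(), seed=0)
battery = ns.association_battery(labels + 1, clinical)
print("\nassociation battery (p-values):")
for var, t in battery.items():
    print(f"  {var:>20}: {t.p_value:.3g}  [{t.method}]")
# grade, nodal status and the marker should associate; survival should not
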