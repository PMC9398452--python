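"""Exact small-sample tests used by the comparative analyses.

With eight genomes or two dozen TE families, asymptotic p-values are
unreliable; these tests enumerate the full null distribution.
"""

from tespread import stats as ts

# sign test: 18 of 23 TE families show a negative frequency-vs-magnitude
# regression coefficient -- more than chance under a fair-coin null
r = ts.binomial_sign_test(18, 23)
print(f"binomial sign test 18/23: p = {r.p_value:.4f}")
r = ts.binomial_sign_test(17, 23)
print(f"binomial sign test 17/23: p = {r.p_value:.4f}")

# Mann-Whitney comparing 4 yakuba-complex vs 4 melanogaster-complex
# genomes; complete separation of mean magnitudes
r = ts.mannwhitney_exact([2.1, 2.4, 2.6, 3.0], [1.2, 1.3, 1.5, 1.6])
print(f"Mann-Whitney, complete separation 4v4: U = {r.statistic:.0f}, p = {r.p_value:.3f}")

# the same comparison for mean extent gives U = 7, far from separation
r = ts.mannwhitney_exact([5.1, 5.9, 8.2, 9.4], [6.0, 6.5, 7.0, 9.0])
print(f"Mann-Whitney, extent comparison 4v4:   U = {r.statistic:.0f}, p = {r.p_value:.2f}")

# exact Spearman permutation p at n = 8
r = ts.spearman([1, 2, 3, 4, 5, 6, 7, 8], [2, 1, 4, 3, 6, 5, 8, 7])
print(f"Spearman n=8: rho = {r.statistic:.3f}, exact p = {r.p_value:.4f}")
print("(p-values enumerate all group assignments / rank permutations)")
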