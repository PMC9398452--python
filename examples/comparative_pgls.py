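"""Phylogenetic regression of TE abundance on mean epigenetic effect.

Fits TE abundance ~ species complex + mean magnitude across the eight
assayed genomes, by OLS with sequential ANOVA and by PGLS under Brownian
motion on the study tree, on data simulated with a known negative slope.
"""

import numpy as np
import pandas as pd

from tespread import stats as ts

tree = ts.parse_tree()  # the 8-tip strain phylogeny, arbitrary branch lengths
labels = list(ts.MELANOGASTER_COMPLEX + ts.YAKUBA_COMPLEX)
print(f"tree tips ({len(labels)}):", ", ".join(labels))

rng = np.random.default_rng(0)
complex_ind = np.array([0.0] * 4 + [1.0] * 4)       # melanogaster vs yakuba
magnitude = np.array([1.3, 1.5, 1.4, 1.2, 2.3, 2.6, 2.2, 2.5])
# abundance: complex effect + a -1500 TEs-per-unit-magnitude slope + noise
abundance = 2000 + 1500 * complex_ind - 1500 * magnitude + rng.normal(0, 120, 8)

X = pd.DataFrame({"complex": complex_ind, "magnitude": magnitude})
ols = ts.lm_sequential_anova(abundance, X)
pgls = ts.pgls_brownian(tree, abundance, X, labels)

print(f"\nOLS  magnitude coefficient: {ols['coef']['magnitude']:.0f}  "
      f"(sequential F = {ols['anova'].loc['magnitude', 'F']:.2f}, "
      f"p = {ols['anova'].loc['magnitude', 'p']:.3f})")
print(f"PGLS magnitude coefficient: {pgls['coef']['magnitude']:.0f}  "
      f"(sequential F = {pgls['anova'].loc['magnitude', 'F']:.2f}, "
      f"p = {pgls['anova'].loc['magnitude', 'p']:.3f})")
print("a negative coefficient means genomes with stronger TE-mediated")
print("H3K9me2 enrichment carry fewer euchromatic TEs, after removing the")
print("species-complex effect and (for PGLS) phylogenetic covariance.")
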