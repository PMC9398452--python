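"""Statistical layer: exact nonparametric tests, regressions, PGLS, screens.

The comparative analyses run at very small sample sizes (eight genomes, a
handful of TE families), where asymptotic rank-test p-values are
unreliable.  The tests here therefore use full enumeration of the null
distribution whenever the sample is small enough:

* Mann-Whitney U with the exact p from all C(n1+n2, n1) group assignments;
* the exact binomial sign test, two-sided by tail doubling at p0 = 1/2;
* Spearman rank correlation with the exact permutation p for n <= 9
  (untied data), otherwise the t-approximation;
* OLS with sequential (type-I) ANOVA F-tests, and its phylogenetic
  generalization (PGLS) under a Brownian-motion covariance derived from a
  Newick tree;
* logistic regression (maximum likelihood via statsmodels) with explicit
  separation / non-convergence flags;
* a gene-wise screen relating per-genome expression ranks to the mean
  magnitude of TE-mediated H3K9me2 enrichment, contrasting a candidate
  gene set (e.g. Su(var) genes) against the genomic background.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

#: 8-tip phylogeny of the assayed strains (two D. simulans and two
#: D. yakuba strains plus D. mauritiana, D. melanogaster, D. santomea and
#: D. teissieri); branch lengths are in arbitrary units.
MELANOGASTER_SUBGROUP_TREE = (
    "((((Dsim_strain1:0.1,Dsim_strain2:0.1):0.15, Dmau:0.25):3,Dmel:3.25):7.25,"
    " (((Dyak_strain1:0.1,Dyak_strain2:0.1):0.9,Dsan:1):1.75, Dtei:2.75):7.75);"
)

MELANOGASTER_COMPLEX = ("Dsim_strain1", "Dsim_strain2", "Dmau", "Dmel")
YAKUBA_COMPLEX = ("Dyak_strain1", "Dyak_strain2", "Dsan", "Dtei")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool = False
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# rank tests


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mannwhitney_exact(
    x: Sequence[float], y: Sequence[float], enumerate_max: int = 10
) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration for small groups.

    With both group sizes <= ``enumerate_max`` the null distribution of U
    is built from all C(n1+n2, n1) assignments of the pooled observations
    and p = 2 * P(U <= min(U, n1*n2 - U)), capped at 1.  Larger samples use
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    if n1 <= enumerate_max and n2 <= enumerate_max:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # average ranks handle ties
        offset = n1 * (n1 + 1) / 2
        u_min = min(u_obs, n1 * n2 - u_obs)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if u <= u_min + 1e-9:
                count += 1
        p = min(1.0, 2 * count / total)
        return TestResult(u_obs, p, "Mann-Whitney U (exact enumeration)", True, (n1, n2))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(u_obs, float(res.pvalue), "Mann-Whitney U (normal approximation)", False, (n1, n2))


def binomial_sign_test(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test by tail doubling.

    p = 2 * min(P(X <= k), P(X >= k)) under Binomial(n, p0), capped at 1.
    """
    if not 0 <= k <= n:
        raise ValueError("k must be between 0 and n")
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    p = min(1.0, 2 * min(lower, upper))
    return TestResult(float(k), float(p), "exact binomial sign test", True, (n,))


def spearman(
    x: Sequence[float], y: Sequence[float], exact_n_max: int = 9
) -> TestResult:
    """Spearman rank correlation with exact permutation p for small n.

    rho uses average ranks; for n <= ``exact_n_max`` with no ties the
    two-sided p enumerates all n! permutations of one variable's ranks,
    otherwise the t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need at least three paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tied = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_n_max and not tied:
        # untied: rho = 1 - 6*S/(n(n^2-1)), S = sum of squared rank diffs
        denom = n * (n * n - 1)
        target = abs(rho)
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            s = float(np.sum((rx - np.asarray(perm)) ** 2))
            r = 1 - 6 * s / denom
            if abs(r) >= target - 1e-12:
                count += 1
        return TestResult(rho, count / total, "Spearman (exact permutation)", True, (n,))
    if abs(rho) >= 1:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p = 2 * sps.t.sf(abs(t), n - 2)
    return TestResult(rho, float(p), "Spearman (t approximation)", False, (n,))


# ---------------------------------------------------------------------------
# regression


def logistic_fit(
    response: Sequence[int], predictors: pd.DataFrame, min_obs: int = 10
) -> dict:
    """Maximum-likelihood logistic regression with diagnostic flags.

    ``response`` is 0/1 (e.g. low/high population frequency class).
    Returns {'coef': Series incl. intercept, 'zvalues': Series,
    'converged': bool, 'separation': bool, 'n': int}.  Separation or
    non-convergence is flagged rather than silently reported.
    """
    y = np.asarray(response, dtype=float)
    X = sm.add_constant(pd.DataFrame(predictors).astype(float), has_constant="add")
    if len(y) < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("constant response: logistic regression undefined")
    separation = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", True))
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 1e3):
            separation = True
    zvals = fit.params / fit.bse if np.all(np.isfinite(fit.bse)) else fit.params * np.nan
    return {
        "coef": pd.Series(fit.params, index=X.columns),
        "zvalues": pd.Series(zvals, index=X.columns),
        "converged": converged,
        "separation": separation,
        "n": len(y),
    }


def _sequential_anova(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Type-I F per predictor column, in the given order (intercept first)."""
    n, p = len(y), X.shape[1]
    if n < p + 2:
        raise ValueError("too few observations for the design")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design")
    rss = []
    for k in range(1, design.shape[1] + 1):
        _, res, *_ = np.linalg.lstsq(design[:, :k], y, rcond=None)
        fit = design[:, :k] @ np.linalg.lstsq(design[:, :k], y, rcond=None)[0]
        rss.append(float(((y - fit) ** 2).sum()))
    df_resid = n - design.shape[1]
    mse = rss[-1] / df_resid
    rows = []
    for i, name in enumerate(X.columns):
        ss = rss[i] - rss[i + 1]
        f = ss / mse if mse > 0 else np.inf
        pval = float(sps.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
        rows.append({"term": name, "ss": ss, "df": 1, "F": f, "p": pval})
    return pd.DataFrame(rows).set_index("term")


def lm_sequential_anova(
    response: Sequence[float], predictors: pd.DataFrame
) -> dict:
    """OLS with sequential (type-I) ANOVA F-tests in predictor order.

    Returns {'coef': Series (intercept + predictors), 'anova': DataFrame
    with per-term sequential F and p, 'df_resid': int}.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    anova = _sequential_anova(y, X)
    design = np.column_stack([np.ones(len(y)), X.to_numpy()])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef = pd.Series(beta, index=["const", *X.columns])
    return {"coef": coef, "anova": anova, "df_resid": len(y) - design.shape[1]}


def brownian_covariance(
    tree: dendropy.Tree, labels: Sequence[str]
) -> np.ndarray:
    """Brownian-motion tip covariance: shared root-to-MRCA branch length."""
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [l for l in labels if l not in taxa]
    if missing:
        raise ValueError(f"tip labels absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    root_dist = {
        leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    }
    k = len(labels)
    C = np.zeros((k, k))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                C[i, j] = root_dist[a]
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                C[i, j] = (root_dist[a] + root_dist[b] - d) / 2
    return C


def parse_tree(newick: str = MELANOGASTER_SUBGROUP_TREE) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def pgls_brownian(
    tree: dendropy.Tree,
    response: Sequence[float],
    predictors: pd.DataFrame,
    labels: Sequence[str],
) -> dict:
    """Generalized least squares under a Brownian tree covariance.

    Rows of ``response``/``predictors`` correspond to ``labels`` (tip
    names).  Coefficients and sequential F-tests are computed on the
    GLS-whitened model; with an identity-proportional covariance (a star
    tree with equal tip branches) this reduces exactly to OLS.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    C = brownian_covariance(tree, labels)
    L = np.linalg.cholesky(C)
    wy = np.linalg.solve(L, y)
    design = np.column_stack([np.ones(len(y)), X.to_numpy()])
    wdesign = np.linalg.solve(L, design)
    beta, *_ = np.linalg.lstsq(wdesign, wy, rcond=None)
    resid = wy - wdesign @ beta
    df_resid = len(y) - design.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    cov_beta = sigma2 * np.linalg.inv(wdesign.T @ wdesign)
    se = np.sqrt(np.diag(cov_beta))
    # sequential F on the whitened model (whitened intercept included)
    rss = []
    for k in range(1, wdesign.shape[1] + 1):
        b = np.linalg.lstsq(wdesign[:, :k], wy, rcond=None)[0]
        r = wy - wdesign[:, :k] @ b
        rss.append(float(r @ r))
    mse = rss[-1] / df_resid
    rows = []
    for i, name in enumerate(X.columns):
        ss = rss[i] - rss[i + 1]
        f = ss / mse if mse > 0 else np.inf
        pval = float(sps.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
        rows.append({"term": name, "ss": ss, "df": 1, "F": f, "p": pval})
    coef = pd.Series(beta, index=["const", *X.columns])
    return {
        "coef": coef,
        "se": pd.Series(se, index=["const", *X.columns]),
        "anova": pd.DataFrame(rows).set_index("term"),
        "df_resid": df_resid,
    }


# ---------------------------------------------------------------------------
# gene-wise screen


def suvar_screen(
    expression_ranks: pd.DataFrame,
    genome_effect: pd.Series,
    suvar_list: Sequence[str],
    complex_labels: Mapping[str, str],
) -> dict:
    """Gene-wise association of expression rank with genome-level TE effects.

    ``expression_ranks`` is gene x genome (per-genome expression rank,
    1 = highest expressed), ``genome_effect`` the mean magnitude of
    TE-mediated H3K9me2 enrichment per genome, ``complex_labels`` maps
    genome -> species complex.  Per gene: the Spearman rho between its
    expression rank and the genome effect, and the expression coefficient
    from (genome effect ~ gene expression rank + species complex).  Genes
    constant across genomes are excluded.  Candidate genes (``suvar_list``)
    are compared with all other genes by Mann-Whitney and asymptotic
    Kolmogorov-Smirnov tests on both metrics; genes in the lowest 5%/10%
    (most negative association) are flagged.
    """
    genomes = [g for g in expression_ranks.columns if g in genome_effect.index]
    if len(genomes) < 4:
        raise ValueError("at least four genomes are required for the screen")
    if len(set(complex_labels[g] for g in genomes)) > 1:
        counts = pd.Series([complex_labels[g] for g in genomes]).value_counts()
        if (counts < 2).any():
            raise ValueError("each species complex needs at least two genomes")
    eff = genome_effect[genomes].to_numpy(dtype=float)
    complex_ind = np.array(
        [1.0 if complex_labels[g] == sorted(set(complex_labels.values()))[-1] else 0.0 for g in genomes]
    )
    rows = []
    for gene, ranks in expression_ranks[genomes].iterrows():
        r = ranks.to_numpy(dtype=float)
        if np.isnan(r).any() or len(np.unique(r)) < 2:
            continue
        rho = spearman(r, eff, exact_n_max=0).statistic
        X = pd.DataFrame({"expression": r, "complex": complex_ind})
        try:
            fit = lm_sequential_anova(eff, X)
            coef = float(fit["coef"]["expression"])
        except ValueError:
            continue
        rows.append({"gene_id": gene, "rho": rho, "coef": coef})
    table = pd.DataFrame(rows).set_index("gene_id")
    for metric in ("rho", "coef"):
        q05 = table[metric].quantile(0.05)
        q10 = table[metric].quantile(0.10)
        table[f"{metric}_top5pct"] = table[metric] <= q05
        table[f"{metric}_top10pct"] = table[metric] <= q10
    in_set = table.index.isin(set(suvar_list))
    comparisons = {}
    for metric in ("rho", "coef"):
        a = table.loc[in_set, metric].to_numpy()
        b = table.loc[~in_set, metric].to_numpy()
        mwu = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        ks = sps.ks_2samp(a, b, method="asymp")
        comparisons[metric] = {
            "mannwhitney_p": float(mwu.pvalue),
            "ks_p": float(ks.pvalue),
        }
    return {"table": table, "comparisons": comparisons}
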