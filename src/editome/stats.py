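"""Differential-editing and summary statistics.

The differential test is a binomial GLM (logit link) with the group factor as
the full model and an intercept-only null, compared by likelihood ratio
against a chi-square with (groups - 1) degrees of freedom. Because the group
factor saturates the group means, both fits have closed-form maximum
likelihood solutions (pooled and per-group edited fractions), which this
module uses directly. Multiplicity is controlled by Benjamini-Hochberg;
editing-expression association uses mid-rank Spearman correlation; sample
structure is summarized by PCA of the (mean-imputed, site-centered) editing
matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import EditingMatrix


@dataclass
class DifferentialResult:
    site: str
    lrt_statistic: float
    df: int
    p_value: float
    q_value: float | None
    group_means: dict[str, float]
    skipped: str | None = None


def _binom_ll(edited: np.ndarray, total: np.ndarray, p: float) -> float:
    """Binomial log-likelihood up to the combinatorial constant."""
    ll = 0.0
    for e, t in zip(edited, total):
        if p > 0 and e > 0:
            ll += e * math.log(p)
        elif e > 0:
            return -math.inf
        if p < 1 and t - e > 0:
            ll += (t - e) * math.log(1 - p)
        elif t - e > 0:
            return -math.inf
    return ll


def lrt_differential(edited, total, groups, min_depth: int = 10,
                     site: str = "") -> DifferentialResult:
    """Likelihood-ratio test of per-group vs pooled binomial editing rates.

    Samples with depth below ``min_depth`` are excluded; groups left with no
    covered sample are dropped and the degrees of freedom adjusted. With
    fewer than two covered groups the test is skipped.
    """
    edited = np.asarray(edited, dtype=float)
    total = np.asarray(total, dtype=float)
    groups = np.asarray(groups)
    covered = total >= min_depth
    labels = [g for g in dict.fromkeys(groups) if covered[groups == g].any()]
    group_means = {}
    for g in labels:
        m = covered & (groups == g)
        group_means[g] = float(edited[m].sum() / total[m].sum())
    if len(labels) < 2:
        return DifferentialResult(site, 0.0, 0, float("nan"), None, group_means,
                                  skipped="fewer than two covered groups")
    m_all = covered & np.isin(groups, labels)
    p_null = edited[m_all].sum() / total[m_all].sum()
    ll_null = _binom_ll(edited[m_all], total[m_all], p_null)
    ll_full = 0.0
    for g in labels:
        m = covered & (groups == g)
        ll_full += _binom_ll(edited[m], total[m], group_means[g])
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    df = len(labels) - 1
    p = float(sps.chi2.sf(stat, df))
    return DifferentialResult(site, stat, df, p, None, group_means)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate and do not count
    toward the number of tests."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


def spearman(x, y) -> tuple[float, float]:
    """Mid-rank Spearman correlation with an exact permutation p for n <= 9
    and the t approximation above that. Returns (nan, nan) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact permutation distribution of |rho| under exchangeability
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho, min(1.0, p)


@dataclass
class CorrelationResult:
    site: str
    gene_id: str
    rho: float
    p_value: float
    n_pairs: int
    significant: bool


def editing_expression_correlation(matrix: EditingMatrix, tpm: pd.DataFrame,
                                   site_gene: dict[str, str], min_pairs: int = 5,
                                   alpha: float = 0.05) -> list[CorrelationResult]:
    """Spearman association of each site's level with its host gene's TPM."""
    out = []
    samples = list(matrix.levels.columns)
    for site, gene in site_gene.items():
        if gene not in tpm.index or site not in matrix.levels.index:
            continue
        lv = matrix.levels.loc[site, samples].to_numpy(dtype=float)
        ex = tpm.loc[gene, samples].to_numpy(dtype=float)
        ok = ~np.isnan(lv)
        if ok.sum() < min_pairs:
            continue
        rho, p = spearman(lv[ok], ex[ok])
        if math.isnan(rho):
            continue
        out.append(CorrelationResult(site, gene, rho, p, int(ok.sum()), p < alpha))
    return out


def overall_editing_level(matrix: EditingMatrix) -> pd.DataFrame:
    """Per-sample editome summaries: unweighted mean of defined site levels,
    and the read-weighted pooled fraction (sum edited / sum total)."""
    mean_lv = matrix.levels.mean(axis=0, skipna=True)
    if matrix.edited is not None and matrix.total is not None:
        defined = matrix.mask
        ed = (matrix.edited * defined).sum(axis=0)
        tot = (matrix.total * defined).sum(axis=0)
        weighted = ed / tot.where(tot > 0, np.nan)
    else:
        weighted = mean_lv
    return pd.DataFrame({"mean_level": mean_lv, "weighted_level": weighted})


def students_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test on expression values; Welch form by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # sites x components
    variance_fraction: np.ndarray


def pca_editing(matrix: EditingMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the editing matrix via SVD.

    Masked cells are imputed with the site mean; sites with no defined level
    anywhere are dropped; each site is then centered. Scores are per-sample
    coordinates; variance fractions are relative to the total variance.
    """
    lv = matrix.levels.copy()
    lv = lv.loc[lv.notna().any(axis=1)]
    if lv.shape[0] < 2 or lv.shape[1] < 2:
        raise ValueError("need at least two sites and two samples")
    filled = lv.apply(lambda row: row.fillna(row.mean()), axis=1)
    X = filled.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(X.shape)
    k = min(k, s.size)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = (Vt[:k].T * s[:k])
    return PCAResult(
        pd.DataFrame(scores, index=lv.columns,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        pd.DataFrame(U[:, :k], index=lv.index,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        frac[:k],
    )


@dataclass
class OverlapReport:
    region_counts: dict[frozenset, int]   # exact-membership regions
    unique: dict[str, list]
    shared_at_least: dict[int, int]

    def count(self, *names: str) -> int:
        """Elements belonging to exactly this combination of sets."""
        return self.region_counts.get(frozenset(names), 0)


def overlap_sets(sets: dict[str, set]) -> OverlapReport:
    """Venn-style membership summary over up to four sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if len(sets) > 4:
        raise ValueError("at most four sets supported")
    names = list(sets)
    universe = set().union(*sets.values())
    region_counts: dict[frozenset, int] = {}
    for el in universe:
        member = frozenset(n for n in names if el in sets[n])
        region_counts[member] = region_counts.get(member, 0) + 1
    unique = {n: sorted(el for el in sets[n]
                        if all(el not in sets[m] for m in names if m != n))
              for n in names}
    shared = {}
    for k in range(1, len(names) + 1):
        shared[k] = sum(1 for el in universe
                        if sum(el in sets[n] for n in names) >= k)
    return OverlapReport(region_counts, unique, shared)
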