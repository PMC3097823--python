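"""Statistical tests used by model selection and network analysis.

The Wilcoxon rank-sum test compares ancestral with contemporary inventory-size
distributions; the one-sided two-sample Kolmogorov–Smirnov test compares
within-group with between-group lateral-edge weights; the G-test compares
borrowing frequencies between character classes (e.g. nouns vs verbs).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

__all__ = ["wilcoxon_rank_sum", "ks_one_sided", "g_test_2x2", "iqr_fraction"]

#: Pooled sample size up to which the exact rank-sum null is enumerated.
EXACT_LIMIT = 25


def _clean(sample, name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    return arr


def wilcoxon_rank_sum(sample_a, sample_b, sided: str = "two") -> float:
    """Wilcoxon/Mann–Whitney rank-sum p-value.

    Exact enumeration of the null when the pooled sample has at most
    ``EXACT_LIMIT`` observations and no ties; otherwise the tie-corrected
    normal approximation (no continuity correction, so identical samples give
    p = 1 exactly).
    """
    a = _clean(sample_a, "first")
    b = _clean(sample_b, "second")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[sided]
    pooled = np.concatenate([a, b])
    exact = pooled.size <= EXACT_LIMIT and np.unique(pooled).size == pooled.size
    if exact:
        res = _sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        res = _sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=False
        )
    return float(min(res.pvalue, 1.0))


def ks_one_sided(sample_a, sample_b) -> tuple[float, float]:
    """One-sided two-sample KS test of H0: ``a`` stochastically <= ``b``.

    Returns ``(d_plus, p)`` with ``d_plus = sup_x (ECDF_b(x) - ECDF_a(x))``,
    large when ``a`` tends to exceed ``b``; the p-value is the asymptotic
    one-sided tail ``exp(-2 m n d^2 / (m + n))``.
    """
    a = _clean(sample_a, "first")
    b = _clean(sample_b, "second")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    d_plus = float(max(np.max(cdf_b - cdf_a), 0.0))
    m, n = a.size, b.size
    p = float(np.exp(-2.0 * m * n * d_plus**2 / (m + n)))
    return d_plus, min(p, 1.0)


def g_test_2x2(table) -> tuple[float, float]:
    """Likelihood-ratio (G) test of independence for a 2x2 count table.

    ``G = 2 * sum O * ln(O / E)`` with expectations from the margins; the
    p-value is the chi-square upper tail with one degree of freedom.  Cells
    with zero observed count contribute zero to G.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("g_test_2x2 needs a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    p = float(_sps.chi2.sf(g, df=1))
    return g, p


def iqr_fraction(ancestral_sizes, contemporary_sizes) -> float:
    """(median(ancestral) - median(contemporary)) / IQR(contemporary).

    Quartiles use linear interpolation.  Negative values mean ancestral
    inventories are smaller than contemporary ones.
    """
    anc = _clean(ancestral_sizes, "ancestral")
    cont = _clean(contemporary_sizes, "contemporary")
    q1, q3 = np.percentile(cont, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("contemporary IQR is zero; fraction undefined")
    return float((np.median(anc) - np.median(cont)) / iqr)
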