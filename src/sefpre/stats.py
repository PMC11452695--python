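"""Shared statistical primitives for the pipeline.

The centerpiece is a vectorized type-II two-way ANOVA that evaluates one
fixed trial design against many response columns at once (the sliding
windows of a neuron share the same trials, so the projection matrices are
computed once per neuron and applied to the whole trial x window matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pingouin
from scipy import stats as sps


@dataclass
class StatTestResult:
    """One test statistic with dof, p-value and an effect size."""

    name: str
    statistic: float
    dof: float | tuple[float, float] | None
    p: float
    effect_size: float | None = None
    effect_name: str | None = None


# ---------------------------------------------------------------------------
# ANOVA


def _rss(Q: np.ndarray, Y: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y for an orthonormal basis Q."""
    proj = Q.T @ Y
    return np.maximum(total - np.einsum("ij,ij->j", proj, proj), 0.0)


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((codes.size, n_levels - 1))
    for lv in range(1, n_levels):
        out[codes == lv, lv - 1] = 1.0
    return out


def two_way_anova_matrix(Y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Type-II two-way ANOVA of each column of ``Y`` on factors ``a`` x ``b``.

    Parameters
    ----------
    Y : (n_trials, n_windows) response matrix.
    a, b : length-n trial factor labels (any hashable values).

    Returns
    -------
    dict with per-window arrays ``F_a, p_a, F_b, p_b, F_int, p_int`` and a
    boolean ``valid`` mask.  Windows with zero residual variance (e.g. all
    responses identical) are marked invalid with p = NaN.

    Raises
    ------
    ValueError if any design cell is empty or the error dof is <= 0.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    a_codes, a_levels = pd_factorize(a)
    b_codes, b_levels = pd_factorize(b)
    na, nb = len(a_levels), len(b_levels)
    n = Y.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each factor needs >= 2 observed levels")
    cells = np.zeros((na, nb), dtype=int)
    np.add.at(cells, (a_codes, b_codes), 1)
    if (cells == 0).any():
        raise ValueError("empty design cell in two-way ANOVA")
    df_err = n - na * nb
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")

    one = np.ones((n, 1))
    A = _dummy(a_codes, na)
    B = _dummy(b_codes, nb)
    AB = np.einsum("ni,nj->nij", A, B).reshape(n, -1)

    total = np.einsum("ij,ij->j", Y, Y)
    q = lambda X: np.linalg.qr(X, mode="reduced")[0]
    rss_a = _rss(q(np.hstack([one, A])), Y, total)
    rss_b = _rss(q(np.hstack([one, B])), Y, total)
    rss_add = _rss(q(np.hstack([one, A, B])), Y, total)
    rss_full = _rss(q(np.hstack([one, A, B, AB])), Y, total)

    df_a, df_b, df_int = na - 1, nb - 1, (na - 1) * (nb - 1)
    ss_a = np.maximum(rss_b - rss_add, 0.0)
    ss_b = np.maximum(rss_a - rss_add, 0.0)
    ss_int = np.maximum(rss_add - rss_full, 0.0)
    mse = rss_full / df_err

    # a window is degenerate when the residual variance is (numerically) 0
    scale = np.maximum(total / n, 1.0)
    valid = mse > 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F_a = np.where(valid, (ss_a / df_a) / mse, np.nan)
        F_b = np.where(valid, (ss_b / df_b) / mse, np.nan)
        F_int = np.where(valid, (ss_int / df_int) / mse, np.nan)
    p_a = np.where(valid, sps.f.sf(F_a, df_a, df_err), np.nan)
    p_b = np.where(valid, sps.f.sf(F_b, df_b, df_err), np.nan)
    p_int = np.where(valid, sps.f.sf(F_int, df_int, df_err), np.nan)
    return {
        "F_a": F_a, "p_a": p_a, "F_b": F_b, "p_b": p_b,
        "F_int": F_int, "p_int": p_int, "valid": valid,
        "df": (df_a, df_b, df_int, df_err),
        "ss": (ss_a, ss_b, ss_int, rss_full),
    }


def pd_factorize(labels) -> tuple[np.ndarray, list]:
    """Stable factorization of a label sequence into integer codes."""
    labels = list(labels)
    levels = sorted(set(labels), key=lambda v: (str(type(v)), v))
    index = {lv: i for i, lv in enumerate(levels)}
    return np.array([index[lv] for lv in labels], dtype=int), levels


def one_way_anova(groups: list[np.ndarray]) -> StatTestResult:
    """One-way fixed-effects ANOVA across groups, with eta-squared."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    F, p = sps.f_oneway(*groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    dof = (len(groups) - 1, allv.size - len(groups))
    return StatTestResult("one-way ANOVA", float(F), dof, float(p),
                          eta2, "eta_squared")


# ---------------------------------------------------------------------------
# ROC / AUC


def auc(a, b) -> float:
    """Mann-Whitney probability that a draw from ``a`` exceeds one from ``b``.

    Ties count one half; 1 means every value of ``a`` beats every value of
    ``b``, 0.5 means the distributions are indistinguishable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("auc requires two non-empty samples")
    ranks = sps.rankdata(np.concatenate([a, b]))
    ra = ranks[: a.size].sum()
    return float((ra - a.size * (a.size + 1) / 2) / (a.size * b.size))


def auc_matrix(Y: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Columnwise AUC of rows ``mask_a`` vs the rest of ``Y`` (ties = 1/2)."""
    Y = np.asarray(Y, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    na = int(mask_a.sum())
    nb = Y.shape[0] - na
    if na == 0 or nb == 0:
        raise ValueError("auc requires two non-empty samples")
    ranks = sps.rankdata(Y, axis=0)
    ra = ranks[mask_a].sum(axis=0)
    return (ra - na * (na + 1) / 2) / (na * nb)


# ---------------------------------------------------------------------------
# Multiple comparisons


def fdr_bh(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``alpha``.

    NaN p-values are never rejected and do not count toward the number of
    tests.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    finite = ~np.isnan(p)
    m = int(finite.sum())
    reject = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return reject
    idx = np.where(finite)[0]
    order = idx[np.argsort(p[idx])]
    sorted_p = p[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    below = np.where(sorted_p <= thresh)[0]
    if below.size:
        k = below[-1]
        reject[order[: k + 1]] = True
    return reject


def binomial_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p against proportion one half; p=1 if n=0."""
    if n == 0:
        return 1.0
    return float(sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Effect sizes


def cohen_d_independent(a, b) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def cohen_d_paired(diff) -> float:
    """Cohen's d for paired data: mean difference over SD of differences."""
    diff = np.asarray(diff, dtype=float)
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(diff.mean() / sd)


# ---------------------------------------------------------------------------
# Circular statistics


def rayleigh_uniformity(angles_deg) -> StatTestResult:
    """Rayleigh test of circular uniformity on direction angles (degrees)."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 3:
        raise ValueError("Rayleigh test needs at least 3 directions")
    z, p = pingouin.circ_rayleigh(np.deg2rad(angles))
    return StatTestResult("Rayleigh", float(z), None, float(p))


def wilcoxon_one_sided(x, y) -> float:
    """One-sided signed-rank p for median(x - y) > 0; all-zero diffs -> 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == y):
        return 1.0
    return float(sps.wilcoxon(x, y, alternative="greater",
                              zero_method="wilcox").pvalue)
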