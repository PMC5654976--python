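"""Diagnostic-evaluation statistics for paired rim-area parameters.

AUC (Mann-Whitney estimator), the DeLong structural-components test for
paired AUCs, unnormalized partial AUC over a specificity range with a
paired stratified bootstrap comparison, sensitivity at fixed specificity,
Spearman correlation with a bootstrap comparison of two correlations, and
Benjamini-Hochberg step-up adjustment.

Rim areas are smaller in disease, so the default direction is
``lower_is_case``. Partial AUC is reported unnormalized over specificity
[0.9, 1.0] (maximum 0.1). Bootstraps are stratified by class and preserve
the per-eye pairing of the two parameters; resampling is per eye, not per
patient (no clustering correction).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "auc",
    "delong_paired_test",
    "partial_auc",
    "bootstrap_pauc_test",
    "sensitivity_at_specificity",
    "spearman_rho",
    "compare_correlations_bootstrap",
    "benjamini_hochberg",
]

LOWER_IS_CASE = "lower_is_case"
HIGHER_IS_CASE = "higher_is_case"


def _split(scores, labels, direction):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if s.shape[0] != y.shape[0]:
        raise InputError("scores and labels must have equal length")
    case = y == "case" if y.dtype.kind in "US" else y.astype(bool)
    if not case.any() or case.all():
        raise InputError("need at least one case and one control")
    if direction == LOWER_IS_CASE:
        s = -s
    elif direction != HIGHER_IS_CASE:
        raise InputError(f"unknown direction {direction!r}")
    return s[case], s[~case]


def auc(scores, labels, direction: str = LOWER_IS_CASE) -> float:
    """Mann-Whitney AUC: fraction of correctly ordered case/control pairs,
    ties counted 1/2."""
    cases, controls = _split(scores, labels, direction)
    return _auc_mw(cases, controls)


def _auc_mw(cases: np.ndarray, controls: np.ndarray) -> float:
    n1, n0 = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components via midranks.

    V10[i] = fraction of controls scored below case i (ties 1/2), and the
    control-side analogue V01.
    """
    m, n = len(cases), len(controls)
    allv = np.concatenate([cases, controls])
    rk_all = stats.rankdata(allv)
    v10 = (rk_all[:m] - stats.rankdata(cases)) / n
    v01 = 1.0 - (rk_all[m:] - stats.rankdata(controls)) / m
    return v10, v01


def delong_paired_test(scores1, scores2, labels, direction: str = LOWER_IS_CASE):
    """DeLong (1988) test for two correlated AUCs measured on the same eyes.

    Returns (auc1, auc2, z, p) with a two-sided normal p-value. When the
    paired difference has zero variance (e.g. identical parameters), the
    defined result is z = 0, p = 1.
    """
    c1, g1 = _split(scores1, labels, direction)
    c2, g2 = _split(scores2, labels, direction)
    if len(c1) != len(c2) or len(g1) != len(g2):
        raise InputError("both parameters must cover the same eyes")
    a1, a2 = _auc_mw(c1, g1), _auc_mw(c2, g2)
    v10 = np.vstack(( _placements(c1, g1)[0], _placements(c2, g2)[0]))
    v01 = np.vstack(( _placements(c1, g1)[1], _placements(c2, g2)[1]))
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var = s[0, 0] + s[1, 1] - 2.0 * s[0, 1]
    if var <= 0:
        return a1, a2, 0.0, 1.0
    z = (a1 - a2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return a1, a2, float(z), float(min(p, 1.0))


def _roc_points(cases: np.ndarray, controls: np.ndarray):
    """Empirical ROC as (fpr, tpr) arrays from (0,0) to (1,1), one point
    per distinct threshold (staircase convention; tied scores produce one
    combined step)."""
    scores = np.concatenate([cases, controls])
    is_case = np.concatenate(
        [np.ones(len(cases), bool), np.zeros(len(controls), bool)]
    )
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    is_case = is_case[order]
    tp = np.cumsum(is_case)
    fp = np.cumsum(~is_case)
    distinct = np.flatnonzero(np.diff(scores) != 0)
    idx = np.concatenate([distinct, [len(scores) - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / len(cases)])
    fpr = np.concatenate([[0.0], fp[idx] / len(controls)])
    return fpr, tpr


def partial_auc(
    scores, labels, spec_lo: float = 0.9, spec_hi: float = 1.0,
    direction: str = LOWER_IS_CASE,
) -> float:
    """Unnormalized partial AUC over specificity in [spec_lo, spec_hi].

    Trapezoidal integration over the empirical ROC, with linear
    interpolation of the curve at the range endpoints; maximum value is
    spec_hi - spec_lo (0.1 for the default range).
    """
    if not (0.0 <= spec_lo < spec_hi <= 1.0):
        raise InputError("need 0 <= spec_lo < spec_hi <= 1")
    cases, controls = _split(scores, labels, direction)
    fpr, tpr = _roc_points(cases, controls)
    return _pauc_from_roc(fpr, tpr, 1.0 - spec_hi, 1.0 - spec_lo)


def _pauc_from_roc(fpr, tpr, f_lo, f_hi) -> float:
    # integrate the ROC polyline segment-wise, clipping each segment to the
    # FPR window; vertical segments (tied thresholds) have zero width and
    # the window endpoints are linearly interpolated along their segment
    x0, x1 = fpr[:-1], fpr[1:]
    y0, y1 = tpr[:-1], tpr[1:]
    lo = np.maximum(x0, f_lo)
    hi = np.minimum(x1, f_hi)
    keep = hi > lo
    if not np.any(keep):
        return 0.0
    x0, x1, y0, y1 = x0[keep], x1[keep], y0[keep], y1[keep]
    lo, hi = lo[keep], hi[keep]
    slope = (y1 - y0) / (x1 - x0)
    y_lo = y0 + slope * (lo - x0)
    y_hi = y0 + slope * (hi - x0)
    return float(np.sum(0.5 * (y_lo + y_hi) * (hi - lo)))


def bootstrap_pauc_test(
    scores1, scores2, labels, B: int = 1000, seed: int = 0,
    spec_lo: float = 0.9, spec_hi: float = 1.0, direction: str = LOWER_IS_CASE,
) -> float:
    """Paired stratified bootstrap comparison of two partial AUCs.

    Cases and controls are resampled separately, keeping the pairing of
    the two parameters within each eye. The two-sided p-value is a normal
    approximation using the bootstrap standard error of pAUC1 - pAUC2
    (p = 1 when the bootstrap difference is degenerate, e.g. identical
    parameters).
    """
    if B < 100:
        raise InputError("need B >= 100 bootstrap resamples")
    c1, g1 = _split(scores1, labels, direction)
    c2, g2 = _split(scores2, labels, direction)
    if len(c1) != len(c2) or len(g1) != len(g2):
        raise InputError("both parameters must cover the same eyes")
    f_lo, f_hi = 1.0 - spec_hi, 1.0 - spec_lo
    d_obs = _pauc_from_roc(*_roc_points(c1, g1), f_lo, f_hi) - _pauc_from_roc(
        *_roc_points(c2, g2), f_lo, f_hi
    )
    rng = np.random.default_rng(seed)
    m, n = len(c1), len(g1)
    diffs = np.empty(B)
    for bi in range(B):
        ic = rng.integers(0, m, m)
        ig = rng.integers(0, n, n)
        diffs[bi] = _pauc_from_roc(*_roc_points(c1[ic], g1[ig]), f_lo, f_hi) - \
            _pauc_from_roc(*_roc_points(c2[ic], g2[ig]), f_lo, f_hi)
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        return 1.0
    z = d_obs / sd
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def sensitivity_at_specificity(
    scores, labels, spec: float = 0.95, direction: str = LOWER_IS_CASE
) -> float:
    """Sensitivity at the most permissive threshold still achieving
    specificity >= spec (conservative step-function convention; no
    interpolation)."""
    if not (0.0 < spec <= 1.0):
        raise InputError("specificity must be in (0, 1]")
    cases, controls = _split(scores, labels, direction)
    fpr, tpr = _roc_points(cases, controls)
    ok = fpr <= (1.0 - spec) + 1e-12
    return float(tpr[ok].max())


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midrank ties; needs n >= 3 and
    non-constant inputs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[0] != y.shape[0] or x.shape[0] < 3:
        raise InputError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("Spearman rho undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def compare_correlations_bootstrap(x, y1, y2, B: int = 1000, seed: int = 0) -> float:
    """Two-sided bootstrap p-value for rho(x, y1) - rho(x, y2).

    Triples are resampled with replacement; normal approximation on the
    bootstrap standard error of the difference.
    """
    x = np.asarray(x, float)
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n = x.shape[0]
    if y1.shape[0] != n or y2.shape[0] != n:
        raise InputError("x, y1, y2 must be paired")
    if n < 10:
        raise InputError("need n >= 10 paired triples for a stable bootstrap")
    if B < 100:
        raise InputError("need B >= 100 bootstrap resamples")
    d_obs = spearman_rho(x, y1) - spearman_rho(x, y2)
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    for bi in range(B):
        while True:
            idx = rng.integers(0, n, n)
            xb = x[idx]
            if np.ptp(xb) > 0 and np.ptp(y1[idx]) > 0 and np.ptp(y2[idx]) > 0:
                break
        diffs[bi] = spearman_rho(xb, y1[idx]) - spearman_rho(xb, y2[idx])
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        return 1.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(d_obs / sd))))


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values in input order, significance threshold):
    the threshold is the largest raw p with p_(k) <= (k/m) * alpha, or 0
    if none qualifies.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    m = p.size
    order = np.sort(p)
    ok = order <= (np.arange(1, m + 1) / m) * alpha
    threshold = float(order[ok].max()) if ok.any() else 0.0
    return adjusted, threshold
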