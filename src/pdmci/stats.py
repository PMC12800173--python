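"""Shared statistical machinery.

Effect sizes (Cohen's d, standardised point-biserial r, phi / Cramér's V),
normality-routed two-group tests, Benjamini–Hochberg adjustment, and the
bootstrap procedure that compares the discriminative strength of two
diagnostic procedures by resampling the effect-size difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


# --- effect sizes ----------------------------------------------------------

def cohens_d(a, b) -> float:
    """Standardised mean difference with the pooled-SD denominator.

    Pooled variance weights each group's variance by (n - 1). Raises on a
    zero pooled SD (no within-group spread), where d is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled SD: Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _cohens_d_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Cohen's d for bootstrap matrices (n_boot x n)."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(pooled)


def phi_coefficient(table: np.ndarray) -> float:
    """Phi for a 2x2 contingency table: (ad - bc) / sqrt(product of margins)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("phi is defined for 2x2 tables only")
    (a, b), (c, d) = t
    denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        raise ZeroDivisionError("degenerate 2x2 table: zero margin")
    return float((a * d - b * c) / denom)


def cramers_v(table: np.ndarray) -> float:
    """Cramér's V for an r x c contingency table."""
    t = np.asarray(table, dtype=float)
    chi2 = sps.chi2_contingency(t, correction=False).statistic
    n = t.sum()
    k = min(t.shape) - 1
    if n == 0 or k == 0:
        raise ValueError("degenerate contingency table")
    return float(np.sqrt(chi2 / (n * k)))


def mann_whitney_z(a, b) -> tuple[float, float, float]:
    """Mann–Whitney U with tie-corrected normal approximation.

    Returns (U of the first sample, two-sided p, standardised Z). The
    standardised point-biserial effect size is Z / sqrt(n1 + n2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0, 0.0
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return float(u1), float(min(p, 1.0)), float(z)


# --- routed two-group testing ---------------------------------------------

@dataclass
class TestResult:
    feature: str
    test_used: str  # "t" | "mann_whitney" | "chi_squared"
    statistic: float
    p: float
    effect_size: float
    effect_size_name: str
    routing_reason: str
    adjusted_p: float | None = None


def distributional_test(
    a, b, feature: str = "", kind: str = "numeric", alpha: float = ALPHA
) -> TestResult:
    """Two-group test routed by feature kind and normality.

    Categorical / ordinal features go to Pearson's chi-squared with phi
    (2x2) or Cramér's V. Numeric features are Shapiro–Wilk-checked per
    group at the given alpha: both normal -> two-tailed pooled-variance
    t-test with Cohen's d, otherwise two-tailed Mann–Whitney U with the
    standardised point-biserial r = Z / sqrt(n).
    """
    a = pd.Series(a).dropna().to_numpy()
    b = pd.Series(b).dropna().to_numpy()

    if kind in ("categorical", "ordinal"):
        levels = np.union1d(a, b)
        table = np.array(
            [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]]
        ).T
        table = table[table.sum(axis=1) > 0]
        if (table.sum(axis=0) == 0).any() or table.shape[0] < 2:
            raise ValueError(f"{feature}: degenerate contingency table")
        res = sps.chi2_contingency(table, correction=False)
        if table.shape == (2, 2):
            es, es_name = phi_coefficient(table), "phi"
        else:
            es, es_name = cramers_v(table), "cramers_v"
        return TestResult(
            feature, "chi_squared", float(res.statistic), float(res.pvalue),
            es, es_name, f"{kind} feature",
        )

    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"{feature}: need >= 3 observations per group")
    normal_a = len(np.unique(a)) > 1 and sps.shapiro(a).pvalue > alpha
    normal_b = len(np.unique(b)) > 1 and sps.shapiro(b).pvalue > alpha
    if normal_a and normal_b:
        res = sps.ttest_ind(a, b, equal_var=True)
        return TestResult(
            feature, "t", float(res.statistic), float(res.pvalue),
            cohens_d(a, b), "cohens_d", "both groups Shapiro-Wilk normal",
        )
    u, p, z = mann_whitney_z(a, b)
    r = z / np.sqrt(len(a) + len(b))
    return TestResult(
        feature, "mann_whitney", u, p, float(r), "point_biserial_r",
        "non-normal by Shapiro-Wilk",
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --- bootstrap effect-size-difference comparison ---------------------------

@dataclass
class EffectSizeComparison:
    feature: str
    d_model: float
    d_reference: float
    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool
    n_redrawn: int = 0
    boot_p: float | None = None


def bootstrap_effectsize_difference(
    values,
    labels_model,
    labels_reference,
    feature: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
    positive_label: str = "MCI",
) -> EffectSizeComparison:
    """Compare two diagnostic procedures' effect sizes by bootstrap.

    In each of ``n_boot`` iterations the four (procedure x group) samples
    are independently resampled with replacement at their original sizes;
    Cohen's d is computed per procedure (NC minus MCI group) and the
    difference model - reference is stored. The 95% CI is the 2.5th/97.5th
    percentile of stored differences; the difference is significant iff the
    CI excludes zero. Degenerate resamples (zero pooled SD) are redrawn and
    counted.
    """
    values = np.asarray(values, dtype=float)
    labels_model = np.asarray(labels_model)
    labels_reference = np.asarray(labels_reference)
    rng = np.random.default_rng(seed)

    groups = {}
    for proc, labels in (("model", labels_model), ("reference", labels_reference)):
        pos = values[labels == positive_label]
        neg = values[labels != positive_label]
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError(f"{proc}: needs >= 2 observations in each group")
        groups[proc] = (neg, pos)  # d oriented NC minus MCI

    def one_round(size):
        out = {}
        for proc, (neg, pos) in groups.items():
            neg_s = rng.choice(neg, size=(size, len(neg)), replace=True)
            pos_s = rng.choice(pos, size=(size, len(pos)), replace=True)
            out[proc] = _cohens_d_matrix(neg_s, pos_s)
        return out["model"] - out["reference"]

    deltas = one_round(n_boot)
    n_redrawn = 0
    for _ in range(100):  # redraw degenerate iterations
        bad = ~np.isfinite(deltas)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        deltas[bad] = one_round(int(bad.sum()))
    deltas = deltas[np.isfinite(deltas)]

    d_model = cohens_d(*groups["model"])
    d_ref = cohens_d(*groups["reference"])
    ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    # two-sided bootstrap p: fraction of resampled differences beyond zero
    frac = float(np.mean(deltas > 0))
    boot_p = 2 * min(frac, 1 - frac)
    return EffectSizeComparison(
        feature=feature,
        d_model=d_model,
        d_reference=d_ref,
        delta=d_model - d_ref,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        significant=not (ci_low <= 0.0 <= ci_high),
        n_redrawn=n_redrawn,
        boot_p=float(min(boot_p, 1.0)),
    )
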