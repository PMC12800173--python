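"""Data-driven MCI diagnostic model.

Feature construction (battery z-scores + disease-related, motor and
comorbidity variables), three clustering algorithms — spectral clustering
on the symmetric normalised Laplacian, K-Means, and Gaussian mixtures — a
silhouette-guided grid search gated by external clinical-plausibility
rules, mutual-information feature importance, and evaluation against the
clinical diagnostic reference test.

The external rules encode the expected PD-MCI phenotype: the putative MCI
cluster (the one with the lower median MoCA) must also be at least as old,
have at least as long a disease duration and at least as advanced a Hoehn &
Yahr stage as the other cluster. Solutions violating any rule are excluded
from model selection regardless of their silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.metrics import mutual_info_score, roc_auc_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .schema import COMORBIDITY_FLAGS, TESTS, z_col

#: Default numeric (robust-scaled) features beyond the 10 battery z-scores.
NUMERIC_CLINICAL_FEATURES = [
    "age_at_onset",
    "disease_duration",
    "updrs_iii",
    "hoehn_yahr",
    "rbdsq",
]
#: Binary comorbidity / lifestyle flags, one-hot (0/1) encoded.
FLAG_FEATURES = list(COMORBIDITY_FLAGS)

DEFAULT_FEATURES = [z_col(t) for t in TESTS] + NUMERIC_CLINICAL_FEATURES + FLAG_FEATURES


@dataclass
class FeatureMatrix:
    """Preprocessed design matrix with its scaling parameters."""

    X: np.ndarray
    columns: list[str]
    index: pd.Index
    medians: dict[str, float]
    iqrs: dict[str, float]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns, index=self.index)


@dataclass
class ClusterSolution:
    algorithm: str  # "spectral" | "kmeans" | "gmm"
    hyperparameters: dict
    labels: np.ndarray
    silhouette: float
    degenerate: bool = False
    external_ok: bool = False
    failed_rules: list = field(default_factory=list)
    mci_cluster: int | None = None
    label_map: dict | None = None
    soft_score: np.ndarray | None = None  # higher = more MCI-like

    def mapped_labels(self) -> np.ndarray:
        if self.label_map is None:
            raise ValueError("label_map undefined: solution failed external criteria")
        return np.array([self.label_map[c] for c in self.labels])


def build_feature_matrix(
    scored_pd: pd.DataFrame, features: list[str] | None = None
) -> FeatureMatrix:
    """Build the clustering design matrix from a scored PD baseline table.

    Battery z-scores enter as-is (already standardised, already oriented so
    lower = worse, including the inverted timed trail-making scores);
    remaining numeric variables are robust-scaled, (x - median) / IQR on
    the fitting cohort; binary flags pass through as 0/1. No missing cells
    are allowed after preprocessing.
    """
    features = features or DEFAULT_FEATURES
    missing = [f for f in features if f not in scored_pd.columns]
    if missing:
        raise KeyError(f"feature columns missing: {missing}")
    if scored_pd[features].isna().any().any():
        bad = scored_pd[features].isna().any()
        raise ValueError(f"missing cells in features: {list(bad[bad].index)}")

    cols, medians, iqrs = [], {}, {}
    out = np.empty((len(scored_pd), len(features)))
    for j, f in enumerate(features):
        x = scored_pd[f].to_numpy(dtype=float)
        if f.startswith("z_") or f in FLAG_FEATURES:
            out[:, j] = x
        else:
            med = float(np.median(x))
            q1, q3 = np.percentile(x, [25, 75])
            iqr = float(q3 - q1)
            if iqr == 0:
                if np.all(x == x[0]):
                    raise ValueError(
                        f"zero IQR in feature {f!r}: degenerate for robust scaling"
                    )
                # coarse ordinal scales (e.g. Hoehn & Yahr) can have IQR 0
                # while still varying; fall back to the SD as the spread
                iqr = float(x.std(ddof=1))
            out[:, j] = (x - med) / iqr
            medians[f], iqrs[f] = med, iqr
        cols.append(f)
    return FeatureMatrix(out, cols, scored_pd.index, medians, iqrs)


# --- clustering algorithms -------------------------------------------------

def spectral_embedding(
    X: np.ndarray, k: int, bandwidth: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric-normalised-Laplacian embedding.

    Affinity W_ij = exp(-||x_i - x_j||^2 / (2 bandwidth^2)) with zero
    diagonal; L_sym = I - D^{-1/2} W D^{-1/2}. Returns (eigenvalues,
    raw eigenvectors of the k smallest eigenvalues, row-normalised
    embedding).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    W = np.exp(-d2 / (2 * bandwidth**2))
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError(
            "isolated point in affinity graph (zero degree); increase the bandwidth"
        )
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(len(X)) - (dinv[:, None] * W) * dinv[None, :]
    L = (L + L.T) / 2  # enforce symmetry against round-off
    vals, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vals, vecs, vecs / norms


def spectral_cluster(
    X: np.ndarray, k: int = 2, bandwidth: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral clustering; returns (labels, row-normalised embedding)."""
    n = len(X)
    if not n >= k >= 2:
        raise ValueError("need n >= k >= 2")
    _, _, emb = spectral_embedding(X, k, bandwidth)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return labels, emb


def kmeans_cluster(X: np.ndarray, k: int = 2, seed: int = 0, n_init: int = 10) -> np.ndarray:
    if len(X) < k:
        raise ValueError("need n >= k")
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(X)


def gmm_cluster(
    X: np.ndarray, k: int = 2, covariance_type: str = "full", seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """EM-fitted Gaussian mixture; returns (argmax labels, posterior)."""
    if len(X) < k:
        raise ValueError("need n >= k")
    gm = GaussianMixture(
        n_components=k, covariance_type=covariance_type, random_state=seed, n_init=3
    ).fit(X)
    post = gm.predict_proba(X)
    return post.argmax(axis=1), post


def mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean Euclidean silhouette; errors on a single cluster."""
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(X, labels, metric="euclidean"))


# --- external clinical-plausibility rules ----------------------------------

EXTERNAL_RULES = ("older", "longer_duration", "higher_hoehn_yahr", "lower_moca")


def external_criteria_check(
    labels: np.ndarray, clinical: pd.DataFrame
) -> tuple[bool, list[str], int]:
    """Check a 2-cluster solution against the expected PD-MCI phenotype.

    The candidate MCI cluster is the one with the lower median MoCA total.
    The solution passes iff that cluster's median age, disease duration and
    Hoehn & Yahr are >= the other cluster's (ties allowed) and its median
    MoCA is strictly lower. Returns (pass, failed rules, candidate cluster).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("external rules are defined for exactly 2 clusters")
    for col in ("age", "disease_duration", "hoehn_yahr", "moca_total"):
        if col not in clinical.columns:
            raise KeyError(f"clinical column missing: {col!r}")

    med = {
        c: {
            col: float(clinical.loc[labels == c, col].median())
            for col in ("age", "disease_duration", "hoehn_yahr", "moca_total")
        }
        for c in uniq
    }
    # candidate = lower median MoCA (tie -> first cluster id, deterministic)
    cand = min(uniq, key=lambda c: (med[c]["moca_total"], c))
    other = uniq[uniq != cand][0]
    failed = []
    if not med[cand]["moca_total"] < med[other]["moca_total"]:
        failed.append("lower_moca")
    if not med[cand]["age"] >= med[other]["age"]:
        failed.append("older")
    if not med[cand]["disease_duration"] >= med[other]["disease_duration"]:
        failed.append("longer_duration")
    if not med[cand]["hoehn_yahr"] >= med[other]["hoehn_yahr"]:
        failed.append("higher_hoehn_yahr")
    return len(failed) == 0, failed, int(cand)


# --- grid search -----------------------------------------------------------

def default_grids(X: np.ndarray) -> dict:
    """Default hyperparameter grids; spectral bandwidths are multiples of
    the median pairwise Euclidean distance."""
    d = np.sqrt(
        np.maximum(
            np.sum(X**2, 1)[:, None] + np.sum(X**2, 1)[None, :] - 2 * X @ X.T, 0
        )
    )
    med = float(np.median(d[np.triu_indices(len(X), 1)]))
    return {
        "spectral": [{"k": 2, "bandwidth": f * med} for f in (0.5, 1.0, 2.0, 5.0)],
        "kmeans": [{"k": 2, "n_init": 10}],
        "gmm": [{"k": 2, "covariance_type": c} for c in ("full", "diag")],
    }


def _fit_candidate(algorithm: str, X: np.ndarray, params: dict, seed: int):
    """Fit one grid point; returns (labels, soft score, assignment-space X)."""
    k = params.get("k", 2)
    if algorithm == "spectral":
        labels, emb = spectral_cluster(X, k, params["bandwidth"], seed)
        space = emb
        post = None
    elif algorithm == "kmeans":
        labels = kmeans_cluster(X, k, seed, params.get("n_init", 10))
        space = X
        post = None
    elif algorithm == "gmm":
        labels, post = gmm_cluster(X, k, params.get("covariance_type", "full"), seed)
        space = X
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return labels, post, space


def _soft_score(labels, post, space, mci_cluster: int) -> np.ndarray:
    """Per-row MCI-likeness: GMM posterior of the MCI component, otherwise
    the signed difference of distances to the two centroids in the
    algorithm's assignment space."""
    if post is not None:
        return post[:, mci_cluster]
    uniq = np.unique(labels)
    cents = {c: space[labels == c].mean(axis=0) for c in uniq}
    other = uniq[uniq != mci_cluster][0]
    d_mci = np.linalg.norm(space - cents[mci_cluster], axis=1)
    d_other = np.linalg.norm(space - cents[other], axis=1)
    return d_other - d_mci


def grid_search(
    fm: FeatureMatrix,
    clinical: pd.DataFrame,
    grids: dict | None = None,
    seed: int = 0,
    select_k: int = 2,
) -> tuple[dict[str, ClusterSolution | None], pd.DataFrame]:
    """Silhouette-guided, clinically gated model selection.

    Every grid point of every algorithm is fitted and logged; candidates
    failing the external clinical rules (or degenerate, single-cluster
    ones) are excluded; per algorithm, the surviving candidate with the
    highest silhouette wins (ties broken by grid order). Exploratory k
    values are logged but selection is restricted to ``select_k``.

    Returns ({algorithm: best solution or None}, full report frame).
    """
    X = fm.X
    grids = grids or default_grids(X)
    report_rows = []
    best: dict[str, ClusterSolution | None] = {}
    for algorithm, points in grids.items():
        best[algorithm] = None
        for i, params in enumerate(points):
            row = {"algorithm": algorithm, "grid_index": i, **params}
            try:
                labels, post, space = _fit_candidate(algorithm, X, params, seed)
            except ValueError as exc:
                row.update(error=str(exc), silhouette=np.nan, external_ok=False)
                report_rows.append(row)
                continue
            degenerate = len(np.unique(labels)) != params.get("k", 2)
            sil = np.nan if degenerate else mean_silhouette(X, labels)
            external_ok, failed, cand = False, ["degenerate"], None
            if not degenerate and params.get("k", 2) == 2:
                external_ok, failed, cand = external_criteria_check(labels, clinical)
            row.update(
                silhouette=sil,
                degenerate=degenerate,
                external_ok=external_ok,
                failed_rules=";".join(failed),
            )
            report_rows.append(row)
            if degenerate or not external_ok or params.get("k", 2) != select_k:
                continue
            sol = ClusterSolution(
                algorithm=algorithm,
                hyperparameters=dict(params),
                labels=labels,
                silhouette=sil,
                external_ok=True,
                mci_cluster=cand,
                label_map={cand: "MCI", int(np.unique(labels)[np.unique(labels) != cand][0]): "NC"},
                soft_score=_soft_score(labels, post, space, cand),
            )
            if best[algorithm] is None or sol.silhouette > best[algorithm].silhouette:
                best[algorithm] = sol
    return best, pd.DataFrame(report_rows)


# --- feature importance and evaluation -------------------------------------

def feature_importance(
    fm: FeatureMatrix, labels: np.ndarray, n_bins: int = 5
) -> pd.Series:
    """Mutual information between each feature and the cluster labels.

    Continuous features are discretised into equal-frequency bins (at most
    ``n_bins``); constant features get MI = 0. Returned sorted descending,
    in nats.
    """
    out = {}
    for j, name in enumerate(fm.columns):
        x = fm.X[:, j]
        uniq = np.unique(x)
        if len(uniq) <= 1:
            out[name] = 0.0
            continue
        if len(uniq) <= n_bins:
            binned = np.searchsorted(uniq, x)
        else:
            qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
            binned = np.searchsorted(qs, x, side="right")
        out[name] = float(mutual_info_score(binned, labels))
    return pd.Series(out).sort_values(ascending=False)


@dataclass
class EvaluationMetrics:
    sensitivity: float
    precision: float
    accuracy: float
    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


def evaluate_vs_reference(
    solution: ClusterSolution, reference_labels, positive: str = "MCI"
) -> EvaluationMetrics:
    """Confusion-based metrics of a mapped solution against the clinical
    reference labels, with AUC computed from the solution's soft score."""
    pred = solution.mapped_labels()
    ref = np.asarray(reference_labels)
    if len(pred) != len(ref):
        raise ValueError("label sets cover different row sets")
    tp = int(np.sum((pred == positive) & (ref == positive)))
    fp = int(np.sum((pred == positive) & (ref != positive)))
    tn = int(np.sum((pred != positive) & (ref != positive)))
    fn = int(np.sum((pred != positive) & (ref == positive)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    acc = (tp + tn) / len(ref)
    if len(np.unique(ref)) < 2 or solution.soft_score is None:
        auc = None
    else:
        auc = float(roc_auc_score((ref == positive).astype(int), solution.soft_score))
    return EvaluationMetrics(sens, prec, acc, auc, tp, fp, tn, fn)
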