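"""Cluster stage: supervised clinical screening, then k-medoids.

Clinical measurements are screened against the assigned-diagnosis score
with a permissive Benjamini-Hochberg FDR threshold (q = 0.2 by default).
The screened, standardized clinical features are clustered by PAM
(partitioning around medoids) under the Manhattan metric; the number of
clusters is chosen by the gap statistic's one-standard-error rule with the
silhouette width recorded as the second criterion.

PAM here is the deterministic BUILD + SWAP algorithm: greedy
cost-minimizing medoid addition followed by steepest-descent single-swap
local search, ties always broken toward the lowest row index, so repeated
runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .datamodel import FeatureCategories, FeatureTable


@dataclass
class ScreeningConfig:
    q_screen: float = 0.2
    method: str = "pearson"  # or "spearman"

    def validate(self) -> None:
        if not 0.0 < self.q_screen < 1.0:
            raise ValueError("q_screen must lie in (0, 1)")
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown association method {self.method!r}")


@dataclass
class ClusterConfig:
    k_max: int = 6
    gap_B: int = 100
    k_policy: str = "gap"     # "gap" | "silhouette" | "fixed"
    fixed_k: int | None = None
    standardize: bool = True

    def validate(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.gap_B < 10:
            raise ValueError("gap_B must be >= 10")
        if self.k_policy not in ("gap", "silhouette", "fixed"):
            raise ValueError(f"unknown k policy {self.k_policy!r}")
        if self.k_policy == "fixed" and not self.fixed_k:
            raise ValueError("fixed k policy requires fixed_k")


@dataclass
class ClusterModel:
    k: int
    medoid_indices: np.ndarray
    labels: np.ndarray          # 0 .. k-1
    cost: float
    metric: str = "manhattan"
    mean_silhouette: float | None = None
    gap: "GapResult | None" = None
    rationale: str = ""

    @property
    def sizes(self) -> list[int]:
        return [int((self.labels == c).sum()) for c in range(self.k)]


@dataclass
class GapResult:
    ks: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    log_w: np.ndarray
    log_w_ref: np.ndarray
    k_hat: int                  # 1-SE choice over the full k range


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float], q: float = 0.05
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection mask."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def screen_clinical(table: FeatureTable, categories: FeatureCategories,
                    config: ScreeningConfig | None = None) -> pd.DataFrame:
    """Associate each clinical feature with the assigned-diagnosis score.

    Returns a frame with columns feature, r, p, p_adj, selected; a
    zero-variance clinical feature is flagged (p = NaN, never selected) and
    excluded from the BH family.
    """
    config = config or ScreeningConfig()
    config.validate()
    clinical = categories.clinical_features
    if not clinical:
        raise ValueError("no clinical features to screen")
    y = table.column(categories.assigned_diagnosis_feature)
    if np.isnan(y).any():
        raise ValueError("assigned diagnosis column contains missing values")
    rows = []
    for fid in clinical:
        x = table.column(fid)
        if np.isnan(x).any():
            raise ValueError(f"clinical feature {fid!r} has missing values; "
                             "impute first")
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"feature": fid, "r": np.nan, "p": np.nan})
            continue
        if config.method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        rows.append({"feature": fid, "r": float(r), "p": float(p)})
    frame = pd.DataFrame(rows)
    ok = frame["p"].notna().to_numpy()
    p_adj = np.full(len(frame), np.nan)
    selected = np.zeros(len(frame), dtype=bool)
    if ok.any():
        adj, rej = bh_adjust(frame.loc[ok, "p"].to_numpy(), config.q_screen)
        p_adj[ok] = adj
        selected[ok] = rej
    frame["p_adj"] = p_adj
    frame["selected"] = selected
    return frame


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def manhattan_distance(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.abs(a - b).sum())


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    nearest = sub.argmin(axis=1)  # argmin takes the first (lowest) index
    return nearest, float(sub[np.arange(len(D)), nearest].sum())


def pam_cluster(X: np.ndarray, k: int, D: np.ndarray | None = None
                ) -> ClusterModel:
    """Deterministic PAM (BUILD + SWAP) under the Manhattan metric."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if D is None:
        D = cdist(X, X, metric="cityblock")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")

    # BUILD: start from the 1-medoid optimum, then greedily add the point
    # that most reduces the total cost (ties -> lowest index)
    totals = D.sum(axis=0)
    medoids = [int(totals.argmin())]
    d_nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(D, d_nearest[:, None]).sum(axis=0)
        gains[medoids] = np.inf
        nxt = int(gains.argmin())
        medoids.append(nxt)
        d_nearest = np.minimum(d_nearest, D[:, nxt])

    # SWAP: steepest descent over single medoid/non-medoid exchanges
    medoids_arr = np.array(sorted(medoids))
    _, cost = _assign(D, medoids_arr)
    improved = True
    while improved and k < n:
        improved = False
        nearest_idx, _ = _assign(D, medoids_arr)
        nearest_med = medoids_arr[nearest_idx]
        d_near = D[np.arange(n), nearest_med]
        # distance to the second-closest medoid
        if k >= 2:
            sub = D[:, medoids_arr]
            part = np.partition(sub, 1, axis=1)
            d_second = part[:, 1]
        else:
            d_second = np.full(n, np.inf)
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        best = (0.0, None, None)
        for mi, m in enumerate(medoids_arr):
            base = np.where(nearest_med == m, d_second, d_near)
            # cost after removing m and adding h, for all candidates h
            cand_cost = np.minimum(base[:, None], D[:, non_medoids]).sum(axis=0)
            deltas = cand_cost - cost
            hi = int(deltas.argmin())
            if deltas[hi] < best[0] - 1e-12:
                best = (float(deltas[hi]), mi, int(non_medoids[hi]))
        if best[1] is not None:
            medoids_arr[best[1]] = best[2]
            medoids_arr = np.sort(medoids_arr)
            _, cost = _assign(D, medoids_arr)
            improved = True

    nearest_idx, cost = _assign(D, medoids_arr)
    return ClusterModel(k=k, medoid_indices=medoids_arr,
                        labels=nearest_idx.astype(int), cost=cost)


def silhouette_width(X: np.ndarray, labels: Sequence[int]
                     ) -> tuple[np.ndarray, float]:
    """Per-subject silhouette s(i) = (b-a)/max(a,b) under Manhattan distance
    (singleton clusters contribute 0)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    s = silhouette_samples(np.asarray(X, dtype=float), labels,
                           metric="manhattan")
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# gap statistic and k selection
# ---------------------------------------------------------------------------

def gap_curve(X: np.ndarray, k_max: int = 6, B: int = 100,
              rng: np.random.Generator | int | None = None) -> GapResult:
    """Gap statistic over k = 1..k_max with a uniform-box reference.

    gap(k) = mean_b log W_k(ref_b) - log W_k(data), with W_k the total PAM
    Manhattan cost; s_k = SD_b(log W_k(ref_b)) * sqrt(1 + 1/B).  ``k_hat``
    is the smallest k with gap(k) >= gap(k+1) - s_{k+1} (k_max if none).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi - lo == 0):
        raise ValueError("gap statistic undefined for constant data")
    rng = np.random.default_rng(rng)
    ks = np.arange(1, k_max + 1)
    D = cdist(X, X, metric="cityblock")
    log_w = np.array([np.log(max(pam_cluster(X, k, D=D).cost, 1e-12))
                      for k in ks])
    ref_log_w = np.empty((B, k_max))
    for b in range(B):
        R = rng.uniform(lo, hi, size=X.shape)
        DR = cdist(R, R, metric="cityblock")
        for i, k in enumerate(ks):
            ref_log_w[b, i] = np.log(max(pam_cluster(R, k, D=DR).cost, 1e-12))
    gap = ref_log_w.mean(axis=0) - log_w
    s_k = ref_log_w.std(axis=0) * np.sqrt(1.0 + 1.0 / B)
    k_hat = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            k_hat = int(ks[i])
            break
    return GapResult(ks, gap, s_k, log_w, ref_log_w.mean(axis=0), k_hat)


def gap_one_se_choice(gap: GapResult, min_k: int = 1) -> int:
    """One-SE rule restricted to k >= min_k."""
    start = int(np.searchsorted(gap.ks, min_k))
    for i in range(start, len(gap.ks) - 1):
        if gap.gap[i] >= gap.gap[i + 1] - gap.s_k[i + 1]:
            return int(gap.ks[i])
    return int(gap.ks[-1])


def choose_k(gap: GapResult, silhouette_by_k: dict[int, float],
             config: ClusterConfig | None = None, min_k: int = 2
             ) -> tuple[int, dict]:
    """Combine the two k-selection criteria under the configured policy.

    Default policy takes the gap one-SE choice (searched over k >= min_k,
    since the procedure presumes clusters exist) and records whether the
    silhouette argmax agrees; disagreement is reported, never fatal.
    """
    config = config or ClusterConfig()
    config.validate()
    k_gap = gap_one_se_choice(gap, min_k=min_k)
    k_sil = max(silhouette_by_k, key=lambda k: (silhouette_by_k[k], -k))
    if config.k_policy == "fixed":
        k = int(config.fixed_k)
        rationale = f"k={k} fixed by configuration (gap preferred {k_gap}, " \
                    f"silhouette {k_sil})"
    elif config.k_policy == "silhouette":
        k = k_sil
        rationale = f"k={k} by silhouette argmax (gap preferred {k_gap})"
    else:
        k = k_gap
        rationale = f"k={k} by gap one-SE rule (silhouette preferred {k_sil})"
    return k, {"k_gap": k_gap, "k_silhouette": k_sil,
               "agreement": k_gap == k_sil, "rationale": rationale}


def cluster_clinical(X: np.ndarray, config: ClusterConfig | None = None,
                     rng: np.random.Generator | int | None = None
                     ) -> ClusterModel:
    """Full stage-2 clustering of a standardized clinical matrix: gap and
    silhouette curves, policy-based k choice, final PAM fit."""
    config = config or ClusterConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    gap = gap_curve(X, k_max=config.k_max, B=config.gap_B, rng=rng)
    D = cdist(X, X, metric="cityblock")
    sil = {}
    for k in range(2, config.k_max + 1):
        model_k = pam_cluster(X, k, D=D)
        if len(np.unique(model_k.labels)) < 2:
            continue
        sil[k] = silhouette_width(X, model_k.labels)[1]
    k, info = choose_k(gap, sil, config)
    model = pam_cluster(X, k, D=D)
    model.gap = gap
    if k >= 2:
        model.mean_silhouette = silhouette_width(X, model.labels)[1]
    model.rationale = info["rationale"]
    return model
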