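"""Missing-data imputation and monotone symmetrizing transforms.

Missing cells are filled by 5-nearest-neighbour imputation: neighbour
distance is Euclidean over jointly observed, per-feature standardized
columns (rescaled by the number of jointly observed features), and the
imputed value is the unweighted mean of the feature's observed values
among the k nearest subjects.

Each feature is then monotonically transformed to reduce skewness: from an
ordered family {identity, log-shift, square-root, negative reciprocal} the
member minimizing the absolute sample skewness g1 = m3 / m2^(3/2) (biased
central moments) is kept, ties broken toward the earlier family member.
All family members are strictly increasing on the observed range, so
per-subject rank order within each feature is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datamodel import FeatureTable

TRANSFORM_FAMILY = ("identity", "log", "sqrt", "reciprocal")


@dataclass
class PreprocessConfig:
    knn_k: int = 5
    transform_family: tuple[str, ...] = TRANSFORM_FAMILY
    standardize_clinical: bool = True

    def validate(self, n_subjects: int | None = None) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if n_subjects is not None and self.knn_k >= n_subjects:
            raise ValueError("knn_k must be smaller than the subject count")
        if "identity" not in self.transform_family:
            raise ValueError("transform family must contain identity")
        unknown = set(self.transform_family) - set(TRANSFORM_FAMILY)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")


@dataclass
class TransformRecord:
    feature: str
    transform: str
    shift: float
    skew_before: float
    skew_after: float


def sample_skewness(x: np.ndarray) -> float:
    """g1 = m3 / m2^(3/2) with biased central moments; 0 for constant data."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0.0:
        return 0.0
    m3 = np.mean((x - m) ** 3)
    return float(m3 / m2 ** 1.5)


def impute_knn(table: FeatureTable, config: PreprocessConfig | None = None
               ) -> FeatureTable:
    """Fill missing cells by the k-nearest-neighbour column mean (k=5).

    Observed cells are unchanged and the returned mask is all-False.  A
    second pass over the result is the identity (idempotence).
    """
    config = config or PreprocessConfig()
    config.validate(table.n_subjects)
    k = config.knn_k
    values = table.values.copy()
    mask = table.missing_mask
    if not mask.any():
        out = table.copy()
        out.missing_mask = np.zeros_like(out.missing_mask)
        return out

    obs = ~mask
    if (obs.sum(axis=1) == 0).any():
        bad = table.subject_ids[int(np.argmin(obs.sum(axis=1)))]
        raise ValueError(f"subject {bad!r} has no observed features")
    n_obs_per_feature = obs.sum(axis=0)
    short = n_obs_per_feature < k
    if short.any():
        fid = table.feature_ids[int(np.argmax(short))]
        raise ValueError(
            f"feature {fid!r} observed in fewer than {k} subjects")

    # per-feature standardization over observed values, for distances only
    col_mean = np.array([values[obs[:, j], j].mean()
                         for j in range(table.n_features)])
    col_sd = np.array([values[obs[:, j], j].std(ddof=1)
                       for j in range(table.n_features)])
    col_sd[col_sd == 0] = 1.0
    z = (values - col_mean) / col_sd
    z[mask] = np.nan

    filled = values.copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        # squared distance over jointly observed columns, rescaled by their
        # count (mean squared difference) for comparability across patterns
        diff = z - z[i]
        joint = obs & obs[i]
        sq = np.where(joint, diff ** 2, 0.0)
        counts = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.where(counts > 0, sq.sum(axis=1) / counts,
                                    np.inf))
        dist[i] = np.inf
        for j in np.flatnonzero(mask[i]):
            candidates = np.flatnonzero(obs[:, j])
            cd = dist[candidates]
            order = candidates[np.lexsort((candidates, cd))][:k]
            filled[i, j] = values[order, j].mean()

    return FeatureTable(list(table.subject_ids), list(table.feature_ids),
                        filled, np.zeros_like(mask))


def _shift_for(x: np.ndarray) -> float:
    """Shift constant c making x + c strictly positive: 1 - min(x) when
    min(x) <= 0, else 0."""
    mn = float(np.min(x))
    return 1.0 - mn if mn <= 0.0 else 0.0


_TRANSFORMS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "identity": lambda x, c: x,
    "log": lambda x, c: np.log(x + c),
    "sqrt": lambda x, c: np.sqrt(x + c),
    # negative reciprocal keeps the transform strictly increasing
    "reciprocal": lambda x, c: -1.0 / (x + c),
}


def _transform_shift(name: str, x: np.ndarray) -> float:
    if name in ("log", "reciprocal"):
        return _shift_for(x)
    if name == "sqrt":  # sqrt only needs non-negativity
        mn = float(np.min(x))
        return -mn if mn < 0.0 else 0.0
    return 0.0


def symmetrize(table: FeatureTable, config: PreprocessConfig | None = None
               ) -> tuple[FeatureTable, list[TransformRecord]]:
    """Apply, per feature, the family member minimizing |g1|.

    Requires a complete table. Returns the transformed table and a log of
    the chosen transform and achieved skewness for every feature.
    """
    config = config or PreprocessConfig()
    config.validate()
    if table.missing_mask.any():
        raise ValueError("symmetrize requires a complete (imputed) table")
    values = table.values.copy()
    log: list[TransformRecord] = []
    for j, fid in enumerate(table.feature_ids):
        x = values[:, j]
        before = sample_skewness(x)
        best_name, best_y, best_skew = "identity", x, abs(before)
        for name in config.transform_family:
            c = _transform_shift(name, x)
            with np.errstate(invalid="ignore", divide="ignore"):
                y = _TRANSFORMS[name](x, c)
            if not np.all(np.isfinite(y)):
                continue
            s = abs(sample_skewness(y))
            if s < best_skew - 1e-12:  # strict improvement; ties keep earlier
                best_name, best_y, best_skew = name, y, s
        shift = _transform_shift(best_name, x)
        values[:, j] = best_y
        log.append(TransformRecord(fid, best_name, shift, before,
                                   sample_skewness(best_y)))
    out = FeatureTable(list(table.subject_ids), list(table.feature_ids),
                       values, np.zeros_like(table.missing_mask))
    return out, log


def apply_transforms(table: FeatureTable, log: Sequence[TransformRecord]
                     ) -> FeatureTable:
    """Re-apply a frozen transform log to a (complete) table."""
    if table.missing_mask.any():
        raise ValueError("apply_transforms requires a complete table")
    values = table.values.copy()
    by_feature = {r.feature: r for r in log}
    for j, fid in enumerate(table.feature_ids):
        r = by_feature.get(fid)
        if r is None or r.transform == "identity":
            continue
        x = values[:, j]
        # out-of-sample values may undershoot the frozen shift; clamp the
        # argument to keep the transform finite and weakly monotone
        floor = -r.shift if r.transform == "sqrt" else 1e-9 - r.shift
        x = np.maximum(x, floor)
        with np.errstate(invalid="ignore", divide="ignore"):
            values[:, j] = _TRANSFORMS[r.transform](x, r.shift)
    return FeatureTable(list(table.subject_ids), list(table.feature_ids),
                        values, np.zeros_like(table.missing_mask))


def standardize(table: FeatureTable, features: Sequence[str] | None = None
                ) -> FeatureTable:
    """Center the given columns to mean 0 and scale to SD 1 (ddof=1)."""
    if table.missing_mask.any():
        raise ValueError("standardize requires a complete table")
    features = list(features) if features is not None else list(table.feature_ids)
    values = table.values.copy()
    for fid in features:
        j = table.feature_index(fid)
        sd = values[:, j].std(ddof=1)
        if sd == 0:
            raise ValueError(f"feature {fid!r} has zero variance")
        values[:, j] = (values[:, j] - values[:, j].mean()) / sd
    return FeatureTable(list(table.subject_ids), list(table.feature_ids),
                        values, np.zeros_like(table.missing_mask))
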