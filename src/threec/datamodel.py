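"""Core data containers and plain-text I/O for the 3C pipeline.

The pipeline consumes a subjects x features numeric table (CSV), a
feature-category map (YAML) assigning each feature to one of three roles --
the assigned diagnosis score, clinical measurements, or potential
biomarkers -- and optional binary external diagnosis labels. Results are
serialized as a JSON run report plus a human-readable text summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ASSIGNED_DIAGNOSIS = "assigned_diagnosis"
CLINICAL = "clinical"
BIOMARKER = "biomarker"
CATEGORIES = (ASSIGNED_DIAGNOSIS, CLINICAL, BIOMARKER)
BIOMARKER_DOMAINS = ("cognitive", "structural", "functional")

#: tokens read as missing; written back as an empty cell
MISSING_TOKENS = ("", "NA")


@dataclass
class FeatureTable:
    """Subjects x features numeric matrix with an explicit missingness mask.

    Missing entries hold NaN in ``values`` and True in ``missing_mask``;
    they are never silently zero.
    """

    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.feature_ids) != p:
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values shape")
        _check_unique(self.subject_ids, "subject id")
        _check_unique(self.feature_ids, "feature id")
        # NaN payloads must be flagged
        self.missing_mask |= np.isnan(self.values)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_index(feature_id)]

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_index(f) for f in feature_ids]
        return FeatureTable(
            list(self.subject_ids),
            [self.feature_ids[i] for i in idx],
            self.values[:, idx].copy(),
            self.missing_mask[:, idx].copy(),
        )

    def subset_subjects(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            [self.subject_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx, :].copy(),
            self.missing_mask[idx, :].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.subject_ids),
            list(self.feature_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.feature_ids
        )


@dataclass
class FeatureCategories:
    """Per-feature category map.

    Exactly one feature is the assigned diagnosis (the field-standard score
    supervising the clinical screen); biomarkers additionally carry a domain
    tag (cognitive / structural / functional).
    """

    category: dict[str, str]
    domain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, cat in self.category.items():
            if cat not in CATEGORIES:
                raise ValueError(f"feature {fid!r}: unknown category {cat!r}")
        assigned = self.assigned_diagnosis_features()
        if len(assigned) != 1:
            raise ValueError(
                f"exactly one assigned_diagnosis feature required, got "
                f"{len(assigned)}: {assigned}"
            )
        for fid, cat in self.category.items():
            if cat == BIOMARKER:
                if fid not in self.domain:
                    raise ValueError(f"biomarker {fid!r} lacks a domain tag")
                if self.domain[fid] not in BIOMARKER_DOMAINS:
                    raise ValueError(
                        f"biomarker {fid!r}: unknown domain {self.domain[fid]!r}"
                    )
            elif fid in self.domain:
                raise ValueError(
                    f"feature {fid!r} has a domain tag but is not a biomarker"
                )

    def assigned_diagnosis_features(self) -> list[str]:
        return [f for f, c in self.category.items() if c == ASSIGNED_DIAGNOSIS]

    @property
    def assigned_diagnosis_feature(self) -> str:
        return self.assigned_diagnosis_features()[0]

    def features_of(self, category: str) -> list[str]:
        return [f for f, c in self.category.items() if c == category]

    @property
    def clinical_features(self) -> list[str]:
        return self.features_of(CLINICAL)

    @property
    def biomarker_features(self) -> list[str]:
        return self.features_of(BIOMARKER)

    def validate_against(self, feature_ids: Iterable[str]) -> None:
        """Every table feature must have exactly one category entry."""
        missing = [f for f in feature_ids if f not in self.category]
        if missing:
            raise ValueError(
                f"{len(missing)} table feature(s) absent from category map, "
                f"first: {missing[0]!r}"
            )


@dataclass
class DiagnosisLabels:
    """Optional per-subject binary external diagnosis (e.g. DSM PTSD)."""

    subject_ids: list[str]
    values: np.ndarray  # 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 1 or len(self.values) != len(self.subject_ids):
            raise ValueError("labels length must equal subject count")
        bad = set(np.unique(self.values)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary, found {sorted(bad)}")


@dataclass
class RunReport:
    """Serializable record of one full pipeline run."""

    seed: int
    config_hash: str
    created: str
    screening: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    association: dict[str, Any] | None = None
    classifier: dict[str, Any] = field(default_factory=dict)
    stability: list[dict[str, Any]] = field(default_factory=list)
    profiles: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunReport":
        return cls(**{k: d[k] for k in (f.name for f in dataclasses.fields(cls)) if k in d})


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, delimiter: str = ",") -> FeatureTable:
    """Read a subjects x features CSV (first row feature ids, first column
    subject ids). Empty cells and ``NA`` mark missing values; any other
    non-numeric cell is an error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    _check_unique([h.strip() for h in header], "feature id")
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=False,
    )
    subject_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    _check_unique(subject_ids, "subject id")
    _check_unique(feature_ids, "feature id")
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(raw):
        cell = "" if cell is None else str(cell).strip()
        if cell in MISSING_TOKENS:
            values[i, j] = np.nan
            mask[i, j] = True
        else:
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at subject "
                    f"{subject_ids[i]!r}, feature {feature_ids[j]!r}"
                ) from None
    return FeatureTable(subject_ids, feature_ids, values, mask)


def write_feature_table(table: FeatureTable, path: str | Path,
                        delimiter: str = ",") -> None:
    """Write the table as CSV; missing entries become empty cells."""
    df = table.to_dataframe().copy()
    arr = df.to_numpy()
    arr[table.missing_mask] = np.nan
    df = pd.DataFrame(arr, index=df.index, columns=df.columns)
    df.to_csv(path, sep=delimiter, na_rep="")


def read_category_map(path: str | Path,
                      feature_ids: Iterable[str] | None = None
                      ) -> FeatureCategories:
    """Read a YAML feature->category map.

    Entries are ``feature: category`` or ``feature: biomarker/domain``.
    If ``feature_ids`` is given, coverage of those features is enforced.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError("category map must be a mapping of feature -> category")
    category: dict[str, str] = {}
    domain: dict[str, str] = {}
    for fid, entry in raw.items():
        fid = str(fid)
        entry = str(entry)
        if "/" in entry:
            cat, dom = entry.split("/", 1)
            category[fid] = cat.strip()
            domain[fid] = dom.strip()
        else:
            category[fid] = entry.strip()
    cats = FeatureCategories(category, domain)
    if feature_ids is not None:
        cats.validate_against(feature_ids)
    return cats


def write_category_map(categories: FeatureCategories, path: str | Path) -> None:
    entries = {}
    for fid, cat in categories.category.items():
        if cat == BIOMARKER:
            entries[fid] = f"{cat}/{categories.domain[fid]}"
        else:
            entries[fid] = cat
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def read_diagnosis_labels(path: str | Path) -> DiagnosisLabels:
    """Read a two-column CSV ``subject_id,diagnosis`` with 0/1 payload."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("diagnosis label file needs subject_id and label columns")
    return DiagnosisLabels(
        [str(s) for s in df.iloc[:, 0]], df.iloc[:, 1].to_numpy(dtype=int)
    )


def write_diagnosis_labels(labels: DiagnosisLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": labels.subject_ids, "diagnosis": labels.values}
    ).to_csv(path, index=False)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable SHA-256 of a canonical JSON rendering of the configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(report: RunReport, path: str | Path) -> None:
    """Serialize the run report as JSON plus a ``.txt`` plain summary.

    Re-reading the JSON with :func:`read_report` reproduces every numeric
    field exactly (floats round-trip through repr).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, cls=_NumpyEncoder)
    summary = _render_summary(report)
    path.with_suffix(".txt").write_text(summary, encoding="utf-8")


def read_report(path: str | Path) -> RunReport:
    with open(path, "r", encoding="utf-8") as fh:
        return RunReport.from_dict(json.load(fh))


def _render_summary(report: RunReport) -> str:
    lines = [
        "3C pipeline run report",
        "======================",
        f"seed:        {report.seed}",
        f"config hash: {report.config_hash}",
        f"created:     {report.created}",
        "",
    ]
    if report.screening:
        lines.append("Clinical screening (vs assigned diagnosis):")
        for row in report.screening.get("table", []):
            lines.append(
                "  {feature:<12} r={r:+.3f}  p={p:.3g}  p_adj={p_adj:.3g}  "
                "{sel}".format(
                    feature=row["feature"], r=row.get("r", float("nan")),
                    p=row["p"], p_adj=row["p_adj"],
                    sel="selected" if row["selected"] else "dropped",
                )
            )
        lines.append("")
    if report.cluster:
        c = report.cluster
        lines.append(
            f"Clustering: k={c.get('k')} (metric={c.get('metric')}, "
            f"mean silhouette={c.get('mean_silhouette'):.3f})"
        )
        lines.append(f"  sizes: {c.get('sizes')}")
        lines.append(f"  rationale: {c.get('rationale')}")
        lines.append("")
    if report.association:
        a = report.association
        lines.append(
            f"Cluster-diagnosis association: Z={a['z']:.2f} p={a['p']:.2g} "
            f"(proportions {a['p1']:.2f} vs {a['p2']:.2f})"
        )
        lines.append("")
    if report.classifier:
        top = report.classifier.get("importance", [])[:10]
        if top:
            lines.append("Top biomarkers by mean decrease Gini:")
            for row in top:
                lines.append(
                    f"  {row['rank']:>2}. {row['domain']}:{row['feature']}"
                    f"  importance={row['gini_importance']:.3f}"
                )
            lines.append("")
        if "tree_text" in report.classifier:
            lines.append("Classification tree:")
            lines.append(report.classifier["tree_text"])
            lines.append("")
        anova = report.classifier.get("anova_summary")
        if anova:
            lines.append(
                f"Marginal ANOVA: {anova['n_significant']} of "
                f"{anova['n_features']} biomarkers significant at "
                f"FDR {anova['q']}"
            )
            lines.append("")
    if report.stability:
        lines.append("Stability (train/validate cluster matching):")
        lines.append("  P%   mean%   SD%   frac k=2")
        for row in report.stability:
            fk = row.get("frac_k2")
            lines.append(
                f"  {row['p_train']*100:>3.0f} {row['mean_matched_pct']:>6.1f} "
                f"{row['sd_matched_pct']:>6.1f}   "
                + (f"{fk:.2f}" if fk is not None else "fixed")
            )
        lines.append("")
    return "\n".join(lines) + "\n"
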