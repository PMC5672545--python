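"""Count QC and normalization.

Stage II of the pipeline: drop near-empty features, drop shallow samples,
inspect the shared vehicle controls (PCA, pairwise correlations, and the
"D statistic" — each control's mean correlation with the remaining controls,
with a 3-SD exclusion rule), then compute median-of-ratios size factors and
a normalized count matrix for the downstream dose–response stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

PSEUDOCOUNT = 0.5  # pseudocount used in every log2 transform of counts


def log2_counts(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """log2(count + 0.5), the transform used throughout QC and trend testing."""
    return np.log2(np.asarray(counts, dtype=float) + PSEUDOCOUNT)


def read_layout(path, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Read the experimental layout ("hash file") as TSV/CSV.

    Required columns: sample_id, chemical, conc_uM, is_vehicle.  Extra
    columns pass through untouched.  When ``sample_ids`` is given, every one
    must appear exactly once.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = ["sample_id", "chemical", "conc_uM", "is_vehicle"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"layout file {path} is missing required column(s): {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["conc_uM"] = pd.to_numeric(df["conc_uM"], errors="coerce").fillna(0.0)
    if df["is_vehicle"].dtype != bool:
        df["is_vehicle"] = (
            df["is_vehicle"].astype(str).str.strip().str.lower().isin(("1", "true", "yes"))
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in layout: {dupes[:5]}")
    if sample_ids is not None:
        have = set(df["sample_id"])
        absent = [s for s in sample_ids if s not in have]
        if absent:
            raise ValueError(f"count-matrix column(s) missing from layout: {absent[:5]}")
    return df


@dataclass
class QCReport:
    """Book-keeping for one QC pass; conservation holds by construction."""

    genes_in: int = 0
    genes_removed: int = 0
    genes_kept: int = 0
    removed_genes: list[str] = field(default_factory=list)
    samples_in: int = 0
    samples_removed_lowcount: int = 0
    controls_removed_dstat: int = 0
    samples_kept: int = 0
    removed_samples: list[str] = field(default_factory=list)
    excluded_controls: list[str] = field(default_factory=list)
    d_statistic: dict[str, float] = field(default_factory=dict)
    d_threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "genes_in": self.genes_in,
            "genes_removed": self.genes_removed,
            "genes_kept": self.genes_kept,
            "removed_genes": list(self.removed_genes),
            "samples_in": self.samples_in,
            "samples_removed_lowcount": self.samples_removed_lowcount,
            "controls_removed_dstat": self.controls_removed_dstat,
            "samples_kept": self.samples_kept,
            "removed_samples": list(self.removed_samples),
            "excluded_controls": list(self.excluded_controls),
            "d_statistic": dict(self.d_statistic),
            "d_threshold": self.d_threshold,
        }


def filter_features(
    counts: pd.DataFrame, min_row_total: int = 2
) -> tuple[pd.DataFrame, QCReport]:
    """Drop features whose total count across samples is below ``min_row_total``.

    The default keeps rows with >1 count experiment-wide.
    """
    totals = counts.sum(axis=1)
    keep = totals >= min_row_total
    if not keep.any():
        raise ValueError("no features pass the feature filter")
    report = QCReport(
        genes_in=counts.shape[0],
        genes_removed=int((~keep).sum()),
        genes_kept=int(keep.sum()),
        removed_genes=counts.index[~keep].tolist(),
        samples_in=counts.shape[1],
        samples_kept=counts.shape[1],
    )
    return counts.loc[keep], report


def filter_samples(
    counts: pd.DataFrame, min_col_total: int = 100_000
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples whose column total falls below the minimum depth.

    Columns at exactly the threshold are kept.
    """
    totals = counts.sum(axis=0)
    keep = totals >= min_col_total
    if not keep.any():
        raise ValueError("no samples pass the depth filter")
    report = QCReport(
        genes_in=counts.shape[0],
        genes_kept=counts.shape[0],
        samples_in=counts.shape[1],
        samples_removed_lowcount=int((~keep).sum()),
        samples_kept=int(keep.sum()),
        removed_samples=counts.columns[~keep].tolist(),
    )
    return counts.loc[:, keep], report


def control_pca(
    counts: pd.DataFrame,
    layout: pd.DataFrame,
    n_components: int = 3,
) -> tuple[pd.DataFrame, np.ndarray] | None:
    """PCA of vehicle-control samples on log2(count+0.5), gene-centered.

    Diagnostic only — no automatic exclusion.  Returns (scores, variance
    explained ratio) or None (with a warning) when fewer than 3 controls.
    """
    controls = layout.loc[layout["is_vehicle"], "sample_id"]
    controls = [s for s in controls if s in counts.columns]
    if len(controls) < 3:
        warnings.warn("fewer than 3 vehicle controls; skipping control PCA", stacklevel=2)
        return None
    X = log2_counts(counts[controls])
    X = X - X.mean(axis=1, keepdims=True)  # center each gene across controls
    n_components = min(n_components, len(controls) - 1)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X.T)
    scores_df = pd.DataFrame(
        scores, index=controls, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return scores_df, pca.explained_variance_ratio_


def pairwise_control_correlations(
    counts: pd.DataFrame, controls: Sequence[str], method: str = "pearson"
) -> pd.DataFrame:
    """Symmetric correlation matrix of controls on log2(count+0.5) values."""
    X = pd.DataFrame(log2_counts(counts[list(controls)]), columns=list(controls))
    return X.corr(method=method)


def d_statistic(
    counts: pd.DataFrame,
    controls: Sequence[str],
    sd_cut: float = 3.0,
    method: str = "pearson",
) -> tuple[pd.Series, list[str], float | None]:
    """Per-control D statistic and single-pass 3-SD outlier exclusion.

    D_i is control i's mean correlation with the other controls, computed on
    log2(count+0.5) values.  Controls with D_i below mean(D) − sd_cut·sd(D)
    are excluded; the rule is applied once (no re-iteration).  Degenerate
    zero-variance controls are excluded outright since their correlation is
    undefined.  Returns (D series, excluded ids, threshold or None).
    """
    controls = list(controls)
    if len(controls) < 4:
        raise ValueError("D statistic needs at least 4 controls")
    X = log2_counts(counts[controls])
    sds = X.std(axis=0)
    degenerate = [c for c, s in zip(controls, sds) if s == 0]
    if degenerate:
        warnings.warn(
            f"control(s) {degenerate} have zero variance; correlation undefined, excluded",
            stacklevel=2,
        )
    ok = [c for c in controls if c not in degenerate]
    corr = pairwise_control_correlations(counts, ok, method=method)
    n = len(ok)
    d = (corr.sum(axis=1) - 1.0) / (n - 1)
    sd = float(d.std(ddof=1))
    excluded = list(degenerate)
    threshold = None
    if sd > 0:  # identical controls give sd 0: nothing to exclude
        threshold = float(d.mean()) - sd_cut * sd
        excluded += d.index[d < threshold].tolist()
    return d, excluded, threshold


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the standard NB count normalization).

    For every gene with nonzero counts in all samples, compute the ratio of
    each sample's count to the gene's geometric mean across samples; a
    sample's size factor is the median of its ratios.  When no gene is
    positive everywhere, fall back to total-count scaling (factors
    proportional to column sums, geometric mean 1) with a warning.
    """
    K = counts.to_numpy(dtype=float)
    positive = (K > 0).all(axis=1)
    if not positive.any():
        warnings.warn(
            "no gene has nonzero counts in every sample; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = K.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count; cannot compute size factors")
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        logK = np.log(K[positive])
        log_geomean = logK.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logK - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample's counts by its size factor."""
    sf = size_factors(counts)
    return counts / sf, sf


def run_qc(
    counts: pd.DataFrame,
    layout: pd.DataFrame,
    min_row_total: int = 2,
    min_col_total: int = 100_000,
    d_sd: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, QCReport]:
    """Full stage-II pass: feature filter → sample filter → control D-statistic
    exclusion → size-factor normalization.

    Returns (cleaned counts, normalized counts, size factors, report).
    """
    filtered, rep_f = filter_features(counts, min_row_total)
    filtered, rep_s = filter_samples(filtered, min_col_total)
    report = QCReport(
        genes_in=rep_f.genes_in,
        genes_removed=rep_f.genes_removed,
        genes_kept=rep_f.genes_kept,
        removed_genes=rep_f.removed_genes,
        samples_in=rep_s.samples_in,
        samples_removed_lowcount=rep_s.samples_removed_lowcount,
        removed_samples=list(rep_s.removed_samples),
    )
    controls = [
        s
        for s in layout.loc[layout["is_vehicle"], "sample_id"]
        if s in filtered.columns
    ]
    if len(controls) >= 4:
        d, excluded, threshold = d_statistic(filtered, controls, sd_cut=d_sd)
        report.d_statistic = {k: float(v) for k, v in d.items()}
        report.d_threshold = threshold
        report.excluded_controls = excluded
        report.controls_removed_dstat = len(excluded)
        filtered = filtered.drop(columns=excluded)
    else:
        warnings.warn("fewer than 4 controls; skipping D-statistic exclusion", stacklevel=2)
    report.samples_kept = filtered.shape[1]
    report.removed_samples = report.removed_samples + list(report.excluded_controls)
    normalized, sf = normalize(filtered)
    return filtered, normalized, sf, report
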