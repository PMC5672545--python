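"""End-to-end orchestration: counts -> QC -> DE -> flags -> fits -> PODs.

Every stage's outputs are written as plain TSV/JSON under the run directory
and become the next stage's inputs; a machine-readable run manifest records
the configuration, package version, and input hashes.  Given a fixed
configuration and seed the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cr_models import MODEL_NAMES, fit_series, pod_summary
from .diffexpr import deg_count, l2fc_dispersion_summary, l2fc_pca, nb_test
from .probe_counts import count_directory, parse_manifest
from .qc_normalize import read_layout, run_qc
from .trend_flags import ROUTE_MANUAL, ROUTE_POD_MAX, build_series, compute_flags

log = logging.getLogger("crpod")

_FLOAT_FMT = "%.8g"


@dataclass
class RunConfig:
    """All knobs for a pipeline run, with the reference defaults."""

    counts: str | None = None  # precomputed count matrix (TSV/CSV)
    fastq_dir: str | None = None  # or: FASTQ directory + probe manifest
    manifest: str | None = None
    layout: str = ""
    out_dir: str = "crpod_run"
    min_row_total: int = 2
    min_col_total: int = 100_000
    d_sd: float = 3.0
    de_alpha: float = 0.05
    flag_q: float = 0.05
    bsd_multiplier: float = 1.0
    max_mismatch: int = 2
    trend_mode: str = "auto"
    n_mc: int = 10_000
    seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_counts(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = "gene"
    return df


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    # stage I: counts -----------------------------------------------------
    if config.counts:
        log.info("stage I: loading precomputed counts from %s", config.counts)
        counts = read_counts(config.counts)
        inputs["counts"] = _sha256(Path(config.counts))
    elif config.fastq_dir and config.manifest:
        log.info("stage I: counting FASTQ directory %s", config.fastq_dir)
        manifest = parse_manifest(config.manifest)
        inputs["manifest"] = _sha256(Path(config.manifest))
        result = count_directory(config.fastq_dir, manifest, config.max_mismatch)
        counts = result.gene_counts
        _write(result.probe_counts, out / "probe_counts.tsv")
        _write(result.summary, out / "alignment_summary.tsv")
    else:
        raise ValueError("config must provide either 'counts' or 'fastq_dir' + 'manifest'")
    _write(counts, out / "counts_raw.tsv")

    layout = read_layout(config.layout, sample_ids=counts.columns)
    inputs["layout"] = _sha256(Path(config.layout))

    # stage II: QC + normalization ----------------------------------------
    log.info("stage II: QC and normalization")
    cleaned, normalized, sf, qc_report = run_qc(
        counts, layout, config.min_row_total, config.min_col_total, config.d_sd
    )
    _write(cleaned, out / "counts_cleaned.tsv")
    _write(normalized, out / "counts_normalized.tsv")
    _write(sf.to_frame(), out / "size_factors.tsv")
    (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
    layout_kept = layout[layout["sample_id"].isin(cleaned.columns)].reset_index(drop=True)

    chemicals = sorted(
        layout_kept.loc[~layout_kept["is_vehicle"], "chemical"].unique().tolist()
    )

    # stage III: differential expression at max dose ----------------------
    log.info("stage III: differential expression for %d chemicals", len(chemicals))
    de_results: dict[str, pd.DataFrame] = {}
    deg_counts: dict[str, int] = {}
    for chem in chemicals:
        res = nb_test(cleaned, layout_kept, chem, size_factors=sf)
        de_results[chem] = res
        deg_counts[chem] = deg_count(res, config.de_alpha)
        _write(res, out / f"de_{chem}.tsv")
    de_summary: dict = {"alpha": config.de_alpha, "deg_counts": deg_counts}
    if len(chemicals) >= 2:
        scores, evr = l2fc_pca(de_results)
        _write(scores, out / "de_l2fc_pca.tsv")
        de_summary["l2fc_pca_variance_explained"] = [float(v) for v in evr]
    _write(l2fc_dispersion_summary(de_results), out / "de_l2fc_summary.tsv")
    (out / "de_summary.json").write_text(json.dumps(de_summary, indent=2))

    # stage IV-a: trend flags ---------------------------------------------
    log.info("stage IV-a: statistical flags")
    flag_tables = {}
    for i, chem in enumerate(chemicals):
        flags = compute_flags(
            normalized,
            layout_kept,
            chem,
            q_threshold=config.flag_q,
            trend_mode=config.trend_mode,
            n_mc=config.n_mc,
            seed=config.seed + i,
        )
        flag_tables[chem] = flags
        _write(flags, out / f"flags_{chem}.tsv")
    manual = pd.concat(
        [t[t["route"] == ROUTE_MANUAL] for t in flag_tables.values()]
    ) if flag_tables else pd.DataFrame()
    _write(manual, out / "manual_review.tsv")

    # stage IV-b: model fitting + POD -------------------------------------
    log.info("stage IV-b: concentration-response fits and PODs")
    fit_rows, pod_rows, pods = [], [], []
    for chem in chemicals:
        flags = flag_tables[chem]
        for gene, row in flags.iterrows():
            series = build_series(normalized, layout_kept, gene, chem)
            fits, pod = fit_series(
                series, row["route"], config.bsd_multiplier, config.models
            )
            pods.append(pod)
            pod_rows.append(
                {
                    "gene": gene,
                    "chemical": chem,
                    "route": row["route"],
                    "winner": pod.model,
                    "direction": pod.direction,
                    "pod_log10uM": pod.pod_log10uM,
                    "pod_uM": pod.pod_uM,
                    "bsd": pod.bsd,
                    "basis": pod.basis,
                    "extrapolated": pod.extrapolated,
                }
            )
            if fits is not None:
                for f in fits.values():
                    fit_rows.append(
                        {
                            "gene": gene,
                            "chemical": chem,
                            "model": f.model,
                            "params": json.dumps(
                                {k: round(v, 8) for k, v in f.params.items()}, sort_keys=True
                            ),
                            "loglik": f.loglik,
                            "aic": f.aic,
                            "converged": f.converged,
                            "direction": f.direction,
                        }
                    )
    pods_df = pd.DataFrame(pod_rows)
    _write(pods_df, out / "pods.tsv", index=False)
    _write(pd.DataFrame(fit_rows), out / "fits.tsv", index=False)
    dist, freq = pod_summary(pods)
    _write(dist, out / "pod_distribution.tsv", index=False)
    _write(freq, out / "winner_models.tsv", index=False)

    manifest_doc = {
        "crpod_version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": inputs,
        "stages": {
            "qc": qc_report.to_dict(),
            "de": de_summary,
            "flags": {c: t["route"].value_counts().to_dict() for c, t in flag_tables.items()},
            "pods": {"n": len(pod_rows)},
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_doc, indent=2, default=str))
    log.info("run complete: %s", out)
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "run_manifest.json").read_text())
    pods = pd.read_csv(run_dir / "pods.tsv", sep="\t")
    lines = [f"crpod run report — {run_dir}", ""]
    qc = manifest["stages"]["qc"]
    lines.append(
        f"QC: {qc['genes_kept']}/{qc['genes_in']} genes kept; "
        f"{qc['samples_removed_lowcount']} low-count sample(s) removed; "
        f"{qc['controls_removed_dstat']} control(s) excluded by D statistic"
    )
    lines.append("DEGs at max dose (padj < %s):" % manifest["stages"]["de"]["alpha"])
    for chem, n in manifest["stages"]["de"]["deg_counts"].items():
        lines.append(f"  {chem}: {n}")
    lines.append("Decision routes:")
    for chem, routes in manifest["stages"]["flags"].items():
        lines.append(f"  {chem}: " + ", ".join(f"{k}={v}" for k, v in sorted(routes.items())))
    fitted = pods[pods["basis"] == "curve_crossing"]
    if len(fitted):
        lines.append("Winning models (fitted pairs): " +
                     ", ".join(f"{k}={v}" for k, v in fitted["winner"].value_counts().items()))
        med = fitted.groupby("chemical")["pod_log10uM"].median()
        lines.append("Median POD (log10 uM) by chemical: " +
                     ", ".join(f"{c}={v:.3g}" for c, v in med.items()))
    n_manual = int((pods["route"] == ROUTE_MANUAL).sum()) if "route" in pods else 0
    lines.append(f"Pairs flagged for manual review: {n_manual}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
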