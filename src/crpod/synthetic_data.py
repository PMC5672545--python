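"""Synthetic fixtures for every pipeline stage.

Emulates a targeted-panel concentration-response experiment: a ~3,000-probe
manifest, barcode-free single-end FASTQ reads that are probe copies with iid
substitution errors, and negative-binomial count matrices on a shared
vehicle-control plate layout with a spiked subset of dose-responsive genes
whose mean log2 expression follows a known Hill (or gain-loss) curve.
QC defects — shallow samples, near-empty probe rows, and a shuffled outlier
control — can be planted with known identities.

Every output is a deterministic function of the configuration and seed, and
a truth table is emitted alongside so downstream stages can be scored
without re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cr_models import gainloss_curve, hill3_curve, hill3_pod_closed_form
from .probe_counts import ProbeManifest
from .trend_flags import vehicle_pseudo_dose

_DEFAULT_CHEMICALS = {
    "chemA": [0.1, 1.0, 10.0],
    "chemB": [0.1, 1.0, 10.0],
    "chemC": [0.1, 1.0, 10.0],
    "chemD": [0.1, 1.0, 10.0],
}


@dataclass
class SimConfig:
    """Study-design and noise parameters for the count simulator.

    Defaults mirror the reference design: a 2,982-gene panel, 24 shared
    vehicle controls, four chemicals at {0.1, 1, 10} uM with one replicate
    per concentration, a mean depth of ~200 reads per gene, and NB
    overdispersion 0.05 (variance mu + alpha*mu^2).
    """

    n_genes: int = 2982
    n_controls: int = 24
    chemicals: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_CHEMICALS.items()}
    )
    n_replicates: int = 1
    mean_count: float = 200.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.05
    fraction_responsive: float = 0.05
    depth_lognorm_sd: float = 0.1
    # truth-parameter ranges for responsive genes (log2-response units / log10 uM)
    tp_range: tuple[float, float] = (0.75, 2.5)
    ga_range: tuple[float, float] = (-1.5, 0.5)
    gw_range: tuple[float, float] = (0.5, 3.0)
    gainloss_fraction: float = 0.2
    down_fraction: float = 0.5
    # planted QC defects
    n_weak_genes: int = 0  # rows forced to total count <= 1
    n_low_count_samples: int = 0  # columns thinned below the depth threshold
    low_count_keep: float = 0.05  # binomial thinning rate for those columns
    n_outlier_controls: int = 0  # control columns with shuffled gene values
    seed: int = 0

    def sample_layout(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"ctrl_{i+1:02d}", "chemical": "vehicle", "conc_uM": 0.0, "is_vehicle": True}
            for i in range(self.n_controls)
        ]
        for chem, concs in self.chemicals.items():
            for c in concs:
                for r in range(self.n_replicates):
                    suffix = f"_r{r+1}" if self.n_replicates > 1 else ""
                    rows.append(
                        {
                            "sample_id": f"{chem}_{c:g}uM{suffix}",
                            "chemical": chem,
                            "conc_uM": float(c),
                            "is_vehicle": False,
                        }
                    )
        return pd.DataFrame(rows)


def preset(name: str) -> SimConfig:
    """Named study designs.

    ``study-like``: 24 shared controls, 4 chemicals x {0.1, 1, 10} uM x 1
    replicate.  ``replicate3``: 12 controls and three concentrations with
    three replicates each (the illustrative replicated design).
    """
    if name == "study-like":
        return SimConfig()
    if name == "replicate3":
        return SimConfig(n_controls=12, n_replicates=3)
    raise ValueError(f"unknown preset {name!r}")


def _draw_truth(cfg: SimConfig, rng: np.random.Generator, genes: list[str]) -> pd.DataFrame:
    n_resp = int(round(cfg.fraction_responsive * cfg.n_genes))
    responsive = rng.choice(cfg.n_genes, size=n_resp, replace=False)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "responsive": False,
            "model": "none",
            "direction": "none",
            "tp": np.nan,
            "ga": np.nan,
            "gw": np.nan,
            "la": np.nan,
            "lw": np.nan,
        }
    ).set_index("gene")
    for idx in responsive:
        g = genes[idx]
        model = "gainloss" if rng.random() < cfg.gainloss_fraction else "hill3"
        tp = rng.uniform(*cfg.tp_range)
        ga = rng.uniform(*cfg.ga_range)
        gw = rng.uniform(*cfg.gw_range)
        direction = "down" if rng.random() < cfg.down_fraction else "up"
        truth.loc[g, ["responsive", "model", "direction", "tp", "ga", "gw"]] = [
            True, model, direction, tp, ga, gw,
        ]
        if model == "gainloss":
            truth.loc[g, "la"] = ga + rng.uniform(0.5, 1.5)
            truth.loc[g, "lw"] = rng.uniform(*cfg.gw_range)
    return truth


def _truth_shift(truth_row: pd.Series, log10_dose: float) -> float:
    """Mean log2-expression shift of a responsive gene at one dose."""
    if not truth_row["responsive"]:
        return 0.0
    if truth_row["model"] == "hill3":
        shift = hill3_curve(log10_dose, truth_row["tp"], truth_row["ga"], truth_row["gw"])
    else:
        shift = gainloss_curve(
            log10_dose, truth_row["tp"], truth_row["ga"], truth_row["gw"],
            truth_row["la"], truth_row["lw"],
        )
    return float(-shift if truth_row["direction"] == "down" else shift)


def simulate_counts(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an NB count matrix plus layout and truth tables.

    Baseline log2 expression is Gaussian across genes (centered so the mean
    count matches ``mean_count``); responsive genes shift their mean log2
    expression by the generating curve at each dose; counts are NB with
    variance mu + alpha*mu^2 at per-sample depth factors.  Planted defects
    are injected last, so they override the clean signal.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = [f"G{i+1:04d}" for i in range(cfg.n_genes)]
    layout = cfg.sample_layout()
    samples = layout["sample_id"].tolist()

    base_log2 = np.log2(cfg.mean_count) + rng.normal(0.0, cfg.baseline_log2_sd, cfg.n_genes)
    depth = np.exp(rng.normal(0.0, cfg.depth_lognorm_sd, len(samples)))
    truth = _draw_truth(cfg, rng, genes)

    # per-sample shift vector for responsive genes
    resp_idx = np.flatnonzero(truth["responsive"].to_numpy())
    shifts = np.zeros((cfg.n_genes, len(samples)))
    for j, row in enumerate(layout.itertuples()):
        if row.is_vehicle:
            continue
        ld = np.log10(row.conc_uM)
        for gi in resp_idx:
            shifts[gi, j] = _truth_shift(truth.iloc[gi], ld)

    mu = depth[None, :] * 2.0 ** (base_log2[:, None] + shifts)
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)

    # planted defects ------------------------------------------------------
    treated_cols = layout.index[~layout["is_vehicle"]].tolist()
    if cfg.n_low_count_samples:
        low = rng.choice(treated_cols, size=cfg.n_low_count_samples, replace=False)
        for j in low:
            counts_df.iloc[:, j] = rng.binomial(counts_df.iloc[:, j], cfg.low_count_keep)
        layout["planted_low_count"] = False
        layout.loc[low, "planted_low_count"] = True

    ctrl_cols = layout.index[layout["is_vehicle"]].tolist()
    if cfg.n_outlier_controls:
        out = rng.choice(ctrl_cols, size=cfg.n_outlier_controls, replace=False)
        for j in out:
            counts_df.iloc[:, j] = rng.permutation(counts_df.iloc[:, j].to_numpy())
        layout["planted_outlier_control"] = False
        layout.loc[out, "planted_outlier_control"] = True

    # weak rows go in last so no other defect can re-populate them
    truth["planted_weak"] = False
    if cfg.n_weak_genes:
        weak = rng.choice(cfg.n_genes, size=cfg.n_weak_genes, replace=False)
        counts_df.iloc[weak, :] = 0
        # alternate row totals of 0 and 1 to cover both sub-threshold cases
        for k, gi in enumerate(weak):
            if k % 2 == 0:
                counts_df.iloc[gi, 0] = 1
        truth.iloc[weak, truth.columns.get_loc("planted_weak")] = True

    # closed-form expected POD for hill3 truths at the analytic BSD scale
    ref_bsd = np.sqrt((1.0 / cfg.mean_count + cfg.dispersion)) / np.log(2.0)
    pods = []
    for g in genes:
        row = truth.loc[g]
        if row["responsive"] and row["model"] == "hill3":
            pods.append(hill3_pod_closed_form(row["tp"], row["ga"], row["gw"], ref_bsd))
        else:
            pods.append(None)
    truth["expected_pod_log10uM"] = [np.nan if p is None else p for p in pods]
    return counts_df, layout, truth.reset_index()


# ---------------------------------------------------------------------------
# FASTQ simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_manifest(
    n_probes: int = 24,
    length: int = 50,
    seed: int = 0,
    shared_gene_pairs: int = 0,
    ambiguous_pair: bool = False,
) -> ProbeManifest:
    """Random probe manifest: distinct sequences, optionally with probe pairs
    sharing a gene symbol and one near-identical cross-gene pair."""
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n_probes:
        s = "".join(chr(b) for b in rng.choice(_BASES, size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    probe_ids = [f"P{i+1:04d}" for i in range(n_probes)]
    gene_symbols = [f"GENE{i+1:04d}" for i in range(n_probes)]
    for k in range(shared_gene_pairs):
        # probes 2k and 2k+1 report the same gene
        gene_symbols[2 * k + 1] = gene_symbols[2 * k]
    if ambiguous_pair and n_probes >= 2:
        # make the last two probes (distinct genes) differ at a single base
        s = list(seqs[-2])
        s[0] = "A" if s[0] != "A" else "C"
        seqs[-1] = "".join(s)
    return ProbeManifest(probe_ids, gene_symbols, seqs)


def simulate_fastq(
    manifest: ProbeManifest,
    composition: dict[str, dict[str, int]],
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> pd.DataFrame:
    """Write per-sample FASTQ files of probe copies with substitution errors.

    ``composition`` maps sample id -> {probe_id: n_reads}.  Errors are iid
    base substitutions at ``error_rate`` per position.  Returns the truth
    count table (probes x samples) of generated reads.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx = {p: i for i, p in enumerate(manifest.probe_ids)}
    L = manifest.length
    truth = pd.DataFrame(
        0, index=pd.Index(manifest.probe_ids, name="probe_id"), columns=list(composition)
    )
    for sample, probes in composition.items():
        lines = []
        read_no = 0
        for probe_id, n_reads in probes.items():
            seq_arr = np.frombuffer(manifest.sequences[idx[probe_id]].encode(), dtype=np.uint8)
            for _ in range(int(n_reads)):
                read = seq_arr.copy()
                if error_rate > 0:
                    hit = np.flatnonzero(rng.random(L) < error_rate)
                    if hit.size:
                        read[hit] = _BASES[rng.integers(0, 4, size=hit.size)]
                read_no += 1
                lines.append(f"@{sample}:{read_no} src={probe_id}")
                lines.append(read.tobytes().decode())
                lines.append("+")
                lines.append("I" * L)
            truth.loc[probe_id, sample] += int(n_reads)
        (out_dir / f"{sample}.fastq").write_text("\n".join(lines) + ("\n" if lines else ""))
    return truth


def write_fixture_bundle(
    config: SimConfig | None = None,
    out_dir: str | Path = "fixtures",
    seed: int | None = None,
    with_fastq: bool = False,
    n_fastq_reads: int = 200,
) -> Path:
    """Write a self-describing fixture directory: counts.tsv, layout.tsv,
    truth.tsv, config.json, and optionally a small manifest + FASTQ set."""
    cfg = config or SimConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, layout, truth = simulate_counts(cfg, seed)
    counts.to_csv(out_dir / "counts.tsv", sep="\t")
    layout.to_csv(out_dir / "layout.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    (out_dir / "config.json").write_text(json.dumps(asdict(cfg), indent=2, default=list))
    if with_fastq:
        rng_seed = (cfg.seed if seed is None else seed) + 1
        manifest = random_manifest(n_probes=24, seed=rng_seed)
        rng = np.random.default_rng(rng_seed)
        composition = {}
        for s in ("fq_sample_1", "fq_sample_2"):
            per_probe = rng.multinomial(n_fastq_reads, np.ones(24) / 24)
            composition[s] = {
                p: int(c) for p, c in zip(manifest.probe_ids, per_probe) if c > 0
            }
        fq_truth = simulate_fastq(
            manifest, composition, error_rate=0.005, seed=rng_seed, out_dir=out_dir / "fastq"
        )
        pd.DataFrame(
            {
                "probe_id": manifest.probe_ids,
                "gene_symbol": manifest.gene_symbols,
                "sequence": manifest.sequences,
            }
        ).to_csv(out_dir / "manifest.csv", index=False)
        fq_truth.to_csv(out_dir / "fastq_truth.tsv", sep="\t")
    return out_dir


def expected_dose_vector(config: SimConfig, chemical: str, n_controls_kept: int) -> np.ndarray:
    """The dose vector the flag stage should build for one chemical."""
    concs = np.array(config.chemicals[chemical], dtype=float)
    pseudo = vehicle_pseudo_dose(concs)
    doses = np.sort(np.log10(np.repeat(concs, config.n_replicates)))
    return np.concatenate([np.full(n_controls_kept, pseudo), doses])
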