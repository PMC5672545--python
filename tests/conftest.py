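import numpy as np
import pandas as pd
import pytest

from crpod.probe_counts import ProbeManifest
from crpod.synthetic_data import SimConfig, simulate_counts
from crpod.trend_flags import DoseResponseSeries


@pytest.fixture
def toy_manifest() -> ProbeManifest:
    """Three probes, three genes, 10-mers (short for readability)."""
    return ProbeManifest(
        probe_ids=["P1", "P2", "P3"],
        gene_symbols=["GA", "GB", "GC"],
        sequences=["ACGTACGTAC", "TTTTCCCCGG", "GATCGATCGA"],
    )


@pytest.fixture
def toy_manifest_csv(tmp_path, toy_manifest):
    path = tmp_path / "manifest.csv"
    pd.DataFrame(
        {
            "probe_id": toy_manifest.probe_ids,
            "gene_symbol": toy_manifest.gene_symbols,
            "sequence": toy_manifest.sequences,
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_experiment():
    """A study-like layout scaled to 120 genes, with planted QC defects."""
    cfg = SimConfig(
        n_genes=120,
        fraction_responsive=0.1,
        n_weak_genes=4,
        n_outlier_controls=1,
        seed=11,
    )
    counts, layout, truth = simulate_counts(cfg)
    return cfg, counts, layout, truth


def make_series(
    dose: np.ndarray,
    response: np.ndarray,
    n_control: int,
    control_sd: float,
    gene: str = "g",
    chemical: str = "chem",
) -> DoseResponseSeries:
    """Hand-assembled series for fitting tests."""
    dose = np.asarray(dose, dtype=float)
    return DoseResponseSeries(
        gene=gene,
        chemical=chemical,
        dose=dose,
        response=np.asarray(response, dtype=float),
        is_control=np.arange(dose.size) < n_control,
        n_control=n_control,
        control_sd=control_sd,
        pseudo_dose=float(dose.min()),
        max_dose=float(dose.max()),
    )
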