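import numpy as np
import pandas as pd
import pytest

from wheatgwas import synthdata
from wheatgwas.markers import GenotypePanel


def make_panel(dosages, chroms=None, cms=None, bps=None, prefix="m"):
    """Hand-built panel from a dosage array (accessions x markers)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    marker_ids = [f"{prefix}{j}" for j in range(m)]
    mp = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr01"] * m,
            "cm": cms if cms is not None else np.linspace(0, 100, m),
            "bp": bps if bps is not None else (np.arange(m) + 1) * 10_000,
        },
        index=marker_ids,
    )
    mp.index.name = "marker"
    return GenotypePanel([f"A{i}" for i in range(n)], marker_ids, dosages, mp)


@pytest.fixture(scope="session")
def small_cfg():
    return synthdata.SimConfig(
        n_accessions=120,
        n_chromosomes=2,
        markers_per_chrom=80,
        seed=42,
        h2_targets={"yield": 0.6},
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return synthdata.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_pheno(small_cfg, small_panel):
    tab, truth = synthdata.simulate_phenotypes(small_panel, small_cfg)
    return tab, truth
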