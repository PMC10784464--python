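import numpy as np
import pandas as pd
import pytest

from metgp import genotypes, simdata


@pytest.fixture(scope="session")
def small_config():
    """A 60-hybrid, 400-SNP panel in four environments (fast to fit)."""
    return simdata.SimConfig(
        n_lines_per_group={"dent": 20, "flint": 20, "C": 5},
        n_hybrids=60, n_snps=400, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    parents, hybrids, crosses = simdata.simulate_hybrids(small_config)
    return {"config": small_config, "parents": parents, "hybrids": hybrids,
            "crosses": crosses}


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    cfg = small_panel["config"]
    effects = simdata.simulate_effects(cfg, small_panel["hybrids"])
    eblues = simdata.simulate_eblues(effects, cfg)
    A = genotypes.vanraden_A(small_panel["hybrids"])
    D = genotypes.vitezica_D(small_panel["hybrids"])
    return {**small_panel, "effects": effects, "eblues": eblues, "A": A, "D": D,
            "environments": list(cfg.environments()["environment"])}


def geno_from_array(arr, kind="hybrid", prefix="h"):
    arr = np.asarray(arr, dtype=float)
    ids = [f"{prefix}{i + 1}" for i in range(arr.shape[0])]
    markers = [f"m{j + 1}" for j in range(arr.shape[1])]
    return genotypes.GenotypeMatrix(
        pd.DataFrame(arr, index=ids, columns=markers), kind=kind)
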