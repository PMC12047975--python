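import numpy as np
import pandas as pd
import pytest

from riqtl.genotypes import FounderMap
from riqtl.simulate import QtlSpec, SimConfig, simulate_ri_genotypes, simulate_strain_phenotypes


@pytest.fixture
def small_map() -> FounderMap:
    return FounderMap.regular(n_chromosomes=2, markers_per_chromosome=10,
                              cm_spacing=5.0, mb_per_cm=2.0)


@pytest.fixture
def geno60(small_map):
    return simulate_ri_genotypes(small_map, 60, seed=11)


@pytest.fixture
def planted_trait(geno60):
    """Strain-mean trait with one planted QTL on chromosome 2 (h2 = 0.5)."""
    cfg = SimConfig(n_strains=60, qtl=(QtlSpec("2", 25.0, 1.0),),
                    heritability=0.5, seed=7)
    animals = simulate_strain_phenotypes(geno60, cfg, seed=7)
    return animals.groupby("strain")["value"].mean()


@pytest.fixture
def survival_records() -> pd.DataFrame:
    def rows(strain, deaths, n_censored):
        out = [{"strain": strain, "animal_id": f"{strain}_{i}", "survival_day": d,
                "censored": False} for i, d in enumerate(deaths)]
        out += [{"strain": strain, "animal_id": f"{strain}_c{i}", "survival_day": 10,
                 "censored": True} for i in range(n_censored)]
        return out

    return pd.DataFrame(
        rows("S1", [4, 5, 6, 7, 8], 0)
        + rows("S2", [], 6)
        + rows("S3", [4, 4], 4)
        + rows("S4", [4, 5, 6, 6, 7, 7], 4)
    )
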