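import numpy as np
import pytest

from ssgwas import io as io_mod
from ssgwas import simdata


@pytest.fixture(scope="session")
def family_pop():
    """Family-structured population: 30 founders, 3 overlapping generations
    of 15 matings x 7 offspring, 300 markers, 3 planted QTN, h2 = 0.3."""
    arch = simdata.TraitArchitecture(
        n_qtn=3, qtn_effect_sd=2.0, sigma_u2=0.3, sigma_e2=0.7, n_cg=5
    )
    return simdata.simulate_population(
        n_founders=30,
        n_generations=3,
        n_markers=300,
        litter_params=simdata.LitterParams(n_matings=15, offspring_per_mating=7),
        arch=arch,
        phenotyping_rate=0.9,
        genotyping_rate=0.5,
        seed=1,
    )


@pytest.fixture(scope="session")
def family_geno_qc(family_pop):
    return family_pop.genotypes.drop_monomorphic(min_maf=0.05)


def make_config(**overrides):
    base = dict(
        pedigree="", genotypes="", snp_map="", phenotypes="",
        sigma_u2=0.3, sigma_e2=0.7, method="exact_ginv",
        core_random=30, seed=5, out_dir="out",
    )
    base.update(overrides)
    return io_mod.RunConfig(**base)


@pytest.fixture
def tmp_config(tmp_path):
    def _make(**overrides):
        overrides.setdefault("out_dir", str(tmp_path / "out"))
        return make_config(**overrides)

    return _make
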