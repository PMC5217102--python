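"""Shared fixtures: a small simulated AIL reused across the suite.

The simulated population keeps the full pedigree design (59 founders,
nine generations, ~1539 birds) but uses two QTL regions with reduced
marker counts so the expensive stages stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ailfm.imputation import impute_pipeline
from ailfm.synthetic_data import (
    RegionSpec,
    SimulationConfig,
    build_marker_map,
    simulate_ail,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_REGIONS = (
    RegionSpec("R1", "GGA1", 1_000_000, 11_000_000, 30, 150),
    RegionSpec("R2", "GGA2", 1_000_000, 9_000_000, 25, 120),
)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    kwargs = dict(seed=seed, regions=SMALL_REGIONS)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def planted_config(seed: int = 11, effects=(18.0, 16.0, 20.0)) -> SimulationConfig:
    """Two linked QTL in R1 plus one in R2, planted on backbone markers."""
    cfg = small_config(seed)
    mm = build_marker_map(cfg)
    bb1 = mm.table[
        (mm.table.region == "R1") & (mm.table.source == "backbone")
    ]["marker"].tolist()
    bb2 = mm.table[
        (mm.table.region == "R2") & (mm.table.source == "backbone")
    ]["marker"].tolist()
    cfg.qtl_spec = (
        (bb1[8], effects[0]),
        (bb1[20], effects[1]),
        (bb2[12], effects[2]),
    )
    return cfg


@pytest.fixture(scope="session")
def sim():
    """Planted two-region AIL simulation at the default population design."""
    return simulate_ail(planted_config())


@pytest.fixture(scope="session")
def imputed_bundle(sim):
    """(ImputedGenotypes, PhasedBackbone, SegmentPainting) for ``sim``."""
    return impute_pipeline(
        sim.observed,
        sim.pedigree,
        sim.marker_map,
        sim.dense_founder_ids,
        seed=101,
    )


def phenotypes_from_truth(sim, rng: np.random.Generator, qtl=None):
    """Fresh additive phenotypes on the fixture's true genotypes.

    Independent generative oracle used to re-noise a simulated
    population without re-running meiosis: same model as the simulator
    (mu + sex + generation + sum a(d-1) + Gaussian noise).
    """
    import pandas as pd

    from ailfm.io_formats import PhenotypeTable

    cfg = sim.config
    qtl = dict(cfg.qtl_spec) if qtl is None else dict(qtl)
    ped = sim.pedigree.table
    dose = sim.haplotypes.dosages()
    gen_effect = {f"F{i + 2}": e for i, e in enumerate(cfg.generation_effects)}
    y = np.full(len(ped), np.nan)
    pheno_mask = ped["generation"].isin(gen_effect).to_numpy()
    base = (
        cfg.mu
        + np.where(ped["sex"].to_numpy() == "M", cfg.sex_effect, 0.0)
        + np.array([gen_effect.get(g, 0.0) for g in ped["generation"]])
    )
    for mid, a in qtl.items():
        base = base + a * (dose[mid].reindex(ped["id"]).to_numpy() - 1.0)
    noise = rng.normal(0.0, cfg.sigma_e, size=len(ped))
    y[pheno_mask] = (base + noise)[pheno_mask]
    return PhenotypeTable(
        pd.DataFrame(
            {
                "id": ped["id"],
                "bw56": y,
                "sex": ped["sex"],
                "generation": ped["generation"],
            }
        )
    )
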