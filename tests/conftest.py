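import numpy as np
import pandas as pd
import pytest

from strataphase import simcross
from strataphase.containers import Pedigree, QuartetGenotypes


@pytest.fixture(scope="session")
def two_strata_cfg() -> simcross.SimConfig:
    """2 Mb sex chromosome: PAR, an old and a young stratum."""
    return simcross.SimConfig(
        chrom_length_bp=2_000_000,
        par=((0, 200_000),),
        strata=(
            simcross.StratumSpec(200_000, 1_200_000, 13.0, 0.8, "old"),
            simcross.StratumSpec(1_200_000, 2_000_000, 2.0, 0.1, "young"),
        ),
        seed=5,
    )


@pytest.fixture(scope="session")
def two_strata_sim(two_strata_cfg):
    panel, truth = simcross.simulate_sex_chromosome(two_strata_cfg)
    q = simcross.simulate_quartets(panel, truth, two_strata_cfg)
    return panel, truth, q


@pytest.fixture(scope="session")
def errorfree_cfg() -> simcross.SimConfig:
    """Noise-free cross for exactness tests: no errors, dropout or low quality."""
    return simcross.SimConfig(
        chrom_length_bp=1_000_000,
        par=((0, 200_000),),
        strata=(simcross.StratumSpec(200_000, 1_000_000, 10.0, 0.5, "S"),),
        error_rate=0.0,
        missing_rate=0.0,
        low_gq_rate=0.0,
        low_qual_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def errorfree_sim(errorfree_cfg):
    panel, truth = simcross.simulate_sex_chromosome(errorfree_cfg)
    q = simcross.simulate_quartets(panel, truth, errorfree_cfg)
    return panel, truth, q


def make_quartets(
    gt_rows,
    pos=None,
    qual=None,
    dp=None,
    gq=None,
    families=1,
    chrom="chrT",
    ref=None,
    alt=None,
):
    """Hand-built QuartetGenotypes: one row per site, samples in
    father/mother/son/daughter blocks per family."""
    gt = np.asarray(gt_rows, dtype=np.int8)
    n_sites, n_samples = gt.shape
    assert n_samples == 4 * families
    rows = []
    samples = []
    for f in range(families):
        fam = f"F{f + 1:02d}"
        names = {r: f"{fam}_{r}" for r in ("father", "mother", "son", "daughter")}
        rows.append({"family": fam, **names})
        samples.extend(names.values())
    ped = Pedigree(pd.DataFrame(rows))
    pos = np.asarray(pos if pos is not None else np.arange(1, n_sites + 1) * 100, dtype=np.int64)
    return QuartetGenotypes(
        chrom=chrom,
        pos=pos,
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites),
        qual=np.asarray(qual if qual is not None else [999.0] * n_sites, dtype=float),
        gt=gt,
        dp=np.asarray(dp if dp is not None else np.full_like(gt, 35), dtype=np.int32),
        gq=np.asarray(gq if gq is not None else np.full_like(gt, 99), dtype=np.int16),
        ad_alt=np.zeros_like(gt, dtype=np.int32),
        samples=samples,
        pedigree=ped,
    )
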