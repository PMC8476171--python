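"""Synthetic quartet-cross generator with known sex-chromosome structure.

Simulates father–mother–son–daughter quartets segregating an XY pair whose
sex-determining region (SDR) is organised into evolutionary strata: contiguous
regions where X–Y recombination stopped at different times in the past.  The
generator works at the VCF level (genotypes, depths, qualities), not at the
read level, and encodes the observable signatures of sex-chromosome evolution:

* within a stratum that stopped recombining ``t`` My ago, X and Y alleles
  differ with the probability expected after ``2·mu·t`` substitutions;
* in the pseudoautosomal region (PAR), X and Y alleles are drawn from one
  exchangeable pool;
* genes deleted from the Y emit no Y reads, so males are hemizygous and
  their depth halves over the gene; across a stratum, male depth also
  declines with stratum age because increasingly diverged Y reads fail to
  map to an X-only reference (mappability ``exp(-rate·age)``);
* autosome-to-Y duplications show up on autosomes as inflated male depth,
  a male-restricted allele, and an alternate-read fraction below one half
  (mismapping of reads from the extra Y-linked paralog).

Mutation is infinite-sites on a fixed lattice of candidate SNP positions;
there is no back-mutation and every site is biallelic, matching the
biallelic-SNP analyses downstream.  Time is measured in My and converted to
generations at a configurable rate (default one generation per year).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, Pedigree, QuartetGenotypes

NUCS = np.array(list("ACGT"))

STOP_CODONS = ("TAA", "TAG", "TGA")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: ``[start, end)`` bp, recombination-stop age, deletion prob."""

    start: int
    end: int
    stop_age_my: float
    deletion_prob: float = 0.0
    name: str = ""


@dataclass(frozen=True)
class DuplicationSpec:
    """Autosomal window duplicated onto the Y.

    ``n_y_copies`` extra Y-linked paralogs inflate male depth;
    ``n_fixed_y_alleles`` sites in the window carry an allele fixed on the
    Y paralog and therefore restricted to males.
    """

    start: int
    end: int
    n_y_copies: int = 1
    n_fixed_y_alleles: int = 2


# Default strata mirror a ~20.6 Mb ancestral sex chromosome with a small
# terminal PAR and strata of decreasing age, the layout this pipeline is
# designed to recover (ages in My; deletion probabilities give realistic
# per-stratum hemizygosity levels).
DEFAULT_STRATA = (
    StratumSpec(400_000, 2_600_000, 7.2, 0.70, "R3"),
    StratumSpec(2_600_000, 4_800_000, 12.0, 0.77, "R2"),
    StratumSpec(4_800_000, 12_500_000, 13.0, 0.83, "R1"),
    StratumSpec(12_500_000, 20_600_000, 22.0, 0.92, "S1"),
)
DEFAULT_PAR = ((0, 400_000),)


@dataclass
class SimConfig:
    """Parameters of the synthetic cross.

    Defaults describe the study conditions this package targets: 15 quartet
    families, 35× mean coverage, mutation rate 5e-8 per site per generation,
    autosomal diversity pi = 0.001, and a 14.3 My split to the outgroup-side
    lineage (2.0 My within the sister pair).
    """

    n_families: int = 15
    chrom: str = "chrXIX"
    chrom_length_bp: int = 20_600_000
    snp_density: float = 0.01          # candidate SNP sites per bp
    mu: float = 5e-8                   # per site per generation
    generations_per_year: float = 1.0
    mean_depth: float = 35.0
    error_rate: float = 1e-3           # per-genotype miscall probability
    missing_rate: float = 0.01         # per-genotype dropout probability
    low_gq_rate: float = 0.01          # genotypes emitted with GQ < 20
    low_qual_rate: float = 0.005       # sites emitted with QUAL < 999
    pi: float = 0.001                  # per-bp nucleotide diversity (X pool)
    y_theta_per_site: float = 0.005    # private Y mutation prob per lattice site
    map_loss_rate_per_my: float = 0.085  # decay of Y-read mappability with stratum age
    seed: int = 0
    reference_seed: int | None = None  # lattice ref/alt bases; share across species
    split_times_my: tuple[float, float] = (14.3, 2.0)
    strata: tuple[StratumSpec, ...] = DEFAULT_STRATA
    par: tuple[tuple[int, int], ...] = DEFAULT_PAR
    duplications: tuple[DuplicationSpec, ...] = ()
    genes: pd.DataFrame | None = None  # columns gene_id, start, end; auto grid if None
    gene_spacing_bp: int = 20_000
    gene_length_bp: int = 5_000
    sfs_pool_size: int = 60            # chromosomes in the frequency-spectrum pool

    @property
    def mu_per_my(self) -> float:
        return self.mu * self.generations_per_year * 1e6

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def validate(self) -> None:
        intervals = sorted(
            [(s.start, s.end, s.stop_age_my, s.deletion_prob) for s in self.strata]
            + [(a, b, 0.0, 0.0) for a, b in self.par]
        )
        prev_end = 0
        for start, end, age, dele in intervals:
            if start != prev_end:
                raise ConfigurationError(
                    f"strata/PAR intervals must tile the chromosome; gap or overlap at {start}"
                )
            if end <= start:
                raise ConfigurationError("empty stratum interval")
            if not 0.0 <= age <= max(self.split_times_my):
                raise ConfigurationError(
                    f"stratum age {age} outside [0, oldest split {max(self.split_times_my)}]"
                )
            if not 0.0 <= dele <= 1.0:
                raise ConfigurationError("deletion_prob must be in [0, 1]")
            prev_end = end
        if prev_end != self.chrom_length_bp:
            raise ConfigurationError("strata/PAR intervals must extend to chromosome end")
        if self.snp_density <= 0 or self.mu < 0 or self.mean_depth <= 0:
            raise ConfigurationError("snp_density, mu and mean_depth must be positive")


def autosome_config(**kw) -> SimConfig:
    """Config for an autosome: one exchangeable pool over the whole length."""
    length = kw.pop("chrom_length_bp", 20_000_000)
    cfg = SimConfig(
        chrom=kw.pop("chrom", "chrI"),
        chrom_length_bp=length,
        strata=(),
        par=((0, length),),
        **kw,
    )
    return cfg


# ---------------------------------------------------------------------------
# divergence model helpers

def expected_divergence(mu_per_my: float, t_total_my: float) -> float:
    """Expected substitutions per site over a total branch time (My)."""
    return mu_per_my * t_total_my


def p_divergent(mu_per_my: float, t_total_my: float) -> float:
    """Probability a biallelic lattice site differs after ``t_total_my``.

    Two-state symmetric mutation model: saturates at 1/2 and inverts exactly
    via :func:`binary_distance`.
    """
    d = expected_divergence(mu_per_my, t_total_my)
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def binary_distance(p_diff: float) -> float:
    """Substitutions per site from an observed binary difference fraction."""
    if p_diff >= 0.5:
        return np.inf
    return -0.5 * np.log(1.0 - 2.0 * p_diff)


# ---------------------------------------------------------------------------
# haplotype panel

@dataclass
class HaplotypePanel:
    """Population haplotypes at lattice sites, plus per-site annotation."""

    chrom: str
    positions: np.ndarray          # 1-based
    ref: np.ndarray
    alt: np.ndarray
    p_alt: np.ndarray              # ALT frequency in the recombining pool
    stratum_idx: np.ndarray        # index into cfg.strata, -1 for PAR
    site_age: np.ndarray           # recombination-stop age (My) of the site's region
    father_x: np.ndarray           # (n_families, n_sites) int8
    father_y: np.ndarray
    mother_x1: np.ndarray
    mother_x2: np.ndarray
    outgroup: np.ndarray           # (n_sites,) int8
    y_deleted: np.ndarray          # (n_sites,) bool — site lies on a Y-deleted gene
    dup_site_alleles: np.ndarray   # (n_sites,) int8: 1 if fixed Y-paralog ALT here
    dup_window_idx: np.ndarray     # index into cfg.duplications, -1 elsewhere
    genes: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class SimTruth:
    """Generator-side record sufficient to reconstruct every emitted genotype."""

    cfg: SimConfig
    true_paternal_y: np.ndarray        # (n_families, n_sites)
    true_paternal_x: np.ndarray
    true_maternal_to_son: np.ndarray
    true_maternal_to_daughter: np.ndarray
    son_gets_x1: np.ndarray            # (n_families,) bool
    deleted_gene_ids: list[str]
    y_deleted_sites: np.ndarray        # (n_sites,) bool
    strata_table: pd.DataFrame
    duplicated_windows: pd.DataFrame
    dup_site_alleles: np.ndarray
    error_log: pd.DataFrame | None = None  # site_idx, sample_idx, kind, true_gt, obs_gt


def _default_genes(cfg: SimConfig) -> pd.DataFrame:
    starts = np.arange(0, cfg.chrom_length_bp - cfg.gene_length_bp, cfg.gene_spacing_bp)
    return pd.DataFrame(
        {
            "gene_id": [f"{cfg.chrom}_g{i:04d}" for i in range(len(starts))],
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + cfg.gene_length_bp,
        }
    )


def _sfs_frequencies(rng: np.random.Generator, n_draw: int, pool: int) -> np.ndarray:
    """Derived-allele frequencies under the standard neutral 1/i spectrum."""
    i = np.arange(1, pool)
    w = 1.0 / i
    w /= w.sum()
    counts = rng.choice(i, size=n_draw, p=w)
    return counts / pool


def _mean_heterozygosity(pool: int) -> float:
    i = np.arange(1, pool)
    w = 1.0 / i
    w /= w.sum()
    p = i / pool
    return float(np.sum(w * 2 * p * (1 - p)))


def simulate_sex_chromosome(cfg: SimConfig) -> tuple[HaplotypePanel, SimTruth]:
    """Draw population haplotypes for one sex chromosome (or autosome).

    Returns the haplotype panel (father X/Y and mother X haplotypes per
    family, plus an outgroup haplotype) and the truth record.  Within a
    stratum of age ``t`` the X and Y lineages differ with probability
    ``p_divergent(mu, 2 t)``; PAR sites draw all haplotypes from one pool.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ref_rng = np.random.default_rng(
        cfg.reference_seed if cfg.reference_seed is not None else cfg.seed + 10_007
    )

    spacing = max(1, int(round(1.0 / cfg.snp_density)))
    positions = np.arange(spacing, cfg.chrom_length_bp + 1, spacing, dtype=np.int64)
    n_sites = len(positions)
    nf = cfg.n_families

    # reference stream: shared between species mapped to the same reference
    ref_idx = ref_rng.integers(0, 4, size=n_sites)
    alt_shift = ref_rng.integers(1, 4, size=n_sites)
    ref = NUCS[ref_idx]
    alt = NUCS[(ref_idx + alt_shift) % 4]

    # per-site region assignment
    stratum_idx = np.full(n_sites, -1, dtype=np.int32)
    ages = np.zeros(n_sites)
    for k, s in enumerate(cfg.strata):
        m = (positions > s.start) & (positions <= s.end)
        stratum_idx[m] = k
        ages[m] = s.stop_age_my

    # X-pool standing variation
    het_target = cfg.pi / cfg.snp_density
    q_poly = min(1.0, het_target / _mean_heterozygosity(cfg.sfs_pool_size))
    poly = rng.random(n_sites) < q_poly
    p_alt = np.zeros(n_sites)
    p_alt[poly] = _sfs_frequencies(rng, int(poly.sum()), cfg.sfs_pool_size)

    father_x = (rng.random((nf, n_sites)) < p_alt).astype(np.int8)
    mother_x1 = (rng.random((nf, n_sites)) < p_alt).astype(np.int8)
    mother_x2 = (rng.random((nf, n_sites)) < p_alt).astype(np.int8)

    # Y haplotypes: single ancestral Y per stratum plus private mutations
    in_sdr = stratum_idx >= 0
    p_div = p_divergent(cfg.mu_per_my, 2.0 * ages)
    y_base = np.where(in_sdr, rng.random(n_sites) < p_div, 0).astype(np.int8)
    father_y = np.tile(y_base, (nf, 1))
    private = (rng.random((nf, n_sites)) < cfg.y_theta_per_site) & in_sdr
    father_y = np.where(private, 1 - father_y, father_y).astype(np.int8)
    # PAR: Y drawn from the shared pool, exchangeable with X
    par_draw = (rng.random((nf, n_sites)) < p_alt).astype(np.int8)
    father_y[:, ~in_sdr] = par_draw[:, ~in_sdr]

    # outgroup diverged at the oldest split
    t_out = max(cfg.split_times_my)
    outgroup = (rng.random(n_sites) < p_divergent(cfg.mu_per_my, 2.0 * t_out)).astype(np.int8)

    # Y gene deletions (fixed on the Y: shared by all families)
    genes = cfg.genes if cfg.genes is not None else _default_genes(cfg)
    genes = genes.reset_index(drop=True)
    deleted_ids: list[str] = []
    y_deleted = np.zeros(n_sites, dtype=bool)
    for _, g in genes.iterrows():
        mid = 0.5 * (g["start"] + g["end"])
        k = -1
        for j, s in enumerate(cfg.strata):
            if s.start <= mid < s.end:
                k = j
                break
        if k < 0:
            continue
        if rng.random() < cfg.strata[k].deletion_prob:
            deleted_ids.append(g["gene_id"])
            y_deleted |= (positions > g["start"]) & (positions <= g["end"])
    father_y[:, y_deleted] = MISSING  # no Y copy exists at deleted sites

    # autosome-to-Y duplication signature sites (deterministic within window
    # so that two species sharing a DuplicationSpec share the same alleles)
    dup_site_alleles = np.zeros(n_sites, dtype=np.int8)
    dup_window_idx = np.full(n_sites, -1, dtype=np.int32)
    for j, d in enumerate(cfg.duplications):
        m = (positions > d.start) & (positions <= d.end)
        dup_window_idx[m] = j
        idx = np.nonzero(m)[0]
        if len(idx) < d.n_fixed_y_alleles:
            raise ConfigurationError(
                f"duplication window [{d.start},{d.end}) has fewer lattice sites "
                f"than n_fixed_y_alleles={d.n_fixed_y_alleles}"
            )
        fixed = idx[: d.n_fixed_y_alleles]
        dup_site_alleles[fixed] = 1
        # the paralog allele replaces standing variation at these sites
        p_alt[fixed] = 0.0
        father_x[:, fixed] = 0
        mother_x1[:, fixed] = 0
        mother_x2[:, fixed] = 0
        father_y[:, fixed] = 0

    panel = HaplotypePanel(
        chrom=cfg.chrom,
        positions=positions,
        ref=ref,
        alt=alt,
        p_alt=p_alt,
        stratum_idx=stratum_idx,
        site_age=ages,
        father_x=father_x,
        father_y=father_y,
        mother_x1=mother_x1,
        mother_x2=mother_x2,
        outgroup=outgroup,
        y_deleted=y_deleted,
        dup_site_alleles=dup_site_alleles,
        dup_window_idx=dup_window_idx,
        genes=genes,
    )

    strata_table = pd.DataFrame(
        [
            {
                "name": s.name or f"S{k}",
                "start": s.start,
                "end": s.end,
                "stop_age_my": s.stop_age_my,
                "deletion_prob": s.deletion_prob,
            }
            for k, s in enumerate(cfg.strata)
        ]
    )
    dup_table = pd.DataFrame(
        [
            {"dup_idx": j, "start": d.start, "end": d.end, "n_y_copies": d.n_y_copies}
            for j, d in enumerate(cfg.duplications)
        ]
    )
    truth = SimTruth(
        cfg=cfg,
        true_paternal_y=father_y.copy(),
        true_paternal_x=father_x.copy(),
        true_maternal_to_son=np.empty((0, 0), dtype=np.int8),
        true_maternal_to_daughter=np.empty((0, 0), dtype=np.int8),
        son_gets_x1=np.zeros(nf, dtype=bool),
        deleted_gene_ids=deleted_ids,
        y_deleted_sites=y_deleted,
        strata_table=strata_table,
        duplicated_windows=dup_table,
        dup_site_alleles=dup_site_alleles,
    )
    return panel, truth


def _sample_names(cfg: SimConfig) -> tuple[list[str], Pedigree]:
    rows = []
    samples: list[str] = []
    for f in range(cfg.n_families):
        fam = f"F{f + 1:02d}"
        names = {role: f"{fam}_{role}" for role in ("father", "mother", "son", "daughter")}
        rows.append({"family": fam, **names})
        samples.extend(names.values())
    return samples, Pedigree(pd.DataFrame(rows))


def simulate_quartets(
    panel: HaplotypePanel, truth: SimTruth, cfg: SimConfig
) -> QuartetGenotypes:
    """Transmit haplotypes through the cross and emit quartet genotypes.

    Sons receive the paternal Y and one maternal X; daughters the paternal X
    and the other maternal X.  Depth is Poisson(mean_depth), halved for males
    over Y-deleted genes and inflated over duplication windows.  Genotype
    errors, dropout, low-GQ and low-QUAL events are injected at the config
    rates and recorded in ``truth.error_log``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nf, n_sites = panel.father_x.shape
    samples, pedigree = _sample_names(cfg)
    n_samples = 4 * nf

    son_gets_x1 = rng.random(nf) < 0.5
    mat_son = np.where(son_gets_x1[:, None], panel.mother_x1, panel.mother_x2)
    mat_dau = np.where(son_gets_x1[:, None], panel.mother_x2, panel.mother_x1)

    truth.true_maternal_to_son = mat_son.astype(np.int8)
    truth.true_maternal_to_daughter = mat_dau.astype(np.int8)
    truth.son_gets_x1 = son_gets_x1

    deleted = panel.y_deleted  # (n_sites,)
    dup_fixed = panel.dup_site_alleles == 1
    in_dup = panel.dup_window_idx >= 0
    dup_copies = np.zeros(n_sites)
    if in_dup.any():
        copies = np.array([d.n_y_copies for d in cfg.duplications])
        dup_copies[in_dup] = copies[panel.dup_window_idx[in_dup]]

    gt = np.empty((n_sites, n_samples), dtype=np.int8)
    frac_alt = np.empty((n_sites, n_samples), dtype=np.float64)
    male_cols = np.zeros(n_samples, dtype=bool)

    for f in range(nf):
        c_f, c_m, c_s, c_d = 4 * f, 4 * f + 1, 4 * f + 2, 4 * f + 3
        male_cols[[c_f, c_s]] = True
        fx, fy = panel.father_x[f], panel.father_y[f]
        ms, md = mat_son[f], mat_dau[f]

        father = np.where(deleted, 2 * fx, fx + np.maximum(fy, 0)).astype(np.int8)
        son = np.where(deleted, 2 * ms, ms + np.maximum(fy, 0)).astype(np.int8)
        mother = (panel.mother_x1[f] + panel.mother_x2[f]).astype(np.int8)
        daughter = (fx + md).astype(np.int8)

        # fixed Y-paralog allele: mismapped paralog reads make father and son
        # appear heterozygous for ALT; the true autosomal alleles are REF
        father = np.where(dup_fixed, 1, father)
        son = np.where(dup_fixed, 1, son)

        gt[:, c_f], gt[:, c_m], gt[:, c_s], gt[:, c_d] = father, mother, son, daughter
        for c, g in ((c_f, father), (c_m, mother), (c_s, son), (c_d, daughter)):
            frac_alt[:, c] = g / 2.0
        # paralog reads dilute ALT below 1/2 in carrier males
        with np.errstate(invalid="ignore"):
            dil = dup_copies / (2.0 + dup_copies)
        for c in (c_f, c_s):
            frac_alt[:, c] = np.where(dup_fixed, dil, frac_alt[:, c])

    # depths: male depth over the SDR decays with stratum age as diverged Y
    # reads fail to map to the X reference; deletion removes the Y copy
    # entirely (mappability 0, depth ratio 0.5)
    y_map = np.where(
        panel.stratum_idx >= 0,
        np.exp(-cfg.map_loss_rate_per_my * panel.site_age),
        1.0,
    )
    y_map = np.where(deleted, 0.0, y_map)
    lam = np.full((n_sites, n_samples), cfg.mean_depth)
    male_mult = (1.0 + y_map) / 2.0
    lam[:, male_cols] *= male_mult[:, None]
    infl = (1.0 + dup_copies / 2.0)[:, None]
    lam = np.where(in_dup[:, None] & male_cols[None, :], lam * infl, lam)
    dp = rng.poisson(lam).astype(np.int32)
    ad_alt = rng.binomial(dp, np.clip(frac_alt, 0.0, 1.0)).astype(np.int32)

    gq = np.full((n_sites, n_samples), 99, dtype=np.int16)
    low_gq = rng.random((n_sites, n_samples)) < cfg.low_gq_rate
    gq[low_gq] = rng.integers(2, 20, size=int(low_gq.sum()))

    qual = np.full(n_sites, 999.0)
    low_q = rng.random(n_sites) < cfg.low_qual_rate
    qual[low_q] = rng.integers(100, 999, size=int(low_q.sum())).astype(float)

    # genotype errors then dropout, both logged
    true_gt = gt.copy()
    err = rng.random((n_sites, n_samples)) < cfg.error_rate
    shift = rng.integers(1, 3, size=(n_sites, n_samples)).astype(np.int8)
    gt = np.where(err, (gt + shift) % 3, gt).astype(np.int8)
    drop = rng.random((n_sites, n_samples)) < cfg.missing_rate
    gt[drop] = MISSING

    logs = []
    for kind, mask in (("flip", err & ~drop), ("missing", drop)):
        si, sj = np.nonzero(mask)
        logs.append(
            pd.DataFrame(
                {
                    "site_idx": si,
                    "sample_idx": sj,
                    "kind": kind,
                    "true_gt": true_gt[si, sj],
                    "obs_gt": gt[si, sj],
                }
            )
        )
    truth.error_log = (
        pd.concat(logs, ignore_index=True)
        .sort_values(["site_idx", "sample_idx", "kind"])
        .reset_index(drop=True)
    )

    return QuartetGenotypes(
        chrom=cfg.chrom,
        pos=panel.positions,
        ref=panel.ref,
        alt=panel.alt,
        qual=qual,
        gt=gt,
        dp=dp,
        gq=gq,
        ad_alt=ad_alt,
        samples=samples,
        pedigree=pedigree,
    )


def simulate_quartet_vcf(cfg: SimConfig) -> tuple[QuartetGenotypes, SimTruth]:
    """One-call convenience: panel + quartet genotypes for a config."""
    panel, truth = simulate_sex_chromosome(cfg)
    q = simulate_quartets(panel, truth, cfg)
    return q, truth


# ---------------------------------------------------------------------------
# multispecies scenario trees and sequence evolution

SCENARIOS = (
    "ancestral_sdr",
    "independent_sdr",
    "turnover",
    "par_both",
    "sdr_a_par_b",
)


def _random_ultrametric(labels: list[str], height: float, rng: np.random.Generator) -> str:
    """Newick (no trailing semicolon) of a random ultrametric tree of depth ``height``."""
    if len(labels) == 1:
        return f"{labels[0]}:{height:.6f}"
    # random sequential coalescence with sorted uniform node depths
    depths = np.sort(rng.uniform(0.05 * height, height, size=len(labels) - 1))
    nodes = [(lab, 0.0) for lab in labels]
    order = list(rng.permutation(len(labels)))
    items = [nodes[i] for i in order]
    for d in depths[:-1]:
        (n1, h1), (n2, h2) = items.pop(), items.pop()
        merged = f"({n1}:{d - h1:.6f},{n2}:{d - h2:.6f})"
        items.insert(int(rng.integers(0, len(items) + 1)), (merged, d))
    (n1, h1), (n2, h2) = items
    d = height
    return f"({n1}:{d - h1:.6f},{n2}:{d - h2:.6f})"


def _intermingled_subtree(
    labels_x: list[str],
    labels_y: list[str],
    height: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> str:
    """Random coalescent over X and Y tips that genuinely intermingles them.

    A recombining PAR has exchangeable X and Y lineages; a draw in which
    either class happens to come out monophyletic does not represent that
    history, so such draws are rejected.
    """
    from skbio import TreeNode

    for _ in range(max_tries):
        nwk = _random_ultrametric(labels_x + labels_y, height, rng)
        tree = TreeNode.read([nwk + ";"], convert_underscores=False)
        clades = {
            frozenset(t.name for t in node.tips(include_self=True))
            for node in tree.postorder(include_self=True)
        }
        if frozenset(labels_x) not in clades and frozenset(labels_y) not in clades:
            return nwk
    raise RuntimeError("failed to draw an intermingled PAR subtree")


def scenario_tree(
    scenario: str,
    rng: np.random.Generator,
    n_per_class: int = 4,
    t_split: float = 14.3,
    t_ancestral_sdr: float = 18.0,
    t_young_sdr: float = 8.0,
    t_turnover: float = 3.0,
    tip_height: float = 0.3,
    par_height: float = 2.0,
    t_outgroup: float = 25.0,
) -> str:
    """Newick for one Fig-2-style evolutionary history (branch lengths in My).

    Tip labels are ``<species>_<class>_<i>`` (e.g. ``A_Y_1``) plus ``OUT``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")

    def cls(sp: str, cl: str) -> list[str]:
        return [f"{sp}_{cl}_{i + 1}" for i in range(n_per_class)]

    def sub(labels: list[str], h: float) -> str:
        return _random_ultrametric(labels, h, rng)

    th = tip_height
    if scenario == "ancestral_sdr":
        ys = f"({sub(cls('A', 'Y'), th)}:{t_split - th:.6f},{sub(cls('B', 'Y'), th)}:{t_split - th:.6f})"
        xs = f"({sub(cls('A', 'X'), th)}:{t_split - th:.6f},{sub(cls('B', 'X'), th)}:{t_split - th:.6f})"
        core = f"({ys}:{t_ancestral_sdr - t_split:.6f},{xs}:{t_ancestral_sdr - t_split:.6f})"
        h_core = t_ancestral_sdr
    elif scenario == "independent_sdr":
        a = f"({sub(cls('A', 'X'), th)}:{t_young_sdr - th:.6f},{sub(cls('A', 'Y'), th)}:{t_young_sdr - th:.6f})"
        b = f"({sub(cls('B', 'X'), th)}:{t_young_sdr - th:.6f},{sub(cls('B', 'Y'), th)}:{t_young_sdr - th:.6f})"
        core = f"({a}:{t_split - t_young_sdr:.6f},{b}:{t_split - t_young_sdr:.6f})"
        h_core = t_split
    elif scenario == "turnover":
        # B retains the ancestral Y; A's Y arose recently from A's X
        a = f"({sub(cls('A', 'X'), th)}:{t_turnover - th:.6f},{sub(cls('A', 'Y'), th)}:{t_turnover - th:.6f})"
        x_clade = f"({a}:{t_split - t_turnover:.6f},{sub(cls('B', 'X'), th)}:{t_split - th:.6f})"
        core = (
            f"({x_clade}:{t_ancestral_sdr - t_split:.6f},"
            f"{sub(cls('B', 'Y'), th)}:{t_ancestral_sdr - th:.6f})"
        )
        h_core = t_ancestral_sdr
    elif scenario == "par_both":
        a = _intermingled_subtree(cls("A", "X"), cls("A", "Y"), par_height, rng)
        b = _intermingled_subtree(cls("B", "X"), cls("B", "Y"), par_height, rng)
        core = f"({a}:{t_split - par_height:.6f},{b}:{t_split - par_height:.6f})"
        h_core = t_split
    else:  # sdr_a_par_b
        a = f"({sub(cls('A', 'X'), th)}:{t_young_sdr - th:.6f},{sub(cls('A', 'Y'), th)}:{t_young_sdr - th:.6f})"
        b = _intermingled_subtree(cls("B", "X"), cls("B", "Y"), par_height, rng)
        core = f"({a}:{t_split - t_young_sdr:.6f},{b}:{t_split - par_height:.6f})"
        h_core = t_split

    return f"({core}:{t_outgroup - h_core:.6f},OUT:{t_outgroup:.6f});"


def simulate_alignment_on_tree(
    newick: str, n_sites: int, mu_per_my: float, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve nucleotide sequences down a tree under Jukes–Cantor.

    Branch lengths are in My; the substitution rate is ``mu_per_my`` per site
    per My.  Returns ``{tip_label: sequence}``.
    """
    from skbio import TreeNode

    tree = TreeNode.read([newick], convert_underscores=False)
    root_seq = rng.integers(0, 4, size=n_sites)
    seqs: dict[str, np.ndarray] = {}

    def mutate(seq: np.ndarray, length: float) -> np.ndarray:
        p_same = 0.25 + 0.75 * np.exp(-4.0 / 3.0 * mu_per_my * max(length, 0.0))
        change = rng.random(len(seq)) > p_same
        shift = rng.integers(1, 4, size=len(seq))
        return np.where(change, (seq + shift) % 4, seq)

    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            cseq = mutate(seq, child.length or 0.0)
            if child.is_tip():
                seqs[child.name] = cseq
            else:
                stack.append((child, cseq))
    return {k: "".join(NUCS[v]) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# coding-sequence divergence simulator (for dN/dS and stratum dating)

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in STOP_CODONS:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame CDS of sense codons (no internal stops)."""
    table = _codon_table()
    sense = [c for c in table if table[c] != "*"]
    return "".join(rng.choice(sense) for _ in range(n_codons))


def evolve_cds(
    seq: str,
    branch_my: float,
    mu_per_my: float,
    omega: float,
    rng: np.random.Generator,
    allow_stops: bool = False,
) -> str:
    """Evolve a CDS along one branch with purifying selection.

    Mutations arrive as Poisson(mu · L · t); nonsynonymous changes are
    accepted with probability ``omega``; changes creating a stop codon are
    rejected unless ``allow_stops``.
    """
    table = _codon_table()
    s = list(seq)
    n_events = rng.poisson(mu_per_my * branch_my * len(s))
    for _ in range(n_events):
        pos = int(rng.integers(0, len(s)))
        old = s[pos]
        new = NUCS[(np.flatnonzero(NUCS == old)[0] + rng.integers(1, 4)) % 4]
        c0 = pos - pos % 3
        codon_old = "".join(s[c0 : c0 + 3])
        codon_new = codon_old[: pos % 3] + new + codon_old[pos % 3 + 1 :]
        if table[codon_new] == "*" and not allow_stops:
            continue
        if table[codon_new] != table[codon_old] and rng.random() >= omega:
            continue
        s[pos] = new
    return "".join(s)


def inject_nonsense(cds: str, rng: np.random.Generator) -> str:
    """Replace one random internal codon with a stop (simulated nonsense)."""
    n_codons = len(cds) // 3
    k = int(rng.integers(1, n_codons - 1))
    stop = STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))]
    return cds[: 3 * k] + stop + cds[3 * (k + 1) :]


def simulate_gene_triplet(
    n_codons: int,
    t_my: float,
    split_my: float,
    mu_per_my: float,
    omega: float,
    rng: np.random.Generator,
) -> tuple[str, str, str]:
    """CDS consensus triple (X, Y, outgroup-X) under the stratum clock.

    X and Y diverge at ``t_my``; the outgroup lineage split at ``split_my``.
    Expected synonymous divergence: dS(X,Y) ≈ 2·mu·t and
    dS(Y,out) ≈ 2·mu·split, so the ratio-dating formula recovers ``t_my``.
    """
    if not 0.0 <= t_my <= split_my:
        raise ValueError("stratum age must lie in [0, split time]")
    anc = random_cds(n_codons, rng)
    out = evolve_cds(anc, split_my, mu_per_my, omega, rng)
    xy_anc = evolve_cds(anc, split_my - t_my, mu_per_my, omega, rng)
    x = evolve_cds(xy_anc, t_my, mu_per_my, omega, rng)
    y = evolve_cds(xy_anc, t_my, mu_per_my, omega, rng)
    return x, y, out
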