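"""Windowed and per-gene statistics for sex-chromosome differentiation.

Implements the male/female read-depth ratio, the weighted Weir–Cockerham
F_ST between groups of phased haploid sequences, hemizygosity calls from
per-gene depth ratios, major-allele consensus sequences, a premature-stop
scan, and the naive theta-based effective-population-size estimate.

The "weighted" F_ST estimator is the ratio-of-sums form: per-SNP
Weir–Cockerham variance components are summed over a window before the
ratio is taken.  Because the groups compared here are haploid gamete
sequences (phased X vs Y), the components come from the allele-frequency
ANOVA without individual heterozygosity terms; fixed differences give
exactly F_ST = 1 and the estimator is not clipped below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GameteMatrix, QuartetGenotypes, window_index


@dataclass
class AnalysisConfig:
    """Fixed thresholds of the analysis pipeline."""

    stat_window_bp: int = 10_000        # depth ratio and F_ST windows
    tree_window_bp: int = 100_000       # gene-tree windows
    hemizygosity_threshold: float = 0.75
    dup_snp_fst_threshold: float = 0.25
    outlier_quantile: float = 0.02
    min_qual: float = 999.0
    min_gq: int = 20
    max_missing: int = 3
    depth_lo_mult: float = 0.75
    depth_hi_mult: float = 1.5
    min_snps_per_gene: int = 5          # dN/dS gene filter (ancestral chromosome)
    min_snps_per_gene_neo: int = 8      # dN/dS gene filter (neo-sex chromosome)
    consensus_min_fraction: float = 0.5
    split_time_my: float = 14.3

    def __post_init__(self) -> None:
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier_quantile must be in (0, 1)")
        for name in ("stat_window_bp", "tree_window_bp", "hemizygosity_threshold",
                     "dup_snp_fst_threshold", "min_gq", "min_qual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DiversityEstimate:
    """Neutral-theory diversity summary: theta = 4·Ne·mu = pi."""

    pi: float
    mu: float
    theta: float
    ne: float


def estimate_ne(pi: float, mu: float) -> DiversityEstimate:
    """Naive effective population size from diversity: Ne = pi / (4 mu)."""
    if pi < 0:
        raise ValueError("pi must be non-negative")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return DiversityEstimate(pi=pi, mu=mu, theta=pi, ne=pi / (4.0 * mu))


# ---------------------------------------------------------------------------
# read-depth ratio

def depth_ratio_sites(q: QuartetGenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean depth across sons and across daughters."""
    son_dp = q.role_matrix("dp", "son").astype(float)
    dau_dp = q.role_matrix("dp", "daughter").astype(float)
    return son_dp.mean(axis=1), dau_dp.mean(axis=1)


def depth_ratio_windows(
    q: QuartetGenotypes, windows: np.ndarray, chrom: str | None = None
) -> pd.DataFrame:
    """Son/daughter read-depth ratio per window (ratio of means).

    The ratio is total mean son depth over total mean daughter depth within
    the window — never a mean of per-site ratios.  Windows without SNPs, or
    with zero summed daughter depth, get a missing ratio.
    """
    son_mean, dau_mean = depth_ratio_sites(q)
    widx = window_index(q.pos, windows)
    n_win = len(windows)
    son_sum = np.bincount(widx[widx >= 0], weights=son_mean[widx >= 0], minlength=n_win)
    dau_sum = np.bincount(widx[widx >= 0], weights=dau_mean[widx >= 0], minlength=n_win)
    n_snps = np.bincount(widx[widx >= 0], minlength=n_win)

    ratio = np.full(n_win, np.nan)
    ok = (n_snps > 0) & (dau_sum > 0)
    ratio[ok] = son_sum[ok] / dau_sum[ok]
    if np.any((n_snps > 0) & (dau_sum == 0)):
        warnings.warn("windows with SNPs but zero daughter depth set to missing")
    return pd.DataFrame(
        {
            "chrom": chrom or q.chrom,
            "start": windows[:, 0],
            "end": windows[:, 1],
            "depth_ratio": ratio,
            "n_snps": n_snps,
        }
    )


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST between haploid groups

def wc_fst_components(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham variance-component numerator and denominator.

    ``hap_a``/``hap_b`` are (n_sites, n_seq) haploid ALT dosages with -1 for
    missing.  Sites with fewer than two called sequences in either group get
    NaN components.  For two groups of haploids the estimator is

        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    with MSP the among-group and MSG the within-group mean squares of the
    allele indicator, and n_c the variance-effective sample size.
    """
    a_called = hap_a != MISSING
    b_called = hap_b != MISSING
    n1 = a_called.sum(axis=1).astype(float)
    n2 = b_called.sum(axis=1).astype(float)
    c1 = np.where(a_called, hap_a, 0).sum(axis=1).astype(float)
    c2 = np.where(b_called, hap_b, 0).sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = c1 / n1
        p2 = c2 / n2
        n_tot = n1 + n2
        pbar = (c1 + c2) / n_tot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
        n_c = n_tot - (n1 ** 2 + n2 ** 2) / n_tot
        num = msp - msg
        den = msp + (n_c - 1) * msg

    bad = (n1 < 2) | (n2 < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def wc_fst_sites(hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
    """Per-SNP Weir–Cockerham F_ST (NaN where undefined or monomorphic)."""
    num, den = wc_fst_components(hap_a, hap_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan)


def wc_fst_windows(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    pos: np.ndarray,
    windows: np.ndarray,
    chrom: str = "",
) -> pd.DataFrame:
    """Weighted (ratio-of-sums) Weir–Cockerham F_ST per window.

    Monomorphic windows (summed denominator zero) and windows without
    usable SNPs report a missing F_ST.
    """
    num, den = wc_fst_components(hap_a, hap_b)
    usable = np.isfinite(num) & np.isfinite(den)
    widx = window_index(pos, windows)
    n_win = len(windows)
    sel = usable & (widx >= 0)
    num_sum = np.bincount(widx[sel], weights=num[sel], minlength=n_win)
    den_sum = np.bincount(widx[sel], weights=den[sel], minlength=n_win)
    n_snps = np.bincount(widx[sel], minlength=n_win)

    fst = np.full(n_win, np.nan)
    ok = (n_snps > 0) & (den_sum != 0)
    fst[ok] = num_sum[ok] / den_sum[ok]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": windows[:, 0],
            "end": windows[:, 1],
            "fst": fst,
            "n_snps": n_snps,
        }
    )


def xy_fst_windows(gm: GameteMatrix, windows: np.ndarray) -> pd.DataFrame:
    """Weighted F_ST between the phased Y and X gametes per window."""
    y = gm.haplotypes("paternal_son")
    x = gm.haplotypes("paternal_daughter")
    return wc_fst_windows(y, x, gm.pos, windows, chrom=gm.chrom)


# ---------------------------------------------------------------------------
# hemizygosity

def gene_depth_ratio(q: QuartetGenotypes, genes: pd.DataFrame) -> pd.DataFrame:
    """Mean son/daughter depth ratio over each gene's SNPs (ratio of means)."""
    son_mean, dau_mean = depth_ratio_sites(q)
    rows = []
    for _, g in genes.iterrows():
        m = ((q.pos - 1) >= g["start"]) & ((q.pos - 1) < g["end"])
        n = int(m.sum())
        if n == 0 or dau_mean[m].sum() == 0:
            ratio = np.nan
        else:
            ratio = son_mean[m].sum() / dau_mean[m].sum()
        rows.append(
            {
                "gene_id": g["gene_id"],
                "chrom": g.get("chrom", q.chrom),
                "start": g["start"],
                "end": g["end"],
                "depth_ratio": ratio,
                "n_snps": n,
            }
        )
    return pd.DataFrame(rows)


def call_hemizygous(
    gene_ratios: pd.DataFrame, threshold: float = 0.75
) -> pd.DataFrame:
    """Flag genes hemizygous when mean depth ratio is strictly below threshold.

    Genes without SNP coverage are uncallable (``hemizygous`` left NA).
    """
    out = gene_ratios.copy()
    callable_ = out["depth_ratio"].notna()
    out["callable"] = callable_
    out["hemizygous"] = pd.array(
        np.where(callable_, out["depth_ratio"] < threshold, None), dtype="boolean"
    )
    return out


# ---------------------------------------------------------------------------
# consensus sequences and premature stops

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def consensus_alleles(
    haps: np.ndarray, min_fraction: float = 0.5, strict_majority: bool = False
) -> np.ndarray:
    """Per-site consensus ALT indicator for a haploid group.

    The ALT allele enters the consensus when the fraction of non-missing
    sequences carrying it is at least ``min_fraction`` (default: an exact
    half counts as major).  With ``strict_majority`` the fraction must
    strictly exceed it — the alternative reading of a "fewer than half"
    removal rule.  Sites with no called sequence fall back to REF.
    """
    called = haps != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, haps, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    if strict_majority:
        return (frac > min_fraction).astype(np.int8)
    return (frac >= min_fraction).astype(np.int8)


def consensus_sequence(
    haps: np.ndarray,
    positions: np.ndarray,
    alt_bases: np.ndarray,
    ref_cds: str,
    cds_start: int,
    strand: str = "+",
    min_fraction: float = 0.5,
    strict_majority: bool = False,
) -> str:
    """Substitute group-major ALT alleles into a reference CDS.

    ``positions`` are 1-based genomic positions of the SNPs; ``cds_start``
    is the 0-based genomic start of the CDS on the forward strand.  Minus-
    strand CDSs are reverse-complemented after substitution so codon
    operations run in reading frame.
    """
    if len(ref_cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3: annotation error")
    cons = consensus_alleles(haps, min_fraction, strict_majority)
    seq = list(ref_cds.upper())
    for i in np.nonzero(cons == 1)[0]:
        off = int(positions[i]) - 1 - cds_start
        if 0 <= off < len(seq):
            seq[off] = str(alt_bases[i]).upper()
    out = "".join(seq)
    if strand == "-":
        out = out.translate(COMPLEMENT)[::-1]
    return out


def find_premature_stop(cds: str) -> int | None:
    """0-based codon index of the first internal stop, or None.

    The final codon is allowed to be (and usually is) a stop.
    """
    from Bio.Seq import Seq

    n_codons = len(cds) // 3
    aa = str(Seq(cds[: 3 * n_codons]).translate())
    hit = aa[:-1].find("*")
    return hit if hit >= 0 else None


def scan_premature_stops(cds_by_gene: dict[str, str]) -> pd.DataFrame:
    """Scan in-frame CDS consensus sequences for premature stop codons."""
    rows = []
    for gene_id, cds in cds_by_gene.items():
        stop = find_premature_stop(cds)
        rows.append(
            {
                "gene_id": gene_id,
                "has_premature_stop": stop is not None,
                "stop_codon_index": stop,
            }
        )
    return pd.DataFrame(rows)
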