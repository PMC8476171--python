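"""Phase-by-transmission for father–mother–son–daughter quartets.

For every heterozygous offspring genotype, the parental genotypes determine
which allele came from the father and which from the mother.  On a sex
chromosome, the paternal allele in a son travelled in Y-bearing sperm and in
a daughter in X-bearing sperm, so phasing a quartet yields one haploid Y,
one paternal X, and two maternal X sequences per family.

Sites where father, mother and the offspring are all heterozygous cannot be
phased unambiguously and are treated as missing for that offspring's
gametes.  Sites where an offspring carries an allele absent from both
parents are Mendelian violations and are masked for the whole family (or
dropped for all families with ``violation_scope="global"``).  No
population-level imputation is ever performed: phasing is strictly
family-local.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GameteMatrix, QuartetGenotypes


@dataclass
class FilterParams:
    """Site/genotype quality filters applied before phasing.

    Defaults follow the conventional stringent pedigree-phasing setup:
    site QUAL at least 999, genotypes below GQ 20 set missing, sites dropped
    when more than ``max_missing`` sons or daughters are missing, and sites
    dropped when the mean depth leaves ``[0.75, 1.5] ×`` the autosomal mean.
    """

    min_qual: float = 999.0
    min_gq: int = 20
    max_missing: int = 3
    depth_lo_mult: float = 0.75
    depth_hi_mult: float = 1.5


def filter_sites(
    q: QuartetGenotypes,
    autosomal_mean_depth: float,
    params: FilterParams | None = None,
) -> QuartetGenotypes:
    """Apply quality, depth and missingness filters; returns a site subset.

    Genotypes with GQ below the threshold are set missing before the
    missingness count.  The depth filter removes sites whose mean depth
    across all samples exceeds ``depth_hi_mult ×`` or falls below
    ``depth_lo_mult ×`` the autosomal mean (excess depth flags collapsed
    duplications; depleted depth flags error-prone hemizygous sites).
    """
    p = params or FilterParams()
    keep = q.qual >= p.min_qual

    gt = q.gt.copy()
    gt[q.gq < p.min_gq] = MISSING

    mean_dp = q.dp.mean(axis=1)
    keep &= mean_dp <= p.depth_hi_mult * autosomal_mean_depth
    keep &= mean_dp >= p.depth_lo_mult * autosomal_mean_depth

    idx = q.pedigree.indices(q.samples)
    sons_missing = (gt[:, idx["son"]] == MISSING).sum(axis=1)
    daughters_missing = (gt[:, idx["daughter"]] == MISSING).sum(axis=1)
    keep &= (sons_missing <= p.max_missing) & (daughters_missing <= p.max_missing)

    out = q.take_sites(np.nonzero(keep)[0])
    out.gt = gt[keep]
    return out


def _phase_offspring(
    child: np.ndarray, father: np.ndarray, mother: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized single-trio phasing.

    Returns (paternal, maternal, ambiguous_mask, violation_mask); paternal
    and maternal are ALT dosages in {0,1} or MISSING.
    """
    n = len(child)
    pat = np.full(n, MISSING, dtype=np.int8)
    mat = np.full(n, MISSING, dtype=np.int8)
    ambiguous = np.zeros(n, dtype=bool)
    violation = np.zeros(n, dtype=bool)

    present = (child != MISSING) & (father != MISSING) & (mother != MISSING)
    f_hom = present & ((father == 0) | (father == 2))
    m_hom = present & ((mother == 0) | (mother == 2))
    f_al = (father // 2).astype(np.int8)  # allele if homozygous
    m_al = (mother // 2).astype(np.int8)

    # homozygous child: both gametes carry the same allele
    c_hom = present & ((child == 0) | (child == 2))
    c_al = (child // 2).astype(np.int8)
    bad = c_hom & ((f_hom & (f_al != c_al)) | (m_hom & (m_al != c_al)))
    ok = c_hom & ~bad
    pat[ok] = c_al[ok]
    mat[ok] = c_al[ok]
    violation |= bad

    # heterozygous child
    c_het = present & (child == 1)
    both_hom = c_het & f_hom & m_hom
    bad = both_hom & (f_al == m_al)  # two identical homozygous parents
    ok = both_hom & ~bad
    pat[ok] = f_al[ok]
    mat[ok] = m_al[ok]
    violation |= bad

    f_only = c_het & f_hom & ~m_hom
    pat[f_only] = f_al[f_only]
    mat[f_only] = 1 - f_al[f_only]

    m_only = c_het & ~f_hom & m_hom
    mat[m_only] = m_al[m_only]
    pat[m_only] = 1 - m_al[m_only]

    trip = c_het & ~f_hom & ~m_hom  # father, mother and offspring all het
    ambiguous |= trip

    return pat, mat, ambiguous, violation


def phase_quartet(
    q: QuartetGenotypes, violation_scope: str = "family"
) -> GameteMatrix:
    """Phase every family; returns the transmitted-gamete matrix.

    ``violation_scope`` controls Mendelian violations: ``"family"`` masks the
    four gametes of the offending family only; ``"global"`` masks the site
    for all families.
    """
    if violation_scope not in ("family", "global"):
        raise ValueError("violation_scope must be 'family' or 'global'")
    idx = q.pedigree.indices(q.samples)
    nf = q.pedigree.n_families
    n = q.n_sites
    shape = (n, nf)
    pat_son = np.full(shape, MISSING, dtype=np.int8)
    pat_dau = np.full(shape, MISSING, dtype=np.int8)
    mat_son = np.full(shape, MISSING, dtype=np.int8)
    mat_dau = np.full(shape, MISSING, dtype=np.int8)
    father_het = np.zeros(shape, dtype=bool)

    rows = []
    global_violation = np.zeros(n, dtype=bool)
    for f in range(nf):
        father = q.gt[:, idx["father"][f]]
        mother = q.gt[:, idx["mother"][f]]
        son = q.gt[:, idx["son"][f]]
        daughter = q.gt[:, idx["daughter"][f]]
        father_het[:, f] = father == 1

        ps, ms, amb_s, vio_s = _phase_offspring(son, father, mother)
        pd_, md_, amb_d, vio_d = _phase_offspring(daughter, father, mother)
        vio = vio_s | vio_d
        ps[vio] = MISSING
        ms[vio] = MISSING
        pd_[vio] = MISSING
        md_[vio] = MISSING
        pat_son[:, f] = ps
        mat_son[:, f] = ms
        pat_dau[:, f] = pd_
        mat_dau[:, f] = md_
        global_violation |= vio
        rows.append(
            {
                "family": q.pedigree.families[f],
                "n_sites": n,
                "son_phased": int((ps != MISSING).sum()),
                "daughter_phased": int((pd_ != MISSING).sum()),
                "son_triple_het": int(amb_s.sum()),
                "daughter_triple_het": int(amb_d.sum()),
                "mendelian_violations": int(vio.sum()),
            }
        )

    if violation_scope == "global":
        for m in (pat_son, pat_dau, mat_son, mat_dau):
            m[global_violation] = MISSING

    return GameteMatrix(
        chrom=q.chrom,
        pos=q.pos,
        ref=q.ref,
        alt=q.alt,
        families=q.pedigree.families,
        paternal_son=pat_son,
        paternal_daughter=pat_dau,
        maternal_son=mat_son,
        maternal_daughter=mat_dau,
        report=pd.DataFrame(rows),
        father_het=father_het,
    )


def sdr_consistency_filter(
    gm: GameteMatrix,
    sdr_interval: tuple[int, int],
    chrom_length_bp: int | None = None,
) -> GameteMatrix:
    """Mask SDR sites where both offspring received the same paternal allele.

    Within a sex-determining region, a heterozygous father must transmit one
    allele to sons (on the Y) and the other to daughters (on the X); brothers
    and sisters sharing the paternal allele there indicates a genotyping or
    phasing error (typically imputation of X alleles onto a degenerate Y),
    so the family's paternal calls are set missing at such sites.
    """
    start, end = sdr_interval
    if start < 0 or end <= start or (
        chrom_length_bp is not None and end > chrom_length_bp
    ):
        raise ValueError(f"SDR interval [{start}, {end}) outside chromosome bounds")
    if gm.father_het is None:
        raise ValueError("gamete matrix lacks father heterozygosity flags")

    in_sdr = ((gm.pos - 1) >= start) & ((gm.pos - 1) < end)
    same = (
        (gm.paternal_son != MISSING)
        & (gm.paternal_daughter != MISSING)
        & (gm.paternal_son == gm.paternal_daughter)
        & gm.father_het
        & in_sdr[:, None]
    )
    out = gm.take_sites(np.arange(gm.n_sites))
    out.father_het = gm.father_het.copy()
    out.paternal_son = gm.paternal_son.copy()
    out.paternal_daughter = gm.paternal_daughter.copy()
    out.paternal_son[same] = MISSING
    out.paternal_daughter[same] = MISSING
    out.report = gm.report.copy()
    if len(out.report):
        out.report["sdr_inconsistent"] = same.sum(axis=0)
    return out
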