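"""Autosome-to-Y duplication detection and Y-homology tests.

Regions duplicated from an autosome onto the Y leave a bioinformatic
fingerprint on the autosome when reads are mapped to a female (Y-less)
reference: Y-paralog reads mismap onto the autosomal copy, creating alleles
carried only by males.  Between the paternal alleles that sons and
daughters inherited, such sites show extreme F_ST.  Shared outlier windows
— and, within them, SNPs with the same male-restricted allele in two
species — demonstrate that the duplication, and hence the Y carrying it,
predates the species split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MISSING, GameteMatrix
from .popgen import wc_fst_components, wc_fst_sites


def paternal_fst_windows(
    gm: GameteMatrix,
    windows: np.ndarray,
    min_informative: int = 8,
) -> pd.DataFrame:
    """Son-vs-daughter F_ST on paternally inherited autosomal alleles.

    Per-SNP Weir–Cockerham components between the son-inherited and
    daughter-inherited paternal allele sets are combined per window as a
    ratio of sums.  SNPs with fewer than ``min_informative`` called sons or
    daughters are dropped.
    """
    sons = gm.haplotypes("paternal_son")
    daughters = gm.haplotypes("paternal_daughter")
    n_son = (sons != MISSING).sum(axis=1)
    n_dau = (daughters != MISSING).sum(axis=1)
    ok = (n_son >= min_informative) & (n_dau >= min_informative)

    num, den = wc_fst_components(sons, daughters)
    usable = ok & np.isfinite(num) & np.isfinite(den)

    from .containers import window_index

    widx = window_index(gm.pos, windows)
    n_win = len(windows)
    sel = usable & (widx >= 0)
    num_sum = np.bincount(widx[sel], weights=num[sel], minlength=n_win)
    den_sum = np.bincount(widx[sel], weights=den[sel], minlength=n_win)
    n_snps = np.bincount(widx[sel], minlength=n_win)
    fst = np.full(n_win, np.nan)
    good = (n_snps > 0) & (den_sum != 0)
    fst[good] = num_sum[good] / den_sum[good]
    return pd.DataFrame(
        {
            "chrom": gm.chrom,
            "start": windows[:, 0],
            "end": windows[:, 1],
            "fst": fst,
            "n_snps": n_snps,
        }
    )


def flag_outliers(dup: pd.DataFrame, q: float = 0.02) -> pd.DataFrame:
    """Mark windows whose F_ST lies strictly above the top-``q`` quantile."""
    out = dup.copy()
    vals = out["fst"].dropna()
    if len(vals) == 0:
        out["outlier"] = False
        return out
    if q >= 1.0:
        out["outlier"] = out["fst"].notna()
        return out
    cutoff = np.quantile(vals, 1.0 - q)
    out["outlier"] = (out["fst"] > cutoff).fillna(False)
    return out


@dataclass
class DupOverlapTest:
    """Shared-outlier-window overlap test between two species."""

    n_windows_total: int
    n_outliers_a: int
    n_outliers_b: int
    n_shared_observed: int
    n_shared_expected: float
    chi2: float
    p_chi2: float
    p_hypergeom: float


def shared_outliers(
    dup_a: pd.DataFrame, dup_b: pd.DataFrame, q: float = 0.02
) -> tuple[pd.DataFrame, DupOverlapTest]:
    """Intersect per-species top-``q`` windows and test the overlap.

    Both species must be analysed over one harmonized window grid; windows
    missing F_ST in either species are excluded before the quantile cut so
    the null expectation ``q²·N`` refers to jointly scored windows.  The
    chi-squared goodness-of-fit test (1 df) compares the observed shared
    count with that expectation; a hypergeometric tail probability is also
    reported for small expected counts.
    """
    keya = dup_a[["chrom", "start", "end", "fst"]].rename(columns={"fst": "fst_a"})
    keyb = dup_b[["chrom", "start", "end", "fst"]].rename(columns={"fst": "fst_b"})
    merged = keya.merge(keyb, on=["chrom", "start", "end"], how="inner")
    merged = merged.dropna(subset=["fst_a", "fst_b"]).reset_index(drop=True)
    n = len(merged)
    if n == 0:
        raise ValueError("no jointly scored windows; check the window grids")

    if q >= 1.0:
        merged["outlier_a"] = True
        merged["outlier_b"] = True
    else:
        cut_a = np.quantile(merged["fst_a"], 1.0 - q)
        cut_b = np.quantile(merged["fst_b"], 1.0 - q)
        merged["outlier_a"] = merged["fst_a"] > cut_a
        merged["outlier_b"] = merged["fst_b"] > cut_b
    merged["shared"] = merged["outlier_a"] & merged["outlier_b"]

    ka, kb = int(merged["outlier_a"].sum()), int(merged["outlier_b"].sum())
    obs = int(merged["shared"].sum())
    expected = q * q * n
    if expected <= 0:
        raise ValueError("expected shared count must be positive")
    chi2 = (obs - expected) ** 2 / expected
    p_chi2 = float(sps.chi2.sf(chi2, df=1))
    if q >= 1.0 or (ka == n and kb == n):
        chi2, p_chi2 = 0.0, 1.0
    # hypergeometric: overlap of a size-ka draw with kb marked among n
    p_hyper = float(sps.hypergeom.sf(obs - 1, n, ka, kb)) if obs > 0 else 1.0
    test = DupOverlapTest(
        n_windows_total=n,
        n_outliers_a=ka,
        n_outliers_b=kb,
        n_shared_observed=obs,
        n_shared_expected=expected,
        chi2=float(chi2),
        p_chi2=p_chi2,
        p_hypergeom=p_hyper,
    )
    return merged, test


def _male_specific_allele(gm: GameteMatrix, site_mask: np.ndarray) -> np.ndarray:
    """Per-site male-restricted allele code (0/1), or MISSING if none.

    An allele is male-specific when its frequency is zero among
    daughter-inherited paternal alleles and positive among son-inherited
    ones.
    """
    sons = gm.haplotypes("paternal_son")
    daughters = gm.haplotypes("paternal_daughter")
    out = np.full(gm.n_sites, MISSING, dtype=np.int8)
    for i in np.nonzero(site_mask)[0]:
        s = sons[i][sons[i] != MISSING]
        d = daughters[i][daughters[i] != MISSING]
        if len(s) == 0 or len(d) == 0:
            continue
        for allele in (0, 1):
            if (allele in s) and (allele not in d):
                out[i] = allele
                break
    return out


def homologous_dup_snps(
    shared_windows: pd.DataFrame,
    gm_a: GameteMatrix,
    gm_b: GameteMatrix,
    fst_threshold: float = 0.25,
    min_snps_per_window: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP-level homology evidence inside shared outlier windows.

    A SNP is a homologous Y duplicate when son-vs-daughter F_ST exceeds the
    threshold in both species and the same allele (by base identity) is
    male-restricted in both.  Windows with at least ``min_snps_per_window``
    such SNPs are labelled evidence of Y-chromosome homology.
    """
    shared = shared_windows[shared_windows["shared"]]
    if not np.array_equal(gm_a.pos, gm_b.pos):
        raise ValueError("species gamete matrices must share one site grid")

    fst_a = wc_fst_sites(gm_a.haplotypes("paternal_son"), gm_a.haplotypes("paternal_daughter"))
    fst_b = wc_fst_sites(gm_b.haplotypes("paternal_son"), gm_b.haplotypes("paternal_daughter"))

    in_shared = np.zeros(gm_a.n_sites, dtype=bool)
    win_of_site = np.full(gm_a.n_sites, -1)
    for w, (_, row) in enumerate(shared.iterrows()):
        m = ((gm_a.pos - 1) >= row["start"]) & ((gm_a.pos - 1) < row["end"])
        in_shared |= m
        win_of_site[m] = row.name

    ms_a = _male_specific_allele(gm_a, in_shared)
    ms_b = _male_specific_allele(gm_b, in_shared)

    rows = []
    for i in np.nonzero(in_shared)[0]:
        fa, fb = fst_a[i], fst_b[i]
        pass_fst = np.isfinite(fa) and np.isfinite(fb) and fa > fst_threshold and fb > fst_threshold
        base_a = {0: gm_a.ref[i], 1: gm_a.alt[i], MISSING: None}[int(ms_a[i])]
        base_b = {0: gm_b.ref[i], 1: gm_b.alt[i], MISSING: None}[int(ms_b[i])]
        same_allele = base_a is not None and base_a == base_b
        rows.append(
            {
                "chrom": gm_a.chrom,
                "pos": int(gm_a.pos[i]),
                "window_idx": int(win_of_site[i]),
                "fst_a": fa,
                "fst_b": fb,
                "male_allele_a": base_a,
                "male_allele_b": base_b,
                "homologous": bool(pass_fst and same_allele),
            }
        )
    snps = pd.DataFrame(rows)
    if len(snps):
        win_counts = (
            snps.groupby("window_idx")["homologous"].sum().astype(int).rename("n_homologous_snps")
        )
    else:
        win_counts = pd.Series(dtype=int, name="n_homologous_snps")
    windows = shared.join(win_counts, how="left")
    windows["n_homologous_snps"] = windows.get("n_homologous_snps", 0)
    windows["n_homologous_snps"] = windows["n_homologous_snps"].fillna(0).astype(int)
    windows["y_homology_evidence"] = windows["n_homologous_snps"] >= min_snps_per_window
    return snps, windows
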