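"""Stratum delimitation, coding divergence and recombination-stop dating.

Strata are delimited by penalized least-squares changepoint detection on the
windowed male/female depth-ratio profile (change in mean, Gaussian cost,
exact dynamic programming).  Coding divergence between X and Y consensus
sequences is estimated with the Nei–Gojobori (1986) counting method with
equal-path averaging for multi-hit codons and Jukes–Cantor correction.  A
stratum's recombination-stop age follows the molecular-clock ratio

    age = T_split · mean dS(X, Y) / mean dS(Y, outgroup X)

where the Y enters both comparisons so that a faster-evolving Y cancels
from the ratio.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simcross import STOP_CODONS


# ---------------------------------------------------------------------------
# changepoint detection

def _segment_cost_factory(y: np.ndarray):
    """O(1) within-segment sum-of-squares cost from prefix sums."""
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(i: int, j: int) -> float:  # [i, j)
        n = j - i
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / n

    return cost


def bic_penalty(y: np.ndarray) -> float:
    """Default penalty: 2·sigma²·log n with sigma from robust first differences."""
    n = len(y)
    if n < 3:
        return 1.0
    d = np.diff(y)
    sigma = np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0)
    if sigma == 0:
        sigma = float(np.std(y)) or 1.0
    return 2.0 * sigma**2 * np.log(n)


def detect_changepoints(
    series: np.ndarray,
    penalty: float | None = None,
    min_segment_length: int = 5,
) -> list[int]:
    """Changepoints in a windowed series by exact penalized segmentation.

    Minimizes total within-segment squared error plus ``penalty`` per
    changepoint using optimal-partitioning dynamic programming (exact, so
    equal to an exhaustive search over all segmentations).  Missing values
    are skipped for the cost but boundaries are reported as 0-based indices
    into the original series, each the first window of a new segment.
    """
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    y = series[finite]
    orig_idx = np.nonzero(finite)[0]
    n = len(y)
    if n < 2 * min_segment_length:
        warnings.warn("series shorter than two minimum segments; no changepoints")
        return []
    if penalty is None:
        penalty = bic_penalty(y)

    cost = _segment_cost_factory(y)
    f = np.full(n + 1, np.inf)
    f[0] = -penalty  # first segment incurs no penalty
    last = np.zeros(n + 1, dtype=int)
    for t in range(min_segment_length, n + 1):
        best, arg = np.inf, 0
        for s in range(0, t - min_segment_length + 1):
            if not np.isfinite(f[s]):
                continue
            if s != 0 and s < min_segment_length:
                continue
            val = f[s] + cost(s, t) + penalty
            if val < best:
                best, arg = val, s
        f[t] = best
        last[t] = arg
    bounds = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            bounds.append(s)
        t = s
    bounds.reverse()
    return [int(orig_idx[b]) for b in bounds]


def segments_from_changepoints(n_windows: int, changepoints: list[int]) -> list[tuple[int, int]]:
    """Half-open window-index segments implied by a changepoint list."""
    edges = [0] + list(changepoints) + [n_windows]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


# ---------------------------------------------------------------------------
# Nei–Gojobori divergence

_CODON_CACHE: dict[str, tuple[float, float]] = {}


def _aa(codon: str) -> str:
    from .simcross import _codon_table

    return _codon_table()[codon]


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes creating a stop codon count as
    nonsynonymous (the original counting convention).
    """
    if codon in _CODON_CACHE:
        return _CODON_CACHE[codon]
    bases = "ACGT"
    syn = 0.0
    for i in range(3):
        for b in bases:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if _aa(mutant) == _aa(codon):
                syn += 1.0 / 3.0
    out = (syn, 3.0 - syn)
    _CODON_CACHE[codon] = out
    return out


import functools


@functools.lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Multi-hit codons average over all mutational pathways, excluding
    pathways that pass through a stop codon (unless every pathway does).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = float(np.mean([s for s, _ in open_paths]))
    nd = float(np.mean([n for _, n in open_paths]))
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites.

    Returns 0 for identical sequences and +inf at or beyond the 3/4
    saturation point (the correction is undefined there; downstream
    summaries use finite values only).
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return np.inf
    return -0.75 * np.log(1.0 - 4.0 / 3.0 * p)


@dataclass
class GeneDivergence:
    """NG86 divergence between two aligned in-frame CDS consensus sequences."""

    gene_id: str
    ds: float
    dn: float
    omega: float | None
    ps: float
    pn: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_snps: int
    flagged: bool = False
    flag_reason: str = ""


def ng86_divergence(
    cds_a: str, cds_b: str, gene_id: str = ""
) -> GeneDivergence:
    """Nei–Gojobori dS/dN between two equal-length in-frame CDSs.

    Codons containing ambiguity characters are skipped.  A premature stop
    shared by both sequences flags the gene (excluded from omega
    summaries); a stop in only one sequence skips that codon.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS length mismatch between sequences")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")

    s_sites = n_sites_ = sd = nd = 0.0
    n_snps = 0
    flagged = False
    reason = ""
    n_codons = len(cds_a) // 3
    for k in range(n_codons):
        c1 = cds_a[3 * k : 3 * k + 3]
        c2 = cds_b[3 * k : 3 * k + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        stop1, stop2 = _aa(c1) == "*", _aa(c2) == "*"
        internal = k < n_codons - 1
        if stop1 and stop2 and internal:
            flagged = True
            reason = "internal stop codon in both sequences"
            continue
        if stop1 or stop2:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites_ += (n1 + n2) / 2.0
        dsd, dnd = _pathway_counts(c1, c2)
        sd += dsd
        nd += dnd
        n_snps += sum(a != b for a, b in zip(c1, c2))

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites_ if n_sites_ > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    omega = (dn / ds) if (np.isfinite(ds) and np.isfinite(dn) and ds > 0) else None
    return GeneDivergence(
        gene_id=gene_id,
        ds=ds,
        dn=dn,
        omega=omega,
        ps=ps,
        pn=pn,
        syn_sites=s_sites,
        nonsyn_sites=n_sites_,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        n_snps=n_snps,
        flagged=flagged,
        flag_reason=reason,
    )


def divergence_frame(divs: list[GeneDivergence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": d.gene_id,
                "ds": d.ds,
                "dn": d.dn,
                "omega": d.omega,
                "n_snps": d.n_snps,
                "flagged": d.flagged,
            }
            for d in divs
        ]
    )


# ---------------------------------------------------------------------------
# stratum dating and summaries

def estimate_stratum_age(
    mean_ds_xy: float, mean_ds_out: float, split_time_my: float = 14.3
) -> float:
    """Recombination-stop age from the dS ratio, in My.

    Divides the X–Y synonymous divergence by the Y-versus-outgroup-X
    divergence and multiplies by the split time; using the Y in both
    comparisons cancels faster Y-specific evolution.  Returns NaN (flagged
    undefined) when the outgroup divergence is zero.
    """
    if mean_ds_out is None or not np.isfinite(mean_ds_out) or mean_ds_out <= 0:
        warnings.warn("outgroup dS is zero or undefined; stratum age undefined")
        return np.nan
    return split_time_my * mean_ds_xy / mean_ds_out


@dataclass
class StratumSegment:
    """Per-stratum summary row (Table-1-shaped)."""

    label: str
    start: int
    end: int
    n_genes: int
    pct_hemizygous: float
    mean_depth_ratio: float
    mean_fst: float
    mean_ds_xy: float
    mean_dn_xy: float
    mean_omega: float
    mean_ds_out: float
    age_my: float


def summarize_strata(
    segments: pd.DataFrame,
    gene_stats: pd.DataFrame | None = None,
    gene_divergence: pd.DataFrame | None = None,
    window_stats: pd.DataFrame | None = None,
    split_time_my: float = 14.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum means, hemizygosity percentages, ages and pairwise tests.

    ``segments`` needs start/end/label columns (bp, half-open).
    ``gene_stats`` carries hemizygosity calls, ``gene_divergence`` per-gene
    ds/dn/omega (and optionally ds_out) keyed by gene midpoint, and
    ``window_stats`` per-window depth_ratio/fst.  Pairwise between-stratum
    comparisons use the Mann–Whitney U test on per-gene ds, dn and omega
    and per-window fst; raw p-values are reported with a Holm-adjusted
    column.
    """
    rows = []
    per_stratum: dict[str, dict[str, np.ndarray]] = {}
    for _, seg in segments.iterrows():
        label = seg["label"]
        start, end = int(seg["start"]), int(seg["end"])
        vals: dict[str, np.ndarray] = {}

        n_genes = 0
        pct_hemi = np.nan
        if gene_stats is not None and len(gene_stats):
            mid = 0.5 * (gene_stats["start"] + gene_stats["end"])
            sel = gene_stats[(mid >= start) & (mid < end)]
            callable_ = sel[sel["callable"]] if "callable" in sel else sel
            n_genes = len(sel)
            if len(callable_):
                pct_hemi = 100.0 * callable_["hemizygous"].astype("boolean").mean()

        mean_ds = mean_dn = mean_om = mean_out = np.nan
        if gene_divergence is not None and len(gene_divergence):
            mid = 0.5 * (gene_divergence["start"] + gene_divergence["end"])
            sel = gene_divergence[(mid >= start) & (mid < end)]
            for col in ("ds", "dn", "omega", "ds_out"):
                if col in sel:
                    arr = sel[col].astype(float).to_numpy()
                    vals[col] = arr[np.isfinite(arr)]  # saturated genes excluded

            def _mean(key: str) -> float:
                arr = vals.get(key, np.array([]))
                return float(arr.mean()) if len(arr) else np.nan

            mean_ds = _mean("ds")
            mean_dn = _mean("dn")
            mean_om = _mean("omega")
            mean_out = _mean("ds_out")

        mean_ratio = mean_fst = np.nan
        if window_stats is not None and len(window_stats):
            sel = window_stats[(window_stats["start"] >= start) & (window_stats["start"] < end)]
            if "depth_ratio" in sel:
                mean_ratio = float(sel["depth_ratio"].mean())
            if "fst" in sel:
                mean_fst = float(sel["fst"].mean())
                vals["fst"] = sel["fst"].dropna().to_numpy()

        age = (
            estimate_stratum_age(mean_ds, mean_out, split_time_my)
            if np.isfinite(mean_ds) and np.isfinite(mean_out)
            else np.nan
        )
        per_stratum[label] = vals
        rows.append(
            StratumSegment(
                label=label,
                start=start,
                end=end,
                n_genes=n_genes,
                pct_hemizygous=pct_hemi,
                mean_depth_ratio=mean_ratio,
                mean_fst=mean_fst,
                mean_ds_xy=mean_ds,
                mean_dn_xy=mean_dn,
                mean_omega=mean_om,
                mean_ds_out=mean_out,
                age_my=age,
            )
        )

    table = pd.DataFrame([vars(r) for r in rows])

    # pairwise Mann–Whitney U between strata
    pw_rows = []
    labels = list(per_stratum)
    for a, b in itertools.combinations(labels, 2):
        for stat in ("ds", "dn", "omega", "fst"):
            xa = per_stratum[a].get(stat, np.array([]))
            xb = per_stratum[b].get(stat, np.array([]))
            if len(xa) < 2 or len(xb) < 2:
                continue
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            pw_rows.append(
                {"stratum_a": a, "stratum_b": b, "statistic": stat,
                 "u": res.statistic, "p_raw": res.pvalue}
            )
    pairwise = pd.DataFrame(pw_rows)
    if len(pairwise):
        order = np.argsort(pairwise["p_raw"].to_numpy())
        m = len(pairwise)
        holm = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            adj = (m - rank) * pairwise["p_raw"].iloc[i]
            running = max(running, min(1.0, adj))
            holm[i] = running
        pairwise["p_holm"] = holm
    return table, pairwise
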