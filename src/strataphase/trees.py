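"""Window gene trees, monophyly fractions and SDR-homology topology calls.

Within one species, a region where X–Y recombination has ceased shows all Y
sequences in a single clade (Y monophyly); a recombining PAR intermingles X
and Y tips.  Across species, the arrangement of the four X/Y clades
distinguishes an SDR inherited from the common ancestor, SDRs of
independent origin, and X-to-Y turnover.

Trees are built by neighbor joining on pairwise Hamming distances with
pairwise deletion of missing sites; any externally supplied Newick tree per
window is accepted in place of the bundled NJ path, since the topology
logic — not tree inference — is the point of this module.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .containers import MISSING, GameteMatrix

TOPOLOGY_CLASSES = (
    "ANCESTRAL_SDR",
    "INDEPENDENT_SDR",
    "TURNOVER",
    "PAR_BOTH",
    "SDR_A_PAR_B",
    "OTHER",
)


@dataclass
class TreeWindowStat:
    """Per-window tree with X/Y monophyly fractions."""

    chrom: str
    start: int
    end: int
    newick: str | None
    n_snps: int
    n_tips: int
    y_monophyly_fraction: float = np.nan
    x_monophyly_fraction: float = np.nan
    uninformative: bool = False


@dataclass
class TopologyCall:
    """Evolutionary-history class assigned to one window's multispecies tree."""

    chrom: str
    start: int
    end: int
    call: str
    pattern: str = ""
    passes_prefilter: bool = True


# ---------------------------------------------------------------------------
# distances and NJ

def hamming_distances(seqs: dict[str, np.ndarray]) -> DistanceMatrix:
    """Pairwise Hamming distance with pairwise deletion of missing sites.

    ``seqs`` maps tip label to an integer vector with -1 for missing.  Pairs
    with no shared called site get the maximal observed distance plus a
    small increment rather than NaN, so NJ stays defined.
    """
    ids = list(seqs)
    mat = np.stack([np.asarray(seqs[i]) for i in ids])
    called = mat != MISSING
    n = len(ids)
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            ns = int(shared.sum())
            if ns == 0:
                undefined.append((i, j))
                continue
            d[i, j] = d[j, i] = float(np.mean(mat[i, shared] != mat[j, shared]))
    if undefined:
        fill = d.max() * 1.5 if d.max() > 0 else 1.0
        for i, j in undefined:
            d[i, j] = d[j, i] = fill
    return DistanceMatrix(d, ids)


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string keeping underscores in tip labels verbatim."""
    return TreeNode.read([newick], convert_underscores=False)


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> TreeNode:
    """Neighbor-joining tree, rooted on the outgroup when given."""
    tree = nj(dm)
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    return tree


def root_on_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    names = {t.name for t in tree.tips()}
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among tree tips")
    rooted = tree.root_by_outgroup([outgroup])
    # rooting round-trips through newick, which maps '_' to ' '; undo it
    for node in rooted.traverse(include_self=True):
        if node.name and " " in node.name and node.name not in names:
            fixed = node.name.replace(" ", "_")
            if fixed in names:
                node.name = fixed
    return rooted


def _ensure_rooted(tree: TreeNode, outgroup: str | None) -> TreeNode:
    if len(tree.children) <= 2:
        return tree
    if outgroup is None:
        raise ValueError("unrooted tree and no outgroup declared for rooting")
    return root_on_outgroup(tree, outgroup)


# ---------------------------------------------------------------------------
# monophyly

def clade_tip_sets(tree: TreeNode) -> list[frozenset[str]]:
    """Tip-name sets of every node (clades of a rooted tree), tips included."""
    out = []
    for node in tree.postorder(include_self=True):
        out.append(frozenset(t.name for t in node.tips(include_self=True)))
    return out


def monophyly_fraction(
    tree: TreeNode, class_tips, outgroup: str | None = None
) -> float:
    """Fraction of a class's tips inside the largest clade made only of that class.

    Equals 1 exactly when the class is monophyletic.  The tree must be
    rooted; unrooted input is rooted on the declared outgroup first.
    """
    class_tips = frozenset(class_tips)
    if not class_tips:
        raise ValueError("empty tip class")
    tree = _ensure_rooted(tree, outgroup)
    names = {t.name for t in tree.tips()}
    absent = class_tips - names
    if absent:
        raise ValueError(f"class tips absent from tree: {sorted(absent)}")
    best = 1  # a single tip is always a (trivial) clade
    for clade in clade_tip_sets(tree):
        if clade <= class_tips:
            best = max(best, len(clade))
    return best / len(class_tips)


# ---------------------------------------------------------------------------
# window trees from phased gametes

def build_window_trees(
    gm: GameteMatrix,
    windows: np.ndarray,
    outgroup_hap: np.ndarray | None = None,
    min_snps: int = 5,
    min_sequences: int = 4,
    outgroup_label: str = "OUT",
) -> list[TreeWindowStat]:
    """NJ tree and monophyly fractions for each genomic window.

    Tips are the phased Y gametes (``Y_<family>``) and paternal X gametes
    (``X_<family>``); an outgroup haplotype over the same sites roots the
    trees.  Windows with fewer than ``min_snps`` variable sites or fewer
    than ``min_sequences`` usable sequences are skipped (tree left None).
    """
    y = gm.haplotypes("paternal_son")
    x = gm.haplotypes("paternal_daughter")
    out: list[TreeWindowStat] = []
    for start, end in windows:
        m = ((gm.pos - 1) >= start) & ((gm.pos - 1) < end)
        n_snps = int(m.sum())
        stat = TreeWindowStat(gm.chrom, int(start), int(end), None, n_snps, 0)
        if n_snps < min_snps:
            out.append(stat)
            continue
        seqs: dict[str, np.ndarray] = {}
        for f, fam in enumerate(gm.families):
            yv, xv = y[m, f], x[m, f]
            if (yv != MISSING).sum() > 0:
                seqs[f"Y_{fam}"] = yv
            if (xv != MISSING).sum() > 0:
                seqs[f"X_{fam}"] = xv
        if outgroup_hap is not None:
            seqs[outgroup_label] = np.asarray(outgroup_hap)[m]
        if len(seqs) < min_sequences:
            out.append(stat)
            continue
        dm = hamming_distances(seqs)
        if np.all(dm.data == 0):
            stat.uninformative = True
            stat.n_tips = len(seqs)
            out.append(stat)
            continue
        rooted = outgroup_hap is not None
        tree = nj_tree(dm, outgroup=outgroup_label if rooted else None)
        y_tips = [s for s in seqs if s.startswith("Y_")]
        x_tips = [s for s in seqs if s.startswith("X_")]
        stat.newick = str(tree).strip()
        stat.n_tips = len(seqs)
        # monophyly is defined on rooted trees only
        if rooted and y_tips:
            stat.y_monophyly_fraction = monophyly_fraction(tree, y_tips)
        if rooted and x_tips:
            stat.x_monophyly_fraction = monophyly_fraction(tree, x_tips)
        out.append(stat)
    return out


def tree_stats_frame(stats: list[TreeWindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "n_tips": s.n_tips,
                "y_monophyly_fraction": s.y_monophyly_fraction,
                "x_monophyly_fraction": s.x_monophyly_fraction,
                "uninformative": s.uninformative,
                "newick": s.newick,
            }
            for s in stats
        ]
    )


# ---------------------------------------------------------------------------
# multispecies topology classification

def _tip_groups(tree: TreeNode, species: tuple[str, str], outgroup: str):
    groups: dict[tuple[str, str], set[str]] = {
        (sp, cl): set() for sp in species for cl in ("X", "Y")
    }
    for tip in tree.tips():
        if tip.name == outgroup:
            continue
        parts = tip.name.split("_")
        if len(parts) >= 2 and parts[0] in species and parts[1] in ("X", "Y"):
            groups[(parts[0], parts[1])].add(tip.name)
    return groups


def classify_topology(
    tree: TreeNode | str,
    species: tuple[str, str] = ("A", "B"),
    outgroup: str = "OUT",
    chrom: str = "",
    start: int = 0,
    end: int = 0,
) -> TopologyCall:
    """Assign one multispecies gene tree to an SDR-history class.

    Tips must be labelled ``<species>_<X|Y>_<i>`` plus one outgroup tip.
    The prefilter retains trees with four reciprocally monophyletic
    X/Y-by-species clades, or with monophyletic species clades; all other
    trees are OTHER (implausible arrangements, typically phasing error).

    Classes: both Ys sister and both Xs sister → ANCESTRAL_SDR; within-
    species X+Y clades for both species → INDEPENDENT_SDR; one species' Y
    nested inside the X assemblage → TURNOVER; species clades with X and Y
    intermingled in both → PAR_BOTH; one species with discrete X and Y
    clades and the other intermingled → SDR_A_PAR_B.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    tree = _ensure_rooted(tree, outgroup)
    sp_a, sp_b = species
    groups = _tip_groups(tree, species, outgroup)
    absent = [f"{sp}_{cl}" for (sp, cl), tips in groups.items() if not tips]
    if absent:
        raise ValueError(f"tree is missing required groups: {absent}")

    ax, ay = groups[(sp_a, "X")], groups[(sp_a, "Y")]
    bx, by = groups[(sp_b, "X")], groups[(sp_b, "Y")]
    clades = set(clade_tip_sets(tree))

    def mono(*tip_sets) -> bool:
        merged = frozenset().union(*tip_sets)
        return merged in clades

    all4 = all(mono(s) for s in (ax, ay, bx, by))
    species_mono = mono(ax, ay) and mono(bx, by)

    def call(c: str, pattern: str, ok: bool = True) -> TopologyCall:
        return TopologyCall(chrom, int(start), int(end), c, pattern, ok)

    if all4:
        if mono(ay, by) and mono(ax, bx):
            return call("ANCESTRAL_SDR", "(A_Y,B_Y) and (A_X,B_X) clades")
        if species_mono:
            return call("INDEPENDENT_SDR", "(A_X,A_Y) and (B_X,B_Y) clades")
        if mono(ax, ay) and mono(ax, ay, bx):
            return call("TURNOVER", f"{sp_a}_Y nested within the X assemblage")
        if mono(bx, by) and mono(bx, by, ax):
            return call("TURNOVER", f"{sp_b}_Y nested within the X assemblage")
        return call("OTHER", "four monophyletic clades, unexpected arrangement")

    if species_mono:
        a_sdr = mono(ax) and mono(ay)
        b_sdr = mono(bx) and mono(by)
        if not a_sdr and not b_sdr:
            return call("PAR_BOTH", "X and Y intermingled within both species")
        if a_sdr != b_sdr:
            which = sp_a if a_sdr else sp_b
            return call("SDR_A_PAR_B", f"SDR in {which}, PAR in the other species")
        return call("OTHER", "species clades with partially resolved classes")

    return call("OTHER", "fails reciprocal-monophyly prefilter", ok=False)


def topology_tally(calls: list[TopologyCall]) -> pd.Series:
    """Class counts over a set of windows (Supplementary-style tally)."""
    counts = Counter(c.call for c in calls)
    return pd.Series({cls: counts.get(cls, 0) for cls in TOPOLOGY_CLASSES})


def majority_topology(calls: list[TopologyCall]) -> tuple[str, pd.Series]:
    """Per-stratum majority vote: the most common class is taken as the
    region's true history (rarer classes usually reflect genotyping or
    phasing error)."""
    tally = topology_tally(calls)
    informative = tally.drop("OTHER")
    if informative.sum() == 0:
        return "OTHER", tally
    return str(informative.idxmax()), tally
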