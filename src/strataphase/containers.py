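"""In-memory containers shared across the pipeline.

Genotypes are stored as ALT-allele dosages (0, 1, 2) with -1 for missing.
Phased gamete calls are haploid ALT dosages (0, 1) with -1 for missing or
masked sites.  Coordinates are 1-based positions (VCF convention); window
arithmetic elsewhere is half-open ``[start, end)`` in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class Pedigree:
    """Mapping of quartet families to sample names.

    One row per family with father, mother, son and daughter sample ids,
    matching the sample columns of the quartet VCF.
    """

    table: pd.DataFrame  # columns: family, father, mother, son, daughter

    REQUIRED = ("family", "father", "mother", "son", "daughter")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table lacks columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def families(self) -> list[str]:
        return list(self.table["family"])

    @property
    def n_families(self) -> int:
        return len(self.table)

    def sample_roles(self) -> dict[str, tuple[str, str]]:
        """Return ``{sample_name: (family, role)}``."""
        out: dict[str, tuple[str, str]] = {}
        for _, row in self.table.iterrows():
            for role in ("father", "mother", "son", "daughter"):
                out[row[role]] = (row["family"], role)
        return out

    def indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        """Column indices of each role in VCF sample order, family-ordered."""
        pos = {s: i for i, s in enumerate(samples)}
        out = {}
        for role in ("father", "mother", "son", "daughter"):
            try:
                out[role] = np.array([pos[s] for s in self.table[role]], dtype=int)
            except KeyError as exc:
                raise ValueError(f"pedigree sample {exc} absent from VCF samples") from exc
        return out


@dataclass
class QuartetGenotypes:
    """Biallelic-SNP genotype matrix for a set of quartet families."""

    chrom: str
    pos: np.ndarray          # (n_sites,) int64, 1-based, strictly increasing
    ref: np.ndarray          # (n_sites,) single-character bases
    alt: np.ndarray
    qual: np.ndarray         # (n_sites,) float
    gt: np.ndarray           # (n_sites, n_samples) int8 ALT dosage, -1 missing
    dp: np.ndarray           # (n_sites, n_samples) int32 read depth
    gq: np.ndarray           # (n_sites, n_samples) int16 genotype quality
    ad_alt: np.ndarray       # (n_sites, n_samples) int32 ALT-supporting reads
    samples: list[str]
    pedigree: Pedigree

    def __post_init__(self) -> None:
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites × samples")
        if len(self.pos) > 1 and np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, mask_or_idx: np.ndarray) -> "QuartetGenotypes":
        return QuartetGenotypes(
            chrom=self.chrom,
            pos=self.pos[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            qual=self.qual[mask_or_idx],
            gt=self.gt[mask_or_idx],
            dp=self.dp[mask_or_idx],
            gq=self.gq[mask_or_idx],
            ad_alt=self.ad_alt[mask_or_idx],
            samples=self.samples,
            pedigree=self.pedigree,
        )

    def role_matrix(self, field_name: str, role: str) -> np.ndarray:
        """(n_sites, n_families) view of one FORMAT field for one role."""
        idx = self.pedigree.indices(self.samples)[role]
        return getattr(self, field_name)[:, idx]


GAMETE_CLASSES = ("paternal_son", "paternal_daughter", "maternal_son", "maternal_daughter")


@dataclass
class GameteMatrix:
    """Haploid transmitted-gamete calls, one column per family.

    On a sex chromosome, ``paternal_son`` is the Y-bearing sperm and
    ``paternal_daughter`` the X-bearing sperm.  Values are ALT dosages in
    {0, 1} with -1 for missing/ambiguous/violating sites.
    """

    chrom: str
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    families: list[str]
    paternal_son: np.ndarray      # (n_sites, n_families) int8
    paternal_daughter: np.ndarray
    maternal_son: np.ndarray
    maternal_daughter: np.ndarray
    report: pd.DataFrame = field(default_factory=pd.DataFrame)
    father_het: np.ndarray | None = None  # (n_sites, n_families) bool

    def __post_init__(self) -> None:
        shape = (len(self.pos), len(self.families))
        for name in GAMETE_CLASSES:
            if getattr(self, name).shape != shape:
                raise ValueError(f"gamete matrix {name} has wrong shape")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def haplotypes(self, which: str) -> np.ndarray:
        """Stack of haploid columns for one gamete class (sites × families)."""
        if which not in GAMETE_CLASSES:
            raise ValueError(f"unknown gamete class {which!r}")
        return getattr(self, which)

    def take_sites(self, mask_or_idx: np.ndarray) -> "GameteMatrix":
        return GameteMatrix(
            chrom=self.chrom,
            pos=self.pos[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            families=self.families,
            paternal_son=self.paternal_son[mask_or_idx],
            paternal_daughter=self.paternal_daughter[mask_or_idx],
            maternal_son=self.maternal_son[mask_or_idx],
            maternal_daughter=self.maternal_daughter[mask_or_idx],
            report=self.report,
            father_het=None if self.father_het is None else self.father_het[mask_or_idx],
        )


def make_windows(chrom_length_bp: int, window_bp: int) -> np.ndarray:
    """Half-open tiling windows ``[(start, end), ...]`` covering a chromosome."""
    starts = np.arange(0, chrom_length_bp, window_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, chrom_length_bp)
    return np.column_stack([starts, ends])


def window_index(pos: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Index of the window containing each 1-based position (-1 if none)."""
    idx = np.searchsorted(windows[:, 0], pos - 1, side="right") - 1
    ok = (idx >= 0) & ((pos - 1) < windows[np.clip(idx, 0, None), 1])
    return np.where(ok, idx, -1)
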