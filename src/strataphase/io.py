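"""Readers and writers for the standard interchange formats.

Quartet genotypes travel as multi-sample VCF v4.2 with GT:DP:AD:GQ; phased
gametes as a haploid "gamete VCF" with one pseudo-sample per transmitted
gamete; pedigrees and gene annotations as TSV/BED.  VCF parsing goes through
cyvcf2; writing is plain deterministic text so that regenerating a simulated
data set with the same seed yields a byte-identical file.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GAMETE_CLASSES, MISSING, GameteMatrix, Pedigree, QuartetGenotypes


class VcfFormatError(ValueError):
    """Raised when a VCF lacks a FORMAT field the pipeline requires."""


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a pedigree TSV with columns family/father/mother/son/daughter."""
    return Pedigree(pd.read_csv(path, sep="\t", dtype=str))


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene table: BED (chrom/start/end/name) or TSV with headers."""
    with open(path) as fh:
        first = fh.readline()
    if first.lower().startswith(("chrom\t", "gene_id\t", "#")):
        df = pd.read_csv(path, sep="\t", comment="#")
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"]
        )
    required = {"chrom", "start", "end", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table must provide columns {sorted(required)}")
    return df


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_quartet_vcf(q: QuartetGenotypes, path: str | os.PathLike) -> None:
    """Write quartet genotypes as VCF v4.2 with GT:DP:AD:GQ per sample."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=strataphase-simcross",
        f"##contig=<ID={q.chrom}>",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(q.samples),
    ]
    ns = len(q.samples)
    for i in range(q.n_sites):
        fields = [
            q.chrom,
            str(int(q.pos[i])),
            ".",
            str(q.ref[i]),
            str(q.alt[i]),
            f"{q.qual[i]:g}",
            "PASS",
            f"NS={ns}",
            "GT:DP:AD:GQ",
        ]
        for j in range(ns):
            dp = int(q.dp[i, j])
            ad1 = int(q.ad_alt[i, j])
            fields.append(
                f"{_GT_STRINGS[int(q.gt[i, j])]}:{dp}:{dp - ad1},{ad1}:{int(q.gq[i, j])}"
            )
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_quartet_vcf(path: str | os.PathLike, pedigree: Pedigree) -> QuartetGenotypes:
    """Load biallelic SNPs from a multi-sample VCF into a genotype matrix.

    Multiallelic records and indels are skipped.  Requires GT, DP and GQ
    FORMAT fields; AD is optional (zeros if absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    fmt_ids = {
        h.info().get("ID")
        for h in vcf.header_iter()
        if h.type == "FORMAT"
    }
    for needed in ("GT", "DP", "GQ"):
        if needed not in fmt_ids:
            raise VcfFormatError(f"VCF {path} lacks required FORMAT field {needed}")
    has_ad = "AD" in fmt_ids

    samples = list(vcf.samples)
    pos, ref, alt, qual = [], [], [], []
    gt_rows, dp_rows, gq_rows, ad_rows = [], [], [], []
    chrom = None
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        chrom = v.CHROM
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        gts = v.gt_types.astype(np.int8)  # 0,1,2 dosage; 3=unknown with gts012
        gts[gts == 3] = MISSING
        gt_rows.append(gts)
        dp = v.format("DP")
        dp_rows.append(np.where(dp < 0, 0, dp).astype(np.int32).ravel())
        gq = v.format("GQ")
        gq_rows.append(np.where(gq < 0, 0, gq).astype(np.int16).ravel())
        if has_ad:
            ad = v.format("AD")
            ad_alt = ad[:, 1] if ad is not None and ad.shape[1] > 1 else np.zeros(len(samples))
            ad_rows.append(np.where(ad_alt < 0, 0, ad_alt).astype(np.int32))
        else:
            ad_rows.append(np.zeros(len(samples), dtype=np.int32))
    if chrom is None:
        raise ValueError(f"no biallelic SNPs found in {path}")
    return QuartetGenotypes(
        chrom=chrom,
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        qual=np.array(qual, dtype=float),
        gt=np.vstack(gt_rows),
        dp=np.vstack(dp_rows),
        gq=np.vstack(gq_rows),
        ad_alt=np.vstack(ad_rows),
        samples=samples,
        pedigree=pedigree,
    )


_HAP_STRINGS = {0: "0", 1: "1", MISSING: "."}

_GAMETE_SUFFIX = {
    "paternal_son": "patY",
    "paternal_daughter": "patX",
    "maternal_son": "matS",
    "maternal_daughter": "matD",
}


def write_gamete_vcf(gm: GameteMatrix, path: str | os.PathLike) -> None:
    """Write phased gametes as a haploid VCF, one pseudo-sample per gamete."""
    names = [
        f"{fam}_{_GAMETE_SUFFIX[cls]}" for cls in GAMETE_CLASSES for fam in gm.families
    ]
    lines = [
        "##fileformat=VCFv4.2",
        "##source=strataphase-phasing",
        f"##contig=<ID={gm.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid gamete allele">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names),
    ]
    mats = [gm.haplotypes(cls) for cls in GAMETE_CLASSES]
    for i in range(gm.n_sites):
        calls = [
            _HAP_STRINGS[int(m[i, f])] for m in mats for f in range(len(gm.families))
        ]
        lines.append(
            "\t".join(
                [gm.chrom, str(int(gm.pos[i])), ".", str(gm.ref[i]), str(gm.alt[i]),
                 ".", "PASS", ".", "GT"] + calls
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gamete_vcf(path: str | os.PathLike) -> GameteMatrix:
    """Read a haploid gamete VCF written by :func:`write_gamete_vcf`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    suffix_to_cls = {v: k for k, v in _GAMETE_SUFFIX.items()}
    parsed = [(n.rsplit("_", 1)[0], suffix_to_cls[n.rsplit("_", 1)[1]]) for n in names]
    families = list(dict.fromkeys(fam for fam, _ in parsed))
    fam_idx = {f: i for i, f in enumerate(families)}

    pos, ref, alt, rows = [], [], [], []
    chrom = None
    for v in vcf:
        chrom = v.CHROM
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        # haploid GT: first allele of genotype call
        alleles = np.array([g[0] for g in v.genotypes], dtype=np.int8)
        rows.append(alleles)
    if chrom is None:
        raise ValueError(f"no records in {path}")
    calls = np.vstack(rows)  # (n_sites, n_gametes)
    out = {
        cls: np.full((len(pos), len(families)), MISSING, dtype=np.int8)
        for cls in GAMETE_CLASSES
    }
    for col, (fam, cls) in enumerate(parsed):
        out[cls][:, fam_idx[fam]] = calls[:, col]
    return GameteMatrix(
        chrom=chrom,
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        families=families,
        **out,
    )


def write_truth_tables(truth, outdir: str | os.PathLike) -> None:
    """Dump the generator truth record as TSV files."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    truth.strata_table.to_csv(os.path.join(outdir, "strata_truth.tsv"), sep="\t", index=False)
    truth.duplicated_windows.to_csv(
        os.path.join(outdir, "duplications_truth.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"gene_id": truth.deleted_gene_ids}).to_csv(
        os.path.join(outdir, "deleted_genes_truth.tsv"), sep="\t", index=False
    )
    if truth.error_log is not None:
        truth.error_log.to_csv(os.path.join(outdir, "error_log.tsv"), sep="\t", index=False)
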