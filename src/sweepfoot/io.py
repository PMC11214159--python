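"""Readers and writers for the formats the pipeline consumes and emits.

FASTA goes through Bio.SeqIO, minimal VCF through cyvcf2, JASPAR PFMs
through Bio.motifs and CSV tables through pandas.  All sequence input is
normalized to upper case; coordinates in BED output are 0-based
half-open; floats in tabular output are written at 6 significant digits.
CSV/TSV files written here carry '#'-prefixed header comments recording
the seed and parameters that produced them, and the readers skip such
comments.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ParseError
from .morpho import MorphoMatrix
from .popgen import HaplotypeWindow
from .qtl import CrossData
from .tfbs import PFM

__all__ = [
    "read_fasta",
    "write_fasta",
    "fasta_to_window",
    "read_vcf_minimal",
    "vcf_to_window",
    "read_snp_positions",
    "read_cross",
    "write_cross",
    "read_morpho",
    "write_morpho",
    "write_bed",
    "read_jaspar_pfm",
    "read_mask",
]


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str, str]]:
    """(id, description, upper-cased sequence) per record."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, str(rec.seq).upper()))
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_fasta(path, records: Iterable[tuple[str, str]],
                header_params: dict | None = None) -> None:
    """Write (id, sequence) records; ``header_params`` (seed etc.) are
    appended to the first record's description line."""
    recs = []
    for i, (rid, seq) in enumerate(records):
        desc = ""
        if i == 0 and header_params:
            desc = " ".join(f"{k}={_fmt(v)}" for k, v in header_params.items())
        recs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def fasta_to_window(path, ancestral_id: str) -> HaplotypeWindow:
    """Aligned FASTA -> haplotype window; one record is the ancestral."""
    recs = read_fasta(path)
    anc = [s for rid, _, s in recs if rid == ancestral_id]
    if not anc:
        raise InputError(
            f"ancestral record {ancestral_id!r} not found in {path} "
            f"(records: {[r[0] for r in recs][:6]}...)"
        )
    samples = tuple(s for rid, _, s in recs if rid != ancestral_id)
    return HaplotypeWindow(samples, anc[0])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_minimal(path, fail_on_unphased: bool = False) -> pd.DataFrame:
    """Minimal VCF reader: CHROM, POS, REF, ALT and per-haplotype alleles.

    Only biallelic SNP records are kept; multi-allelic ALT rows are
    skipped with a warning (infinite-sites pipeline).  Diploid genotypes
    are expanded to two haplotype columns per sample assuming phased GTs;
    ``fail_on_unphased=True`` raises on any unphased heterozygote.
    Haplotype columns hold 0 (REF), 1 (ALT) or -1 (missing).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows = []
    haps = []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record at {var.CHROM}:{var.POS}")
            continue
        gt = []
        for g in var.genotypes:  # [allele0, allele1, ..., phased]
            alleles, phased = g[:-1], g[-1]
            if fail_on_unphased and len(alleles) == 2 and not phased \
                    and alleles[0] != alleles[1] and -1 not in alleles:
                raise InputError(
                    f"unphased heterozygote at {var.CHROM}:{var.POS}")
            gt.extend(int(a) for a in alleles)
        rows.append((var.CHROM, var.POS, var.REF.upper(),
                     var.ALT[0].upper()))
        haps.append(gt)
    if not rows:
        raise ParseError(f"no usable records in {path}")
    width = max(len(h) for h in haps)
    if any(len(h) != width for h in haps):
        raise ParseError("inconsistent ploidy across records")
    df = pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT"])
    hap_df = pd.DataFrame(haps, columns=[f"hap{i}" for i in range(width)])
    return pd.concat([df, hap_df], axis=1)


def vcf_to_window(path, locus_length: int, start: int = 0,
                  fail_on_unphased: bool = False) -> HaplotypeWindow:
    """Build a haplotype window from a minimal VCF.

    Sites absent from the VCF are ancestral-identical; the REF allele is
    taken as ancestral (use a FASTA alignment with a true outgroup when
    available — VCF REF polarization is a convenience, not a substitute).
    """
    df = read_vcf_minimal(path, fail_on_unphased)
    hap_cols = [c for c in df.columns if c.startswith("hap")]
    n = len(hap_cols)
    anc = np.zeros(locus_length, dtype="<U1")
    anc[:] = "A"
    hap = np.tile(anc, (n, 1))
    for _, row in df.iterrows():
        j = int(row["POS"]) - 1 - start
        if not 0 <= j < locus_length:
            raise InputError(f"VCF POS {row['POS']} outside the locus")
        anc[j] = row["REF"][0]
        hap[:, j] = row["REF"][0]
        for i, c in enumerate(hap_cols):
            a = row[c]
            hap[i, j] = "N" if a < 0 else (row["ALT"][0] if a else row["REF"][0])
    return HaplotypeWindow(
        tuple("".join(r) for r in hap), "".join(anc), start,
        start + locus_length,
    )


def read_snp_positions(path) -> np.ndarray:
    """0-based SNP positions from a minimal VCF (*.vcf) or 1-column TSV."""
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        df = read_vcf_minimal(path)
        return df["POS"].to_numpy(np.int64) - 1
    tab = pd.read_csv(path, sep="\t", comment="#", header=None)
    return tab.iloc[:, -1].to_numpy(np.int64)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kw)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_cross(geno_csv, map_csv, pheno_csv) -> CrossData:
    """CrossData from three CSVs: genotype matrix (rows = individuals,
    codes b/h/-), map (marker, lg, cM) and phenotype table."""
    geno = _read_csv(geno_csv, index_col=0, dtype=str)
    cmap = _read_csv(map_csv, index_col=0)
    if not {"lg", "cM"} <= set(cmap.columns):
        raise InputError("map CSV needs 'lg' and 'cM' columns")
    pheno = _read_csv(pheno_csv, index_col=0)
    return CrossData(genotypes=geno, map=cmap, phenotypes=pheno)


def _write_csv(df: pd.DataFrame, path, header_params: dict | None) -> None:
    with open(path, "w") as fh:
        if header_params:
            fh.write("# " + " ".join(
                f"{k}={_fmt(v)}" for k, v in header_params.items()) + "\n")
        df.to_csv(fh, float_format="%.6g")


def write_cross(cross: CrossData, geno_csv, map_csv, pheno_csv,
                header_params: dict | None = None) -> None:
    codes = cross.genotypes.copy()
    codes = codes.map(lambda v: "-" if pd.isna(v) else ("h" if v == 1.0 else "b"))
    _write_csv(codes, geno_csv, header_params)
    _write_csv(cross.map, map_csv, header_params)
    _write_csv(cross.phenotypes, pheno_csv, header_params)


def read_morpho(path, group_col: str = "group") -> MorphoMatrix:
    df = _read_csv(path, index_col=0)
    if group_col not in df.columns:
        raise InputError(f"morphometric CSV needs a {group_col!r} column")
    group = df[group_col]
    values = df.drop(columns=[group_col])
    return MorphoMatrix(values=values, group=group)


def write_morpho(matrix: MorphoMatrix, path,
                 header_params: dict | None = None) -> None:
    df = matrix.values.copy()
    df.insert(0, "group", matrix.group)
    _write_csv(df, path, header_params)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(path, rows: Sequence[Sequence], header_comment: str | None = None,
              extra_names: Sequence[str] = ()) -> None:
    """BED6(+) writer: rows of (chrom, start, end, name, score, strand,
    *extras); start < end and 0-based half-open are enforced."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if extra_names:
            fh.write("# chrom start end name score strand "
                     + " ".join(extra_names) + "\n")
        for row in rows:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            if start < 0 or end <= start:
                raise InputError(f"invalid BED interval {start}-{end}")
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs and coding masks
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path) -> list[PFM]:
    """JASPAR flat-format PFMs (">ID NAME" plus four count rows)."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PFM(id=m.matrix_id or m.name, name=m.name or "",
                       counts=counts))
    if not out:
        raise ParseError(f"no PFMs found in {path}")
    return out


def read_mask(path, length: int) -> np.ndarray:
    """Boolean mask (True = masked column) from a BED or GFF3 feature file.

    BED intervals are 0-based half-open; GFF3 are 1-based inclusive.
    Intervals beyond `length` are clipped.
    """
    mask = np.zeros(length, dtype=bool)
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3"))
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    start, end = int(parts[3]) - 1, int(parts[4])
                else:
                    start, end = int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"bad interval in {path}", line=ln) from exc
            mask[max(0, start):min(length, end)] = True
    return mask
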