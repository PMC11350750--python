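"""Readers and writers for the tabular inputs and reports.

All genomic TSV tables are 1-based inclusive; BED files are 0-based
half-open and converted on read.  Writers always emit 1-based TSV with a
header row and rows sorted deterministically so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .core import (
    GeneRecord,
    GenomicInterval,
    InputError,
    MarkerProbe,
    OrthologPair,
    QtlRecord,
)

log = logging.getLogger("equiprio")

PathLike = Union[str, Path]

# genotype = unordered pair of allele symbols; None = missing call
Genotype = Optional[Tuple[str, str]]


def _read_tsv(path: PathLike, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except FileNotFoundError:
        raise InputError(f"input file not found: {path}")


def read_qtl_table(path: PathLike) -> List[QtlRecord]:
    """QTL TSV: qtl_id, species, trait_category, chrom, start, end, peak.

    Interval rows fill start/end and leave peak empty; peak rows the
    reverse.  All coordinates 1-based.
    """
    df = _read_tsv(path)
    out: List[QtlRecord] = []
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if str(row.peak).strip():
            out.append(
                QtlRecord(
                    qtl_id=row.qtl_id,
                    species=row.species,
                    trait_category=row.trait_category,
                    form="peak",
                    peak=(chrom, int(row.peak)),
                )
            )
        else:
            out.append(
                QtlRecord(
                    qtl_id=row.qtl_id,
                    species=row.species,
                    trait_category=row.trait_category,
                    form="interval",
                    interval=GenomicInterval(chrom, int(row.start), int(row.end)),
                )
            )
    return out


def read_gene_table(path: PathLike) -> List[GeneRecord]:
    """Gene TSV: gene_id, symbol, species, chrom, start, end[, strand, biotype, assembly]."""
    df = _read_tsv(path)
    genes: List[GeneRecord] = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.gene_id in seen:
            raise InputError(f"duplicate gene_id in gene table: {row.gene_id}")
        seen.add(row.gene_id)
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                symbol=row.symbol,
                species=row.species,
                interval=GenomicInterval(
                    str(row.chrom),
                    int(row.start),
                    int(row.end),
                    getattr(row, "assembly", ""),
                ),
                strand=getattr(row, "strand", "unknown") or "unknown",
                biotype=getattr(row, "biotype", "protein_coding") or "protein_coding",
            )
        )
    return genes


def read_ortholog_table(path: PathLike) -> List[OrthologPair]:
    """Ortholog TSV: source_gene_id, target_gene_id, pct_identity, pct_similarity."""
    df = _read_tsv(path)

    def _f(v: str) -> Optional[float]:
        v = str(v).strip()
        return float(v) if v else None

    return [
        OrthologPair(
            source_gene_id=row.source_gene_id,
            target_gene_id=row.target_gene_id,
            percent_identity=_f(row.pct_identity),
            percent_similarity=_f(row.pct_similarity),
        )
        for row in df.itertuples(index=False)
    ]


def read_manifest(path: PathLike) -> List[MarkerProbe]:
    """Array manifest CSV: probe_name, chrom, position[, allele_a, allele_b]."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise InputError(f"input file not found: {path}")
    probes = []
    for row in df.itertuples(index=False):
        alleles = None
        a = getattr(row, "allele_a", "")
        b = getattr(row, "allele_b", "")
        if str(a).strip() and str(b).strip():
            alleles = (str(a), str(b))
        probes.append(
            MarkerProbe(
                probe_name=row.probe_name,
                chrom=str(row.chrom),
                position=int(row.position),
                alleles=alleles,
            )
        )
    return probes


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """BED (0-based half-open) -> 1-based closed intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]) + 1, int(f[2])))
    return out


def read_regulatory_bed(path: PathLike) -> List[Tuple[GenomicInterval, str]]:
    """BED with 4th column = feature type (promoter/enhancer/open_chromatin/...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise InputError(f"regulatory BED line lacks a feature type: {line!r}")
            out.append((GenomicInterval(f[0], int(f[1]) + 1, int(f[2])), f[3]))
    return out


def write_bed(path: PathLike, intervals: List[GenomicInterval], names: Optional[List[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if names is not None:
                cols.append(names[i])
            fh.write("\t".join(cols) + "\n")


def read_vep_table(path: PathLike) -> Dict[str, dict]:
    """VEP-style TSV keyed by SNP id.

    Columns: Uploaded_variation, Location (``chrom:pos``), Consequence
    (comma-separated terms), Extra (``;``-separated ``k=v``; CANONICAL=YES
    marks the canonical transcript) and optionally Feature (transcript id).
    One row per (variant, transcript).  Returns
    ``{snp_id: {"location": (chrom, pos), "consequences": [(transcript,
    term, canonical), ...]}}``.
    """
    df = _read_tsv(path)
    out: Dict[str, dict] = {}
    for row in df.itertuples(index=False):
        snp = row.Uploaded_variation
        chrom, pos = str(row.Location).split(":")
        loc = (chrom, int(pos))
        extra = getattr(row, "Extra", "") or ""
        canonical = "CANONICAL=YES" in extra
        transcript = getattr(row, "Feature", "") or "-"
        rec = out.setdefault(snp, {"location": loc, "consequences": []})
        if rec["location"] != loc:
            raise InputError(
                f"SNP {snp} reported at two locations: {rec['location']} vs {loc}"
            )
        for term in str(row.Consequence).split(","):
            term = term.strip()
            if term:
                rec["consequences"].append((transcript, term, canonical))
    return out


def read_gerp_table(path: PathLike) -> Dict[Tuple[str, int], float]:
    """GERP TSV: chrom, pos, score.  Missing sites are simply absent."""
    df = _read_tsv(path)
    return {
        (str(row.chrom), int(row.pos)): float(row.score)
        for row in df.itertuples(index=False)
        if str(row.score).strip()
    }


def read_genotypes_tsv(path: PathLike) -> Dict[Tuple[str, str], Genotype]:
    """Genotype TSV: snp_id, breed, allele1, allele2 (both empty = missing).

    Returns ``{(snp_id, breed): (a1, a2) | None}``.
    """
    df = _read_tsv(path)
    out: Dict[Tuple[str, str], Genotype] = {}
    for row in df.itertuples(index=False):
        a1, a2 = str(row.allele1).strip(), str(row.allele2).strip()
        out[(row.snp_id, row.breed)] = (a1, a2) if a1 and a2 else None
    return out


def read_genotypes_vcf(path: PathLike) -> Dict[Tuple[str, str], Genotype]:
    """VCF with one sample column per breed; GT is decoded to allele symbols.

    The variant id column supplies the SNP id.  ``./.`` becomes a missing
    genotype.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: Dict[Tuple[str, str], Genotype] = {}
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        snp_id = var.ID or f"{var.CHROM}_{var.POS}"
        for i, sample in enumerate(samples):
            g = var.genotypes[i]  # [a1, a2, phased]
            if g[0] < 0 or g[1] < 0:
                out[(snp_id, sample)] = None
            else:
                out[(snp_id, sample)] = (alleles[g[0]], alleles[g[1]])
    return out


def read_protein_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(path: PathLike, df: pd.DataFrame) -> None:
    """Deterministic TSV output (no index, '\\n' line endings)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
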