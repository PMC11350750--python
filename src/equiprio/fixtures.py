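"""Packaged reference fixture: the published priority table and its
companion lists.

``data/published_priority_table.tsv`` transcribes the 28 published priority-table rows (gene,
marker, SNP, consequence, the four criterion checkmarks, phenotype flag,
and the bold breed-differs flag) together with the evidence needed to
*recompute* the checkmarks.  Evidence provenance:

* GERP scores and regulatory feature types printed in the study are used
  verbatim (e.g. 4.15 for rs396701927, 0.72 for rs68875002, open chromatin
  for rs68514854, promoter for rs68670656);
* genomic positions are real where the study prints them (3:107374136,
  11:23334511, 18:67027762, 18:65173441, 18:65288583) and SYNTHETIC spaced
  placeholders elsewhere — position only feeds interval-overlap flags, which
  the fixture constructs consistently either way;
* unprinted GERP scores are SYNTHETIC values on the correct side of the
  threshold (2.5-style values never occur: sub-threshold filler is 0.5/0.8,
  and every above-threshold score is a printed one).

``data/duplicate_groups.tsv`` transcribes the seven duplicate-probe groups
(16 probes, 7 positions); ``data/breed_genotypes.tsv`` carries the breed
genotype contrast table (seven pairs printed in the results, two more from
the discussion, one SYNTHETIC differing pair for rs68876315 whose genotypes
were never printed, and identical-genotype filler for the non-bold SNPs).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .annotation import VariantAnnotation
from .core import GenomicInterval, MarkerLocus, MarkerProbe
from .io import Genotype

_FLAG_COLS = ["protein_effect", "gerp_gt2", "constrained", "regulatory"]


def _data_path(name: str):
    return resources.files("equiprio.data").joinpath(name)


def published_table_rows() -> pd.DataFrame:
    """The transcribed priority table: 28 rows, one per (gene, marker, SNP).

    Boolean columns (0/1): the four criteria, ``phenotype``,
    ``breed_differs``.
    """
    with resources.as_file(_data_path("published_priority_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in _FLAG_COLS + ["phenotype", "breed_differs"]:
        df[col] = df[col].astype(int).astype(bool)
    df["position"] = df["position"].astype(int)
    df["gerp_score"] = df["gerp_score"].astype(float)
    return df


def published_table_evidence() -> Tuple[
    List[MarkerLocus],
    Dict[Tuple[str, int], VariantAnnotation],
    List[GenomicInterval],
    Set[str],
]:
    """Rebuild the raw evidence behind the priority table.

    Returns ``(loci, annotations, constrained_elements,
    phenotype_genes)`` — everything :func:`equiprio.annotation.annotate`
    needs to recompute the four criterion flags from scratch, so tests can
    compare the recomputation against the transcribed checkmarks.
    Constrained elements are 21-bp SYNTHETIC elements centred on each
    constrained-checked position (the study reports membership, not element
    bounds).
    """
    df = published_table_rows()

    loci: List[MarkerLocus] = []
    annotations: Dict[Tuple[str, int], VariantAnnotation] = {}
    constrained: List[GenomicInterval] = []

    for (chrom, pos), grp in df.groupby(["chrom", "position"], sort=False):
        probes = tuple(dict.fromkeys(grp["probe_name"]))
        genes = tuple(dict.fromkeys(grp["gene_symbol"]))
        loci.append(MarkerLocus(chrom=chrom, position=int(pos), probe_names=probes, gene_ids=genes))

        row = grp.iloc[0]
        consequences = [("canonical_tx", row["consequence"], True)]
        extra = row.get("consequence_extra", "")
        if extra:
            consequences.append(("other_tx", extra, False))
        annotations[(chrom, int(pos))] = VariantAnnotation(
            snp_id=row["snp_id"],
            chrom=chrom,
            position=int(pos),
            consequences=tuple(consequences),
            gerp=float(row["gerp_score"]),
            regulatory_feature=row["regulatory_type"],
        )
        if bool(row["constrained"]):
            constrained.append(GenomicInterval(chrom, int(pos) - 10, int(pos) + 10))

    phenotype_genes = set(df.loc[df["phenotype"], "gene_symbol"])
    return loci, annotations, constrained, phenotype_genes


def published_genotypes() -> Dict[Tuple[str, str], Genotype]:
    """Breed genotype table keyed by ``(snp_id, breed)``; breeds are ``P``
    (Percheron) and ``AM`` (American Miniature)."""
    from .io import read_genotypes_tsv

    with resources.as_file(_data_path("breed_genotypes.tsv")) as p:
        return read_genotypes_tsv(p)


def duplicate_group_probes() -> List[MarkerProbe]:
    """The seven published duplicate-probe groups as 16 probes."""
    with resources.as_file(_data_path("duplicate_groups.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return [
        MarkerProbe(probe_name=r.probe_name, chrom=str(r.chrom), position=int(r.position))
        for r in df.itertuples(index=False)
    ]


def appendix_probes() -> List[MarkerProbe]:
    """A 278-probe manifest whose positional dedup yields 268 loci.

    The published appendix list itself is not machine-readable, so this is
    a SYNTHETIC reconstruction honouring its stated arithmetic: the 16 real
    probes of the seven duplicate groups (9 surplus probes) plus 262
    synthetic filler probes of which one duplicates another's position —
    the published groups account for only 9 of the 10 surplus probes
    (278 - 268 = 10), so the tenth duplicate is synthesized.  Construction
    is deterministic (no RNG).
    """
    probes = duplicate_group_probes()
    real_positions = {(p.chrom, p.position) for p in probes}
    filler: List[MarkerProbe] = []
    pos = 1_000_000
    while len(filler) < 261:
        pos += 7_919  # fixed stride; collision with real positions skipped
        if ("3", pos) in real_positions:
            continue
        filler.append(
            MarkerProbe(probe_name=f"APPX_{len(filler):03d}", chrom="3", position=pos)
        )
    # the tenth surplus probe: a second probe at the first filler position
    filler.append(
        MarkerProbe(
            probe_name="APPX_000_DUP", chrom="3", position=filler[0].position
        )
    )
    out = probes + filler
    assert len(out) == 278
    return out


def published_bundle() -> dict:
    """Everything the fixture offers, in one mapping (used by the CLI's
    ``fixture`` subcommand and the acceptance checks)."""
    loci, annotations, constrained, phenotype_genes = published_table_evidence()
    return {
        "rows": published_table_rows(),
        "loci": loci,
        "annotations": annotations,
        "constrained": constrained,
        "phenotype_genes": phenotype_genes,
        "genotypes": published_genotypes(),
        "duplicate_groups": duplicate_group_probes(),
        "appendix_probes": appendix_probes(),
    }
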