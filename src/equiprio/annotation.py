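"""Per-variant evidence and its classification into the four
prioritization criteria.

A marker earns a criterion flag when it

* ``protein_effect`` — carries a consequence term predicted to alter the
  protein product on ANY overlapping transcript, not only the canonical one
  (a variant can be missense on the canonical transcript and 5' UTR on
  another; the canonical-only scan would miss nothing here but the
  all-transcript scan is what the screen uses);
* ``gerp_gt2`` — has a GERP rejected-substitutions score strictly greater
  than 2.0 (missing score never qualifies; 0 is a real score);
* ``constrained`` — lies inside a constrained element (closed-interval
  overlap, boundary positions included);
* ``regulatory`` — overlaps an orthologous regulatory feature of type
  promoter, enhancer or open_chromatin (CTCF/TF-binding-only features do
  not qualify).

All four are pure functions of the evidence bundle, so re-annotation is
idempotent and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import ConflictingAnnotationError, GenomicInterval
from .markers import MarkerLocus

log = logging.getLogger("equiprio")

DEFAULT_GERP_THRESHOLD = 2.0

#: consequence terms (normalized) that can alter the protein product
PROTEIN_AFFECTING_TERMS = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor",
        "splice_donor",
        "splice_donor_region",
    }
)

#: consequence terms that are recognized but never protein-affecting
_BENIGN_TERMS = frozenset(
    {
        "intron",
        "intronic",
        "intergenic",
        "upstream_gene",
        "downstream_gene",
        "3_prime_utr",
        "5_prime_utr",
        "synonymous",
        "non_coding_transcript",
        "non_coding_transcript_exon",
        "splice_region",
        "splice_polypyrimidine_tract",
        "splice_donor_5th_base",
        "regulatory_region",
        "tf_binding_site",
    }
)

#: regulatory feature types that satisfy the regulatory criterion
QUALIFYING_REGULATORY_TYPES = frozenset({"promoter", "enhancer", "open_chromatin"})


def normalize_consequence(term: str) -> str:
    """Map display and VEP spellings onto one canonical token.

    ``"missense variant"``, ``"missense_variant"`` and ``"stop-lost"``
    normalize to ``"missense"`` / ``"stop_lost"``; a trailing ``variant``
    word is dropped; separators collapse to underscores.
    """
    t = term.strip().lower().replace("-", " ").replace("_", " ")
    t = " ".join(t.split())
    for suffix in (" variant",):
        if t.endswith(suffix):
            t = t[: -len(suffix)]
    t = t.replace("'", " prime").replace("’", " prime")
    t = "_".join(t.split())
    return t


@dataclass(frozen=True)
class CriterionFlags:
    """The four boolean prioritization criteria for one marker."""

    protein_effect: bool = False
    gerp_gt2: bool = False
    constrained: bool = False
    regulatory: bool = False

    def any(self) -> bool:
        return self.protein_effect or self.gerp_gt2 or self.constrained or self.regulatory

    def as_tuple(self) -> Tuple[bool, bool, bool, bool]:
        return (self.protein_effect, self.gerp_gt2, self.constrained, self.regulatory)


@dataclass(frozen=True)
class VariantAnnotation:
    """Evidence bundle for one SNP.

    ``consequences`` is a list of ``(transcript_id, term, canonical)``;
    ``gerp`` of ``None`` means no score available (distinct from 0.0);
    ``regulatory_feature`` is ``"none"`` or a feature type string.
    """

    snp_id: str
    chrom: str
    position: int
    consequences: Tuple[Tuple[str, str, bool], ...] = ()
    gerp: Optional[float] = None
    regulatory_feature: str = "none"


def classify_protein_effect(
    consequences: Sequence[Tuple[str, str, bool]],
) -> bool:
    """True iff any transcript's consequence term is protein-affecting.

    Unknown terms are logged once and treated as non-protein-affecting.
    """
    hit = False
    for _transcript, term, _canonical in consequences:
        norm = normalize_consequence(term)
        if norm in PROTEIN_AFFECTING_TERMS:
            hit = True
        elif norm not in _BENIGN_TERMS:
            log.warning("unknown consequence term %r treated as non-protein-affecting", term)
    return hit


def gerp_flag(gerp: Optional[float], threshold: float = DEFAULT_GERP_THRESHOLD) -> bool:
    """Strictly greater-than test; missing scores never pass."""
    return gerp is not None and gerp > threshold


def constrained_flag(
    chrom: str, position: int, constrained_elements: Sequence[GenomicInterval]
) -> bool:
    """True iff the position lies inside any constrained element
    (closed intervals; element boundaries included)."""
    return any(iv.contains_point(chrom, position) for iv in constrained_elements)


def regulatory_flag(
    annotation: VariantAnnotation,
    qualifying_types: frozenset = QUALIFYING_REGULATORY_TYPES,
) -> bool:
    """True iff the variant overlaps an orthologous regulatory feature whose
    type qualifies (promoter, enhancer, open chromatin)."""
    return annotation.regulatory_feature in qualifying_types


def compute_flags(
    annotation: VariantAnnotation,
    constrained_elements: Sequence[GenomicInterval],
    gerp_threshold: float = DEFAULT_GERP_THRESHOLD,
) -> CriterionFlags:
    return CriterionFlags(
        protein_effect=classify_protein_effect(annotation.consequences),
        gerp_gt2=gerp_flag(annotation.gerp, gerp_threshold),
        constrained=constrained_flag(
            annotation.chrom, annotation.position, constrained_elements
        ),
        regulatory=regulatory_flag(annotation),
    )


@dataclass(frozen=True)
class AnnotatedMarker:
    """One (probe, SNP, gene) row with its criterion flags — the unit the
    prioritization rule consumes."""

    probe_name: str
    snp_id: str
    gene_id: str
    chrom: str
    position: int
    consequence: str  # display label, most severe term seen
    flags: CriterionFlags


def build_annotation_index(
    vep: Dict[str, dict],
    gerp: Dict[Tuple[str, int], float],
    regulatory: Sequence[Tuple[GenomicInterval, str]],
) -> Dict[Tuple[str, int], VariantAnnotation]:
    """Fuse VEP, GERP and regulatory tracks into one per-position bundle.

    Two VEP records mapping distinct SNP ids to one position raise
    :class:`ConflictingAnnotationError` (the join would be ambiguous).
    """
    out: Dict[Tuple[str, int], VariantAnnotation] = {}
    for snp_id in sorted(vep):
        rec = vep[snp_id]
        chrom, pos = rec["location"]
        key = (chrom, pos)
        if key in out and out[key].snp_id != snp_id:
            raise ConflictingAnnotationError(
                f"position {chrom}:{pos} annotated under two SNP ids: "
                f"{out[key].snp_id} and {snp_id}"
            )
        reg_type = "none"
        for iv, ftype in regulatory:
            if iv.contains_point(chrom, pos):
                reg_type = ftype
                break
        out[key] = VariantAnnotation(
            snp_id=snp_id,
            chrom=chrom,
            position=pos,
            consequences=tuple(rec["consequences"]),
            gerp=gerp.get(key),
            regulatory_feature=reg_type,
        )
    return out


def _display_consequence(consequences: Sequence[Tuple[str, str, bool]]) -> str:
    """Pick a display term: prefer a protein-affecting term, then a
    canonical-transcript term, then the first term seen."""
    if not consequences:
        return "unannotated"
    for _t, term, _c in consequences:
        if normalize_consequence(term) in PROTEIN_AFFECTING_TERMS:
            return term
    for _t, term, canonical in consequences:
        if canonical:
            return term
    return consequences[0][1]


def annotate(
    loci: Sequence[MarkerLocus],
    annotations: Dict[Tuple[str, int], VariantAnnotation],
    constrained_elements: Sequence[GenomicInterval],
    gerp_threshold: float = DEFAULT_GERP_THRESHOLD,
) -> List[AnnotatedMarker]:
    """Join marker loci with evidence and emit one flagged row per
    (probe_name, snp_id, gene) triple.

    Loci without any annotation record get all-false flags, a synthesized
    ``chrom_pos`` SNP id and a log entry.  Output order follows the locus
    order, then probe order within a locus, then gene order.
    """
    rows: List[AnnotatedMarker] = []
    for locus in loci:
        key = (locus.chrom, locus.position)
        ann = annotations.get(key)
        if ann is None:
            log.info("no annotation for locus %s:%d; all-false flags", *key)
            ann = VariantAnnotation(
                snp_id=f"{locus.chrom}_{locus.position}",
                chrom=locus.chrom,
                position=locus.position,
            )
        flags = compute_flags(ann, constrained_elements, gerp_threshold)
        display = _display_consequence(ann.consequences)
        gene_ids = locus.gene_ids or ("",)
        for probe_name in locus.probe_names:
            for gene_id in gene_ids:
                rows.append(
                    AnnotatedMarker(
                        probe_name=probe_name,
                        snp_id=ann.snp_id,
                        gene_id=gene_id,
                        chrom=locus.chrom,
                        position=locus.position,
                        consequence=display,
                        flags=flags,
                    )
                )
    return rows
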