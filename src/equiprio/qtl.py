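"""Source-species QTL -> candidate gene selection -> ortholog transfer.

The screen keeps source genes that fall inside trait QTLs of at least ``k``
distinct trait categories (the multi-category rule), then maps the survivors
to the target species through a precomputed ortholog table.  Genes without
an ortholog are dropped and logged (the source of the screen's attrition).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Set

from intervaltree import IntervalTree

from .core import GeneRecord, GenomicInterval, OrthologPair, QtlRecord, extend_interval

log = logging.getLogger("equiprio")

# category label -> set of source gene ids
CategoryGeneSets = Dict[str, Set[str]]

DEFAULT_PEAK_FLANK = 5000


def qtl_to_interval(q: QtlRecord, peak_flank: int = DEFAULT_PEAK_FLANK) -> GenomicInterval:
    """Interval-form QTLs pass through; peak-form QTLs become the peak
    position extended by ``peak_flank`` on both sides (left-clamped at 1)."""
    if q.form == "interval":
        assert q.interval is not None
        return q.interval
    chrom, pos = q.peak  # type: ignore[misc]
    return extend_interval(GenomicInterval(chrom, pos, pos), peak_flank)


def genes_in_qtls(
    qtls: Sequence[QtlRecord],
    genes: Sequence[GeneRecord],
    peak_flank: int = DEFAULT_PEAK_FLANK,
) -> CategoryGeneSets:
    """Per trait category, the set of genes overlapping any of its QTLs.

    Overlap is closed-interval and requires >= 1 bp; a gene hit by two QTLs
    of the same category is counted once.  Empty QTL list -> empty mapping.
    """
    # one interval tree per chromosome over gene spans; tree coords are
    # half-open so a closed interval [s, e] is stored as [s, e + 1)
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        iv = g.interval
        trees[iv.chrom].addi(iv.start, iv.end + 1, g.gene_id)

    sets: CategoryGeneSets = {}
    for q in qtls:
        span = qtl_to_interval(q, peak_flank)
        hits = trees[span.chrom].overlap(span.start, span.end + 1)
        bucket = sets.setdefault(q.trait_category, set())
        bucket.update(h.data for h in hits)
    return sets


def genes_in_min_categories(sets: CategoryGeneSets, k: int = 2) -> Set[str]:
    """Genes present in at least ``k`` category sets (monotone decreasing
    in ``k``); ``k`` larger than the category count yields the empty set."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: Dict[str, int] = defaultdict(int)
    for members in sets.values():
        for gid in members:
            counts[gid] += 1
    return {gid for gid, n in counts.items() if n >= k}


def transfer_orthologs(
    source_genes: Iterable[str],
    pairs: Sequence[OrthologPair],
    target_genes: Sequence[GeneRecord],
) -> List[GeneRecord]:
    """Map source gene ids to target-species GeneRecords via the ortholog
    table.

    Source genes without any usable pair are dropped and logged; one-to-many
    orthologs are all retained (and logged).  Output is unique per target
    gene, sorted by gene_id for determinism.
    """
    by_target = {g.gene_id: g for g in target_genes}
    by_source: Dict[str, List[OrthologPair]] = defaultdict(list)
    for p in pairs:
        by_source[p.source_gene_id].append(p)

    picked: Dict[str, GeneRecord] = {}
    dropped: List[str] = []
    for gid in sorted(set(source_genes)):
        usable = [p for p in by_source.get(gid, []) if p.target_gene_id in by_target]
        if not usable:
            dropped.append(gid)
            continue
        if len(usable) > 1:
            log.info(
                "source gene %s has %d orthologs (one-to-many), keeping all",
                gid,
                len(usable),
            )
        for p in usable:
            picked[p.target_gene_id] = by_target[p.target_gene_id]
    if dropped:
        log.info(
            "%d source gene(s) dropped for lack of a target ortholog: %s",
            len(dropped),
            ", ".join(dropped),
        )
    return [picked[t] for t in sorted(picked)]
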