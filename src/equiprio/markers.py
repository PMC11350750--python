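"""Chip-marker extraction within flank-extended candidate gene regions,
and positional deduplication of probes.

A probe inside the extended regions of two genes is attributed to both
(regions are never merged); duplicate probes assaying the same
(chrom, position) collapse to one locus that carries the union of their
gene attributions.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

from intervaltree import IntervalTree

from .core import GeneRecord, GenomicInterval, MarkerLocus, MarkerProbe, extend_interval

DEFAULT_GENE_FLANK = 5000


def candidate_regions(
    genes: Sequence[GeneRecord], flank: int = DEFAULT_GENE_FLANK
) -> List[Tuple[str, GenomicInterval]]:
    """One ``(gene_id, extended interval)`` per gene; overlapping regions of
    different genes are retained separately so a marker can be attributed to
    several genes."""
    return [(g.gene_id, extend_interval(g.interval, flank)) for g in genes]


def markers_in_regions(
    manifest: Sequence[MarkerProbe],
    regions: Sequence[Tuple[str, GenomicInterval]],
) -> List[Tuple[MarkerProbe, str]]:
    """Every (probe, gene_id) pair where the probe position falls inside the
    gene's extended interval (closed bounds).  Many-to-many by construction.
    Output sorted by (chrom, position, probe_name, gene_id)."""
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene_id, iv in regions:
        trees[iv.chrom].addi(iv.start, iv.end + 1, gene_id)

    pairs: List[Tuple[MarkerProbe, str]] = []
    for probe in manifest:
        for hit in trees[probe.chrom].at(probe.position):
            pairs.append((probe, hit.data))
    pairs.sort(key=lambda pg: (pg[0].chrom, pg[0].position, pg[0].probe_name, pg[1]))
    return pairs


def deduplicate_probes(
    probes: Sequence[MarkerProbe],
    gene_map: Dict[str, Sequence[str]] | None = None,
) -> List[MarkerLocus]:
    """Group probes by exact (chrom, position) into loci.

    Alleles and probe chemistry are ignored — the key is positional only.
    Probe counts are conserved (sum of group sizes equals the input probe
    count, after dropping exact repeats of the same probe name at the same
    position), each probe appears in exactly one locus, and the result is
    sorted by coordinate.  ``gene_map`` (probe_name -> gene ids) lets dedup
    preserve the union of gene attributions per locus.
    """
    groups: Dict[Tuple[str, int], List[str]] = defaultdict(list)
    for p in probes:
        if p.probe_name not in groups[(p.chrom, p.position)]:
            groups[(p.chrom, p.position)].append(p.probe_name)

    def _chrom_key(chrom: str):
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom)

    loci = []
    for (chrom, pos) in sorted(groups, key=lambda cp: (_chrom_key(cp[0]), cp[1])):
        names = tuple(groups[(chrom, pos)])
        gene_ids: Tuple[str, ...] = ()
        if gene_map is not None:
            gene_ids = tuple(
                sorted({g for n in names for g in gene_map.get(n, ())})
            )
        loci.append(MarkerLocus(chrom=chrom, position=pos, probe_names=names, gene_ids=gene_ids))
    return loci


def extract_candidate_loci(
    manifest: Sequence[MarkerProbe],
    genes: Sequence[GeneRecord],
    flank: int = DEFAULT_GENE_FLANK,
) -> List[MarkerLocus]:
    """Composed stage: extend gene intervals, pull in-region probes, and
    collapse them to unique loci carrying their gene attributions."""
    regions = candidate_regions(genes, flank)
    pairs = markers_in_regions(manifest, regions)
    gene_map: Dict[str, List[str]] = defaultdict(list)
    seen_probes: Dict[str, MarkerProbe] = {}
    for probe, gene_id in pairs:
        if gene_id not in gene_map[probe.probe_name]:
            gene_map[probe.probe_name].append(gene_id)
        seen_probes[probe.probe_name] = probe
    return deduplicate_probes(list(seen_probes.values()), gene_map)
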