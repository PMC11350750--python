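"""The prioritization rule and its summary counts.

A marker is prioritized when ANY of the four criteria holds (flat union —
no criterion dominates, no ranking among survivors).  The counting units
follow the screen's reporting convention: "markers" are distinct
(probe_name, snp_id) pairs — one probe name can serve two SNPs and one SNP
can be listed under two overlapping genes — and "genes" are distinct gene
symbols, lncRNA ids included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .annotation import AnnotatedMarker, CriterionFlags


@dataclass(frozen=True)
class PriorityCall:
    """One report row: a marker-SNP-gene triple, its criteria and verdict.

    ``phenotype_flag`` marks genes linked to screened mammalian phenotypes
    (body weight/growth/size/fat/muscle/feed); it is consumed as an input
    annotation column and plays no part in the prioritization verdict.
    """

    gene_symbol: str
    probe_name: str
    snp_id: str
    consequence: str
    flags: CriterionFlags
    phenotype_flag: bool = False
    prioritized: bool = False
    chrom: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        # invariant: verdict is exactly the OR of the four flags
        assert self.prioritized == self.flags.any()


def prioritize(
    rows: Sequence[AnnotatedMarker],
    phenotype_genes: frozenset | set | None = None,
) -> List[PriorityCall]:
    """Apply the union-of-criteria rule to every annotated row.

    All rows are retained (the full report keeps non-prioritized markers;
    the priority table is the ``prioritized`` subset).  ``phenotype_genes``
    is an optional set of gene symbols carrying the phenotype annotation.
    """
    phenotype_genes = phenotype_genes or set()
    calls = []
    for r in rows:
        calls.append(
            PriorityCall(
                gene_symbol=r.gene_id,
                probe_name=r.probe_name,
                snp_id=r.snp_id,
                consequence=r.consequence,
                flags=r.flags,
                phenotype_flag=r.gene_id in phenotype_genes,
                prioritized=r.flags.any(),
                chrom=r.chrom,
                position=r.position,
            )
        )
    return calls


def summarize(calls: Sequence[PriorityCall]) -> Dict[str, int]:
    """Summary counts over the prioritized subset.

    Returns ``n_markers`` (distinct prioritized (probe_name, snp_id)
    pairs), ``n_genes`` (distinct prioritized gene symbols), one count per
    criterion (distinct marker pairs satisfying it) and
    ``n_phenotype_genes`` (distinct prioritized genes with the phenotype
    flag).  Invariant under row reordering.
    """
    pri = [c for c in calls if c.prioritized]
    pairs = {(c.probe_name, c.snp_id) for c in pri}
    genes = {c.gene_symbol for c in pri}

    def _pairs_where(pred) -> int:
        return len({(c.probe_name, c.snp_id) for c in pri if pred(c)})

    return {
        "n_markers": len(pairs),
        "n_genes": len(genes),
        "n_protein": _pairs_where(lambda c: c.flags.protein_effect),
        "n_gerp": _pairs_where(lambda c: c.flags.gerp_gt2),
        "n_constrained": _pairs_where(lambda c: c.flags.constrained),
        "n_regulatory": _pairs_where(lambda c: c.flags.regulatory),
        "n_phenotype_genes": len({c.gene_symbol for c in pri if c.phenotype_flag}),
    }
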