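"""Validation of prioritized markers.

Two independent checks:

1. **Breed genotype contrast** — compare genotypes at each prioritized SNP
   between a phenotypically large breed (Percheron) and a small one
   (American Miniature).  "Differs" means any inequality of the unordered
   allele multisets, so a heterozygote against a homozygote counts (the
   screen is a plausibility check, not a fixation test).  SNPs differing
   between the breeds are the *strong candidates*.

2. **Ortholog protein similarity** — orthologs whose proteins share >= 60%
   similarity are assumed functionally equivalent, justifying the
   cross-species transfer.  Similarity normally comes from the ortholog
   table; when absent it can be computed from protein sequences as global
   percent identity.

The percent identity statistic is defined deterministically: over all
optimal-score Needleman-Wunsch global alignments (match +1, mismatch 0,
linear gap -1), take the alignment with the most matched columns (ties
broken by fewest total columns) and report
``100 * matches / alignment columns`` (gap columns included in the
denominator).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .core import InputError, OrthologPair
from .prioritize import PriorityCall

log = logging.getLogger("equiprio")

Genotype = Optional[Tuple[str, str]]

DEFAULT_SIMILARITY_THRESHOLD = 60.0


@dataclass(frozen=True)
class ContrastResult:
    """Genotype comparison at one SNP between two breeds."""

    snp_id: str
    genotype_a: Genotype
    genotype_b: Genotype
    differs: bool
    evaluable: bool = True

    def __post_init__(self) -> None:
        # a missing genotype can never be called differing
        assert not (self.differs and not self.evaluable)


def genotypes_differ(g1: Genotype, g2: Genotype) -> bool:
    """True iff the unordered allele multisets are unequal.

    ``A|G`` equals ``G|A``; het vs. hom counts as differing.  Raises on a
    missing genotype — callers decide how to report non-evaluable SNPs.
    """
    if g1 is None or g2 is None:
        raise InputError("cannot compare a missing genotype")
    return Counter(g1) != Counter(g2)


def allele_sets_differ(genos_a: Sequence[Genotype], genos_b: Sequence[Genotype]) -> bool:
    """Multi-sample rule: breeds differ iff their observed allele sets are
    disjoint (no shared allele across any sample).  Missing calls ignored."""
    set_a = {a for g in genos_a if g is not None for a in g}
    set_b = {a for g in genos_b if g is not None for a in g}
    if not set_a or not set_b:
        raise InputError("cannot compare breeds with no called genotypes")
    return set_a.isdisjoint(set_b)


GenotypeTable = Dict[Tuple[str, str], Union[Genotype, List[Genotype]]]


def _as_list(v: Union[Genotype, List[Genotype]]) -> List[Genotype]:
    if v is None or isinstance(v, tuple):
        return [v]
    return list(v)


def contrast_breeds(
    calls: Sequence[PriorityCall],
    genotypes: GenotypeTable,
    breed_a: str,
    breed_b: str,
    mode: str = "representative",
) -> Tuple[List[ContrastResult], Dict[str, set]]:
    """Compare breed genotypes at every prioritized SNP.

    ``mode="representative"`` (default) compares one genotype per breed;
    ``mode="allele_sets"`` applies the multi-sample disjoint-allele-set
    rule.  Returns one :class:`ContrastResult` per distinct prioritized
    snp_id (sorted) and the strong-candidate sets
    ``{"snp_ids": ..., "genes": ...}`` — SNPs whose genotypes differ, plus
    the distinct genes those SNPs annotate.  Symmetric in the breed
    arguments.  SNPs absent from the table (or with a missing call) are
    reported as non-evaluable and logged.
    """
    if mode not in ("representative", "allele_sets"):
        raise InputError(f"unknown contrast mode {mode!r}")
    pri = [c for c in calls if c.prioritized]
    snp_genes: Dict[str, set] = {}
    for c in pri:
        snp_genes.setdefault(c.snp_id, set()).add(c.gene_symbol)

    results: List[ContrastResult] = []
    strong_snps: set = set()
    for snp_id in sorted(snp_genes):
        ga = genotypes.get((snp_id, breed_a))
        gb = genotypes.get((snp_id, breed_b))
        la, lb = _as_list(ga), _as_list(gb)
        rep_a = la[0] if la else None
        rep_b = lb[0] if lb else None
        if all(g is None for g in la) or all(g is None for g in lb):
            log.info("SNP %s not evaluable: missing genotype in %s or %s", snp_id, breed_a, breed_b)
            results.append(ContrastResult(snp_id, rep_a, rep_b, differs=False, evaluable=False))
            continue
        if mode == "representative":
            differs = genotypes_differ(rep_a, rep_b)
        else:
            differs = allele_sets_differ(la, lb)
        results.append(ContrastResult(snp_id, rep_a, rep_b, differs=differs))
        if differs:
            strong_snps.add(snp_id)

    strong_genes = {g for s in strong_snps for g in snp_genes[s]}
    return results, {"snp_ids": strong_snps, "genes": strong_genes}


def global_percent_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity of the optimal global (Needleman-Wunsch) alignment.

    Among all alignments attaining the optimal score, the one maximizing
    matched columns (then minimizing total columns) defines the statistic:
    ``100 * matches / columns``, gap columns counted in the denominator.
    Symmetric in its arguments; value in [0, 100].
    """
    if not seq_a or not seq_b:
        raise InputError("cannot align an empty sequence")
    m, n = len(seq_a), len(seq_b)
    NEG = float("-inf")

    # pass 1: optimal score, forward
    S = [[NEG] * (n + 1) for _ in range(m + 1)]
    S[0][0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i and S[i - 1][j] + gap > S[i][j]:
                S[i][j] = S[i - 1][j] + gap
            if j and S[i][j - 1] + gap > S[i][j]:
                S[i][j] = S[i][j - 1] + gap
            if i and j:
                d = S[i - 1][j - 1] + (match if seq_a[i - 1] == seq_b[j - 1] else mismatch)
                if d > S[i][j]:
                    S[i][j] = d

    # pass 2: backward scores, to identify edges on some optimal path
    B = [[NEG] * (n + 1) for _ in range(m + 1)]
    B[m][n] = 0.0
    for i in range(m, -1, -1):
        for j in range(n, -1, -1):
            if i < m and B[i + 1][j] + gap > B[i][j]:
                B[i][j] = B[i + 1][j] + gap
            if j < n and B[i][j + 1] + gap > B[i][j]:
                B[i][j] = B[i][j + 1] + gap
            if i < m and j < n:
                d = B[i + 1][j + 1] + (match if seq_a[i] == seq_b[j] else mismatch)
                if d > B[i][j]:
                    B[i][j] = d

    opt = S[m][n]

    def _on_optimal(i: int, j: int, w: float, pi: int, pj: int) -> bool:
        return S[pi][pj] + w + B[i][j] == opt

    # pass 3: along optimal edges only, maximize matches then minimize columns
    M = [[-1] * (n + 1) for _ in range(m + 1)]  # max matches
    C = [[0] * (n + 1) for _ in range(m + 1)]  # min columns at max matches
    M[0][0] = 0
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            best_m, best_c = -1, 0
            # incoming edges: gap-up, gap-left, diagonal
            if i and M[i - 1][j] >= 0 and _on_optimal(i, j, gap, i - 1, j):
                cand = (M[i - 1][j], C[i - 1][j] + 1)
                if cand[0] > best_m or (cand[0] == best_m and cand[1] < best_c):
                    best_m, best_c = cand
            if j and M[i][j - 1] >= 0 and _on_optimal(i, j, gap, i, j - 1):
                cand = (M[i][j - 1], C[i][j - 1] + 1)
                if cand[0] > best_m or (cand[0] == best_m and cand[1] < best_c):
                    best_m, best_c = cand
            if i and j and M[i - 1][j - 1] >= 0:
                is_match = seq_a[i - 1] == seq_b[j - 1]
                w = match if is_match else mismatch
                if _on_optimal(i, j, w, i - 1, j - 1):
                    cand = (M[i - 1][j - 1] + int(is_match), C[i - 1][j - 1] + 1)
                    if cand[0] > best_m or (cand[0] == best_m and cand[1] < best_c):
                        best_m, best_c = cand
            M[i][j], C[i][j] = best_m, best_c

    assert M[m][n] >= 0 and C[m][n] > 0
    return 100.0 * M[m][n] / C[m][n]


@dataclass(frozen=True)
class GateResult:
    """Similarity-gate verdict for one ortholog pair."""

    target_gene_id: str
    value: Optional[float]  # percent used for the gate
    provenance: str  # "table", "computed", or "none"
    passed: Optional[bool]  # None = non-evaluable


def similarity_gate(
    pairs: Sequence[OrthologPair],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    sequences: Optional[Dict[str, str]] = None,
) -> Dict[str, GateResult]:
    """Per target gene: does ortholog similarity reach the threshold?

    The gate is inclusive (``value >= threshold`` passes).  Table
    similarity is preferred; if absent and both protein sequences are
    supplied, global percent identity is computed instead (provenance
    ``"computed"``); with neither, the gene is non-evaluable.
    """
    out: Dict[str, GateResult] = {}
    for p in pairs:
        value: Optional[float] = p.percent_similarity
        provenance = "table"
        if value is None and sequences is not None:
            sa = sequences.get(p.source_gene_id)
            sb = sequences.get(p.target_gene_id)
            if sa and sb:
                value = global_percent_identity(sa, sb)
                provenance = "computed"
        if value is None:
            provenance = "none"
            log.info("ortholog %s->%s not evaluable for the similarity gate",
                     p.source_gene_id, p.target_gene_id)
        out[p.target_gene_id] = GateResult(
            target_gene_id=p.target_gene_id,
            value=value,
            provenance=provenance,
            passed=None if value is None else value >= threshold,
        )
    return out
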