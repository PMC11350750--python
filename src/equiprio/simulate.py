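"""Synthetic input bundles with planted ground truth.

The generator emulates the statistical shape of the real inputs — trait
QTLs in a handful of categories, a syntenic block of source genes hit by
QTLs of two categories, a partial ortholog map to the target species, an
array manifest at genotyping-chip density with a small duplicate-probe
fraction, and per-variant annotation tracks — while controlling exactly
which markers satisfy which prioritization criteria.  Planted markers
receive evidence satisfying exactly their assigned criteria; every other
marker satisfies none, so pipeline output can be compared against truth
with strict equality.

It does NOT attempt realistic linkage disequilibrium, allele-frequency
spectra, or real chromosome lengths; see the package methods note.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    GeneRecord,
    GenomicInterval,
    InfeasibleScenarioError,
    MarkerProbe,
    OrthologPair,
    QtlRecord,
    extend_interval,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic scenario.

    Defaults mirror the real screen where it states a condition: three
    trait categories with ~19 QTLs, 30 multi-category source genes in one
    syntenic block, ortholog coverage 0.73 (30 -> 22 attrition),
    chip density ~30 probes/Mb, per-criterion planted counts equal to the
    published table tallies (protein 8, conservation 8, constrained 7,
    regulatory 12) and 10 breed-divergent prioritized SNPs.  The genome is
    scaled down (3 chromosomes x 20 Mb).
    """

    seed: int = 1
    n_chroms: int = 3
    chrom_length: int = 20_000_000
    n_source_genes: int = 120
    n_target_genes: int = 120
    gene_length_min: int = 5_000
    gene_length_max: int = 60_000
    n_categories: int = 3
    n_anchor_genes: int = 30  # multi-category source genes in the block
    anchor_block_length: int = 6_000_000
    n_extra_qtl_per_category: int = 4
    fraction_peak: float = 0.3
    ortholog_coverage: float = 0.73
    probes_per_mb: float = 30.0
    duplicate_fraction: float = 0.04
    min_probes_per_candidate_gene: int = 3
    planted_protein: int = 8
    planted_gerp: int = 8
    planted_constrained: int = 7
    planted_regulatory: int = 12
    n_decoy_ctcf: int = 3
    n_divergent_prioritized: int = 10
    n_divergent_background: int = 3
    het_divergent: bool = False
    phenotype_fraction: float = 0.36  # ~8 of 22 candidate genes
    peak_flank: int = 5000
    gene_flank: int = 5000
    gerp_conserved_range: Tuple[float, float] = (2.5, 5.0)
    gerp_neutral_range: Tuple[float, float] = (-2.0, 1.5)
    breed_a: str = "P"
    breed_b: str = "AM"


@dataclass
class SyntheticTruth:
    """Planted ground truth, mutually consistent with the emitted files."""

    multicategory_source_genes: Set[str] = field(default_factory=set)
    ortholog_target_genes: Set[str] = field(default_factory=set)
    candidate_loci: Set[Tuple[str, int]] = field(default_factory=set)
    criterion_snps: Dict[str, Set[str]] = field(default_factory=dict)
    prioritized_snps: Set[str] = field(default_factory=set)
    divergent_snps: Set[str] = field(default_factory=set)
    strong_snps: Set[str] = field(default_factory=set)
    phenotype_genes: Set[str] = field(default_factory=set)

    def to_json(self) -> str:
        d = {
            "multicategory_source_genes": sorted(self.multicategory_source_genes),
            "ortholog_target_genes": sorted(self.ortholog_target_genes),
            "candidate_loci": sorted(f"{c}:{p}" for c, p in self.candidate_loci),
            "criterion_snps": {k: sorted(v) for k, v in sorted(self.criterion_snps.items())},
            "prioritized_snps": sorted(self.prioritized_snps),
            "divergent_snps": sorted(self.divergent_snps),
            "strong_snps": sorted(self.strong_snps),
            "phenotype_genes": sorted(self.phenotype_genes),
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _place_genes(
    rng: np.random.Generator,
    n: int,
    prefix: str,
    species: str,
    chroms: Sequence[str],
    chrom_length: int,
    cfg: ScenarioConfig,
    forbidden: Optional[Tuple[str, int, int]] = None,
) -> List[GeneRecord]:
    """Scatter genes across chromosomes; ``forbidden`` excludes a
    (chrom, start, end) block from placement."""
    genes = []
    for i in range(n):
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
            start = int(rng.integers(1, chrom_length - length))
            end = start + length - 1
            if forbidden and chrom == forbidden[0] and not (
                end < forbidden[1] or start > forbidden[2]
            ):
                continue
            break
        genes.append(
            GeneRecord(
                gene_id=f"{prefix}{i:04d}",
                symbol=f"{prefix}{i:04d}",
                species=species,
                interval=GenomicInterval(chrom, start, end),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return genes


def generate_scenario(
    config: ScenarioConfig, out_dir: str | Path
) -> Tuple[Dict[str, Path], SyntheticTruth]:
    """Generate one complete input bundle under ``out_dir``.

    Returns ``(paths, truth)``.  The same seed produces a byte-identical
    bundle.  Raises :class:`InfeasibleScenarioError` before writing
    anything when the planted counts cannot be honoured.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [str(i + 1) for i in range(cfg.n_chroms)]
    truth = SyntheticTruth()

    # --- source genome: anchor block + background genes -------------------
    block_chrom = chroms[0]
    block_start = int(rng.integers(1_000_000, cfg.chrom_length - cfg.anchor_block_length))
    block_end = block_start + cfg.anchor_block_length - 1

    anchors: List[GeneRecord] = []
    step = cfg.anchor_block_length // max(1, cfg.n_anchor_genes)
    for i in range(cfg.n_anchor_genes):
        length = int(rng.integers(cfg.gene_length_min, min(cfg.gene_length_max, step) + 1))
        start = block_start + i * step + int(rng.integers(0, max(1, step - length)))
        anchors.append(
            GeneRecord(
                gene_id=f"SRC_A{i:04d}",
                symbol=f"SRC_A{i:04d}",
                species="source",
                interval=GenomicInterval(block_chrom, start, start + length - 1),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    n_background = max(0, cfg.n_source_genes - cfg.n_anchor_genes)
    background = _place_genes(
        rng, n_background, "SRC_B", "source", chroms, cfg.chrom_length, cfg,
        forbidden=(block_chrom, block_start - cfg.gene_length_max, block_end + cfg.gene_length_max),
    )
    source_genes = anchors + background
    truth.multicategory_source_genes = {g.gene_id for g in anchors}

    # --- QTLs: categories B and C tile the anchor block; category A and the
    # extras are background single-category QTLs ---------------------------
    categories = [f"category_{chr(ord('A') + i)}" for i in range(cfg.n_categories)]
    qtls: List[QtlRecord] = []
    qtl_n = 0

    def _add_interval(cat: str, chrom: str, start: int, end: int) -> None:
        nonlocal qtl_n
        qtl_n += 1
        qtls.append(
            QtlRecord(
                qtl_id=f"QTL{qtl_n:03d}",
                species="source",
                trait_category=cat,
                form="interval",
                interval=GenomicInterval(chrom, max(1, start), end),
            )
        )

    def _add_peak(cat: str, chrom: str, pos: int) -> None:
        nonlocal qtl_n
        qtl_n += 1
        qtls.append(
            QtlRecord(
                qtl_id=f"QTL{qtl_n:03d}",
                species="source",
                trait_category=cat,
                form="peak",
                peak=(chrom, pos),
            )
        )

    if cfg.n_anchor_genes and cfg.n_categories >= 2:
        third = cfg.anchor_block_length // 3
        for cat in categories[1:3]:
            for k in range(3):
                _add_interval(
                    cat,
                    block_chrom,
                    block_start + k * third,
                    block_start + (k + 1) * third - 1,
                )
    for cat in categories:
        for _ in range(cfg.n_extra_qtl_per_category):
            chrom = chroms[int(rng.integers(len(chroms)))]
            if rng.random() < cfg.fraction_peak:
                _add_peak(cat, chrom, int(rng.integers(1, cfg.chrom_length)))
            else:
                start = int(rng.integers(1, cfg.chrom_length - 500_000))
                _add_interval(cat, chrom, start, start + int(rng.integers(100_000, 500_000)))

    # brute-force verification: anchors really are multi-category ----------
    def _qtl_span(q: QtlRecord) -> GenomicInterval:
        if q.form == "interval":
            return q.interval  # type: ignore[return-value]
        c, p = q.peak  # type: ignore[misc]
        return extend_interval(GenomicInterval(c, p, p), cfg.peak_flank)

    cat_sets: Dict[str, Set[str]] = {}
    for q in qtls:
        span = _qtl_span(q)
        for g in source_genes:
            iv = g.interval
            if iv.chrom == span.chrom and max(iv.start, span.start) <= min(iv.end, span.end):
                cat_sets.setdefault(q.trait_category, set()).add(g.gene_id)
    counts: Dict[str, int] = {}
    for members in cat_sets.values():
        for gid in members:
            counts[gid] = counts.get(gid, 0) + 1
    truth.multicategory_source_genes = {g for g, n in counts.items() if n >= 2}

    # --- ortholog map ------------------------------------------------------
    target_genes = _place_genes(rng, cfg.n_target_genes, "TGT_G", "target", chroms, cfg.chrom_length, cfg)
    n_mapped = int(round(cfg.ortholog_coverage * cfg.n_source_genes))
    mapped_sources = sorted(
        rng.choice([g.gene_id for g in source_genes], size=n_mapped, replace=False)
    )
    target_ids = [g.gene_id for g in target_genes]
    mapped_targets = list(rng.choice(target_ids, size=n_mapped, replace=False))
    pairs: List[OrthologPair] = []
    for s, t in zip(mapped_sources, mapped_targets):
        ident = float(rng.uniform(62.0, 99.0))
        sim = min(100.0, ident + float(rng.uniform(0.0, 4.0)))
        pairs.append(OrthologPair(s, t, round(ident, 2), round(sim, 2)))
    pair_by_source = {p.source_gene_id: p for p in pairs}
    truth.ortholog_target_genes = {
        pair_by_source[s].target_gene_id
        for s in truth.multicategory_source_genes
        if s in pair_by_source
    }
    target_by_id = {g.gene_id: g for g in target_genes}
    candidate_genes = [target_by_id[t] for t in sorted(truth.ortholog_target_genes)]

    # --- chip manifest ------------------------------------------------------
    n_random = int(cfg.probes_per_mb * cfg.n_chroms * cfg.chrom_length / 1e6)
    positions: Set[Tuple[str, int]] = set()
    probes: List[MarkerProbe] = []
    k = 0

    def _add_probe(chrom: str, pos: int) -> None:
        nonlocal k
        probes.append(MarkerProbe(probe_name=f"PRB{k:06d}", chrom=chrom, position=pos))
        positions.add((chrom, pos))
        k += 1

    for _ in range(n_random):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, cfg.chrom_length))
        if (chrom, pos) not in positions:
            _add_probe(chrom, pos)
    for g in candidate_genes:
        region = extend_interval(g.interval, cfg.gene_flank)
        have = sum(1 for (c, p) in positions if c == region.chrom and region.start <= p <= region.end)
        for _ in range(max(0, cfg.min_probes_per_candidate_gene - have)):
            while True:
                pos = int(rng.integers(region.start, region.end + 1))
                if (region.chrom, pos) not in positions:
                    break
            _add_probe(region.chrom, pos)
    n_dup = int(cfg.duplicate_fraction * len(probes))
    if n_dup:
        dup_idx = rng.choice(len(probes), size=n_dup, replace=False)
        for i in sorted(int(i) for i in dup_idx):
            src = probes[i]
            probes.append(
                MarkerProbe(
                    probe_name=f"{src.probe_name}_DUP", chrom=src.chrom, position=src.position
                )
            )
    probes.sort(key=lambda p: (int(p.chrom), p.position, p.probe_name))

    # --- eligible loci (brute-force scan of manifest vs candidate regions) -
    regions = [extend_interval(g.interval, cfg.gene_flank) for g in candidate_genes]
    locus_positions = sorted(
        {
            (p.chrom, p.position)
            for p in probes
            if any(r.chrom == p.chrom and r.start <= p.position <= r.end for r in regions)
        },
        key=lambda cp: (int(cp[0]), cp[1]),
    )
    truth.candidate_loci = set(locus_positions)

    n_needed = max(
        cfg.planted_protein, cfg.planted_gerp, cfg.planted_constrained, cfg.planted_regulatory
    )
    if len(locus_positions) < n_needed:
        raise InfeasibleScenarioError(
            f"only {len(locus_positions)} candidate loci available but "
            f"{n_needed} planted sites requested"
        )

    # SNP ids: one per chip position, ordered by coordinate
    all_positions = sorted({(p.chrom, p.position) for p in probes}, key=lambda cp: (int(cp[0]), cp[1]))
    snp_of: Dict[Tuple[str, int], str] = {
        cp: f"rsS{i:06d}" for i, cp in enumerate(all_positions)
    }

    # --- plant the criteria -------------------------------------------------
    def _sample_loci(n: int) -> Set[Tuple[str, int]]:
        idx = rng.choice(len(locus_positions), size=n, replace=False)
        return {locus_positions[int(i)] for i in idx}

    planted: Dict[str, Set[Tuple[str, int]]] = {
        "protein_effect": _sample_loci(cfg.planted_protein),
        "gerp_gt2": _sample_loci(cfg.planted_gerp),
        "constrained": _sample_loci(cfg.planted_constrained),
        "regulatory": _sample_loci(cfg.planted_regulatory),
    }
    truth.criterion_snps = {
        crit: {snp_of[cp] for cp in members} for crit, members in planted.items()
    }
    prioritized_loci = sorted(
        set().union(*planted.values()), key=lambda cp: (int(cp[0]), cp[1])
    )
    truth.prioritized_snps = {snp_of[cp] for cp in prioritized_loci}

    # --- genotypes ----------------------------------------------------------
    non_prior = [cp for cp in locus_positions if cp not in set(prioritized_loci)]
    n_div = min(cfg.n_divergent_prioritized, len(prioritized_loci))
    div_idx = rng.choice(len(prioritized_loci), size=n_div, replace=False)
    divergent = {prioritized_loci[int(i)] for i in div_idx}
    n_bg = min(cfg.n_divergent_background, len(non_prior))
    bg_idx = rng.choice(len(non_prior), size=n_bg, replace=False) if n_bg else []
    divergent_bg = {non_prior[int(i)] for i in bg_idx}
    truth.divergent_snps = {snp_of[cp] for cp in divergent | divergent_bg}
    truth.strong_snps = {snp_of[cp] for cp in divergent}

    genotyped = sorted(set(prioritized_loci) | divergent_bg, key=lambda cp: (int(cp[0]), cp[1]))
    geno_rows: List[Tuple[str, str, str, str]] = []  # snp, breed, a1, a2
    vcf_rows: List[Tuple[str, int, str, str, str, str, str]] = []
    for i, cp in enumerate(genotyped):
        snp = snp_of[cp]
        if cp in divergent or cp in divergent_bg:
            if cfg.het_divergent and i % 2 == 0:
                ga, gb = ("A", "G"), ("G", "G")  # het vs hom still differs
            else:
                ga, gb = ("A", "A"), ("G", "G")
        else:
            ga = gb = ("A", "A")
        geno_rows.append((snp, cfg.breed_a, *ga))
        geno_rows.append((snp, cfg.breed_b, *gb))
        alleles = ["A", "G"]
        code = {a: str(alleles.index(a)) for a in alleles}
        vcf_rows.append(
            (cp[0], cp[1], snp, "A", "G",
             f"{code[ga[0]]}/{code[ga[1]]}", f"{code[gb[0]]}/{code[gb[1]]}")
        )

    # --- annotation tracks ---------------------------------------------------
    vep_lines = ["Uploaded_variation\tLocation\tFeature\tConsequence\tExtra"]
    for cp in all_positions:
        snp = snp_of[cp]
        loc = f"{cp[0]}:{cp[1]}"
        if cp in planted["protein_effect"]:
            vep_lines.append(f"{snp}\t{loc}\ttx_{snp}_1\tmissense_variant\tCANONICAL=YES")
            vep_lines.append(f"{snp}\t{loc}\ttx_{snp}_2\t5_prime_UTR_variant\t-")
        else:
            vep_lines.append(f"{snp}\t{loc}\ttx_{snp}_1\tintron_variant\tCANONICAL=YES")

    gerp_lines = ["chrom\tpos\tscore"]
    lo_c, hi_c = cfg.gerp_conserved_range
    lo_n, hi_n = cfg.gerp_neutral_range
    for cp in all_positions:
        if cp in planted["gerp_gt2"]:
            score = float(rng.uniform(lo_c, hi_c))
        else:
            score = float(rng.uniform(lo_n, hi_n))
        gerp_lines.append(f"{cp[0]}\t{cp[1]}\t{score:.4f}")

    pos_by_chrom: Dict[str, List[int]] = {}
    for c, p in all_positions:
        pos_by_chrom.setdefault(c, []).append(p)
    for v in pos_by_chrom.values():
        v.sort()

    def _safe_element(chrom: str, pos: int, halfwidth: int = 50) -> Tuple[int, int]:
        """An interval around pos that contains no other chip position."""
        import bisect

        arr = pos_by_chrom[chrom]
        i = bisect.bisect_left(arr, pos)
        left_gap = pos - arr[i - 1] - 1 if i > 0 else pos - 1
        right_gap = arr[i + 1] - pos - 1 if i + 1 < len(arr) else halfwidth
        w_l = max(0, min(halfwidth, left_gap, pos - 1))
        w_r = max(0, min(halfwidth, right_gap))
        return pos - w_l, pos + w_r

    constrained_sorted = sorted(planted["constrained"], key=lambda cp: (int(cp[0]), cp[1]))
    bed_lines = []
    for chrom, pos in constrained_sorted:
        s, e = _safe_element(chrom, pos)
        bed_lines.append(f"{chrom}\t{s - 1}\t{e}")

    reg_types = ["promoter", "enhancer", "open_chromatin"]
    regulatory_sorted = sorted(planted["regulatory"], key=lambda cp: (int(cp[0]), cp[1]))
    reg_lines = []
    for chrom, pos in regulatory_sorted:
        s, e = _safe_element(chrom, pos)
        ftype = reg_types[int(rng.integers(len(reg_types)))]
        reg_lines.append(f"{chrom}\t{s - 1}\t{e}\t{ftype}")
    # decoy non-qualifying features on non-planted loci
    decoy_pool = [cp for cp in locus_positions if cp not in planted["regulatory"]]
    n_decoy = min(cfg.n_decoy_ctcf, len(decoy_pool))
    if n_decoy:
        for i in rng.choice(len(decoy_pool), size=n_decoy, replace=False):
            chrom, pos = decoy_pool[int(i)]
            s, e = _safe_element(chrom, pos)
            reg_lines.append(f"{chrom}\t{s - 1}\t{e}\tctcf_binding_site")

    # --- phenotype gene list and ortholog proteins ---------------------------
    cand_ids = sorted(truth.ortholog_target_genes)
    n_pheno = int(round(cfg.phenotype_fraction * len(cand_ids)))
    if n_pheno:
        pheno_idx = rng.choice(len(cand_ids), size=n_pheno, replace=False)
        truth.phenotype_genes = {cand_ids[int(i)] for i in pheno_idx}

    fasta_lines: List[str] = []
    for p in pairs:
        if p.target_gene_id not in truth.ortholog_target_genes:
            continue
        L = 80
        src_seq = "".join(_AA[int(i)] for i in rng.integers(len(_AA), size=L))
        n_mut = int(round((1.0 - (p.percent_identity or 80.0) / 100.0) * L))
        tgt = list(src_seq)
        if n_mut:
            for i in rng.choice(L, size=n_mut, replace=False):
                old = tgt[int(i)]
                tgt[int(i)] = _AA[(_AA.index(old) + 1) % len(_AA)]
        fasta_lines.append(f">{p.source_gene_id}\n{src_seq}")
        fasta_lines.append(f">{p.target_gene_id}\n{''.join(tgt)}")

    # --- serialize everything (only after all checks passed) -----------------
    files: Dict[str, str] = {}

    files["qtls.tsv"] = "\n".join(
        ["qtl_id\tspecies\ttrait_category\tchrom\tstart\tend\tpeak"]
        + [
            (
                f"{q.qtl_id}\t{q.species}\t{q.trait_category}\t{q.interval.chrom}"
                f"\t{q.interval.start}\t{q.interval.end}\t"
                if q.form == "interval"
                else f"{q.qtl_id}\t{q.species}\t{q.trait_category}\t{q.peak[0]}\t\t\t{q.peak[1]}"
            )
            for q in qtls
        ]
    ) + "\n"

    def _gene_table(genes: List[GeneRecord]) -> str:
        rows = ["gene_id\tsymbol\tspecies\tchrom\tstart\tend\tstrand\tbiotype"]
        for g in sorted(genes, key=lambda g: g.gene_id):
            iv = g.interval
            rows.append(
                f"{g.gene_id}\t{g.symbol}\t{g.species}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                f"\t{g.strand}\t{g.biotype}"
            )
        return "\n".join(rows) + "\n"

    files["source_genes.tsv"] = _gene_table(source_genes)
    files["target_genes.tsv"] = _gene_table(target_genes)
    files["orthologs.tsv"] = "\n".join(
        ["source_gene_id\ttarget_gene_id\tpct_identity\tpct_similarity"]
        + [
            f"{p.source_gene_id}\t{p.target_gene_id}\t{p.percent_identity:.2f}\t{p.percent_similarity:.2f}"
            for p in sorted(pairs, key=lambda p: p.source_gene_id)
        ]
    ) + "\n"
    files["manifest.csv"] = "\n".join(
        ["probe_name,chrom,position"]
        + [f"{p.probe_name},{p.chrom},{p.position}" for p in probes]
    ) + "\n"
    files["vep.tsv"] = "\n".join(vep_lines) + "\n"
    files["gerp.tsv"] = "\n".join(gerp_lines) + "\n"
    files["constrained.bed"] = ("\n".join(bed_lines) + "\n") if bed_lines else ""
    files["regulatory.bed"] = ("\n".join(reg_lines) + "\n") if reg_lines else ""
    files["genotypes.tsv"] = "\n".join(
        ["snp_id\tbreed\tallele1\tallele2"]
        + [f"{s}\t{b}\t{a1}\t{a2}" for s, b, a1, a2 in geno_rows]
    ) + "\n"
    files["genotypes.vcf"] = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        + [f"##contig=<ID={c},length={cfg.chrom_length}>" for c in chroms]
        + [f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cfg.breed_a}\t{cfg.breed_b}"]
        + [
            f"{c}\t{pos}\t{snp}\t{ref}\t{alt}\t.\t.\t.\tGT\t{ga}\t{gb}"
            for c, pos, snp, ref, alt, ga, gb in sorted(vcf_rows, key=lambda r: (int(r[0]), r[1]))
        ]
    ) + "\n"
    files["proteins.fasta"] = "\n".join(fasta_lines) + "\n" if fasta_lines else ""
    files["phenotype_genes.txt"] = "\n".join(sorted(truth.phenotype_genes)) + (
        "\n" if truth.phenotype_genes else ""
    )
    files["truth.json"] = truth.to_json() + "\n"

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name, content in files.items():
        path = out / name
        path.write_text(content)
        paths[name] = path

    checksums = {
        name: hashlib.sha256(content.encode()).hexdigest() for name, content in sorted(files.items())
    }
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "checksums": checksums,
    }
    (out / "scenario.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["scenario.json"] = out / "scenario.json"
    return paths, truth


def bundle_config(paths: Dict[str, Path], use_vcf: bool = False, **param_overrides) -> dict:
    """A resolved pipeline config dict for a generated bundle (see
    :func:`equiprio.pipeline.run_pipeline`)."""
    from .pipeline import DEFAULT_PARAMS

    params = dict(DEFAULT_PARAMS)
    params.update(param_overrides)
    return {
        "inputs": {
            "qtls": paths["qtls.tsv"],
            "source_genes": paths["source_genes.tsv"],
            "target_genes": paths["target_genes.tsv"],
            "orthologs": paths["orthologs.tsv"],
            "manifest": paths["manifest.csv"],
            "vep": paths["vep.tsv"],
            "gerp": paths["gerp.tsv"],
            "constrained_bed": paths["constrained.bed"],
            "regulatory_bed": paths["regulatory.bed"],
            "genotypes": paths["genotypes.vcf" if use_vcf else "genotypes.tsv"],
            "proteins_fasta": paths["proteins.fasta"],
            "phenotype_genes": paths["phenotype_genes.txt"],
        },
        "params": params,
    }
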