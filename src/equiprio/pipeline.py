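"""End-to-end orchestration: QTL/ortholog selection -> marker extraction ->
annotation -> prioritization -> breed-contrast validation, with bit-stable
report files.

A YAML config names the input files and the tunable parameters; every
parameter has the screen's default (flanks 5000 bp, GERP threshold 2.0,
similarity threshold 60 %, all four criteria enabled, breeds P / AM) so a
minimal config lists only the inputs.  Reports:

* ``priority_table.tsv`` — prioritized rows (the published-table shape);
* ``full_report.tsv``    — every annotated marker row, with its verdict;
* ``strong_candidates.tsv`` — prioritized SNPs whose breed genotypes differ;
* ``summary.json``       — counts and per-stage attrition.

Identical inputs produce byte-identical reports (rows sorted by
(chrom, position, probe_name); JSON keys sorted; no timestamps).  On any
stage error, partially written outputs are removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import annotation as ann
from . import io as eio
from . import markers as mk
from . import qtl as qs
from . import validate as vd
from .core import EquiprioError, InputError
from .prioritize import PriorityCall, prioritize as _prioritize, summarize as _summarize

log = logging.getLogger("equiprio")

REPORT_FILES = (
    "priority_table.tsv",
    "full_report.tsv",
    "strong_candidates.tsv",
    "summary.json",
)

DEFAULT_PARAMS = {
    "peak_flank": 5000,
    "gene_flank": 5000,
    "gerp_threshold": 2.0,
    "similarity_threshold": 60.0,
    "min_categories": 2,
    "criteria": ["protein_effect", "gerp_gt2", "constrained", "regulatory"],
    "breed_a": "P",
    "breed_b": "AM",
    "contrast_mode": "representative",
}


@dataclass
class PipelineResult:
    """In-memory mirror of the written reports."""

    calls: List[PriorityCall]
    summary: Dict
    strong: Dict[str, set]
    gates: Dict[str, vd.GateResult] = field(default_factory=dict)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "inputs" not in cfg:
        raise InputError("config must have an 'inputs' section")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params") or {})
    base = Path(path).parent
    inputs = {
        k: (base / v if not Path(v).is_absolute() else Path(v))
        for k, v in cfg["inputs"].items()
    }
    return {"inputs": inputs, "params": params}


def _chrom_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def _mask_flags(flags: ann.CriterionFlags, enabled: Sequence[str]) -> ann.CriterionFlags:
    return ann.CriterionFlags(
        protein_effect=flags.protein_effect and "protein_effect" in enabled,
        gerp_gt2=flags.gerp_gt2 and "gerp_gt2" in enabled,
        constrained=flags.constrained and "constrained" in enabled,
        regulatory=flags.regulatory and "regulatory" in enabled,
    )


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> PipelineResult:
    """Execute all stages and write the report files under ``out_dir``.

    ``config`` is a YAML path or an already-resolved config dict (as
    returned by :func:`load_config`).  Raises stage-labelled errors on
    malformed input; partial outputs are removed before re-raising.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception:
        for name in REPORT_FILES:
            (out / name).unlink(missing_ok=True)
        raise


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with a stage label."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, EquiprioError):
                raise EquiprioError(f"[{name}] {exc}") from exc
            if isinstance(exc, EquiprioError) and not str(exc).startswith("["):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _run(config, out: Path) -> PipelineResult:
    if not isinstance(config, dict):
        config = load_config(config)
    inputs: Dict[str, Path] = config["inputs"]
    p = config["params"]
    attrition: Dict[str, int] = {}

    # stage 1: QTL -> multi-category source genes -> target orthologs
    with _stage("qtl_ortholog"):
        qtls = eio.read_qtl_table(inputs["qtls"])
        source_genes = eio.read_gene_table(inputs["source_genes"])
        target_genes = eio.read_gene_table(inputs["target_genes"])
        pairs = eio.read_ortholog_table(inputs["orthologs"])
        cat_sets = qs.genes_in_qtls(qtls, source_genes, p["peak_flank"])
        multi = qs.genes_in_min_categories(cat_sets, p["min_categories"])
        candidates = qs.transfer_orthologs(multi, pairs, target_genes)
    attrition["n_qtls"] = len(qtls)
    attrition["n_source_genes"] = len(source_genes)
    attrition["n_multicategory_genes"] = len(multi)
    attrition["n_candidate_genes"] = len(candidates)
    if not qtls:
        log.warning("empty QTL input: reports will be empty")

    # stage 2: chip markers inside flanked candidate regions, dedup
    with _stage("marker"):
        manifest = eio.read_manifest(inputs["manifest"])
        loci = mk.extract_candidate_loci(manifest, candidates, p["gene_flank"])
    attrition["n_probes_on_chip"] = len(manifest)
    attrition["n_probes_in_regions"] = sum(l.n_probes for l in loci)
    attrition["n_loci"] = len(loci)

    # stage 3: evidence join + criterion flags
    with _stage("annotation"):
        vep = eio.read_vep_table(inputs["vep"])
        gerp = eio.read_gerp_table(inputs["gerp"])
        regulatory = eio.read_regulatory_bed(inputs["regulatory_bed"])
        constrained = eio.read_bed(inputs["constrained_bed"])
        index = ann.build_annotation_index(vep, gerp, regulatory)
        rows = ann.annotate(loci, index, constrained, p["gerp_threshold"])
        rows = [
            ann.AnnotatedMarker(
                probe_name=r.probe_name,
                snp_id=r.snp_id,
                gene_id=r.gene_id,
                chrom=r.chrom,
                position=r.position,
                consequence=r.consequence,
                flags=_mask_flags(r.flags, p["criteria"]),
            )
            for r in rows
        ]
    attrition["n_annotated_rows"] = len(rows)

    # stage 4: prioritization
    with _stage("prioritization"):
        phenotype_genes: set = set()
        if "phenotype_genes" in inputs:
            text = Path(inputs["phenotype_genes"]).read_text()
            phenotype_genes = {ln.strip() for ln in text.splitlines() if ln.strip()}
        calls = _prioritize(rows, phenotype_genes)
        summary = _summarize(calls)
    attrition["n_prioritized_rows"] = sum(c.prioritized for c in calls)

    # stage 5: validation (breed contrast + similarity gate)
    strong: Dict[str, set] = {"snp_ids": set(), "genes": set()}
    contrasts: List[vd.ContrastResult] = []
    gates: Dict[str, vd.GateResult] = {}
    with _stage("validation"):
        if "genotypes" in inputs:
            gpath = Path(inputs["genotypes"])
            if gpath.suffix == ".vcf":
                genotypes = eio.read_genotypes_vcf(gpath)
            else:
                genotypes = eio.read_genotypes_tsv(gpath)
            contrasts, strong = vd.contrast_breeds(
                calls, genotypes, p["breed_a"], p["breed_b"], p["contrast_mode"]
            )
        sequences = None
        if "proteins_fasta" in inputs:
            sequences = eio.read_protein_fasta(inputs["proteins_fasta"])
        strong_pairs = [
            q
            for q in pairs
            if q.target_gene_id in {c.gene_id for c in candidates}
        ]
        gates = vd.similarity_gate(strong_pairs, p["similarity_threshold"], sequences)
    attrition["n_strong_snps"] = len(strong["snp_ids"])
    attrition["n_strong_genes"] = len(strong["genes"])

    summary = dict(summary)
    summary["attrition"] = attrition
    log.info("stage attrition: %s", attrition)

    _write_reports(out, calls, contrasts, strong, summary)
    return PipelineResult(calls=calls, summary=summary, strong=strong, gates=gates)


def _calls_frame(calls: Sequence[PriorityCall]) -> pd.DataFrame:
    recs = [
        {
            "chrom": c.chrom,
            "position": c.position,
            "probe_name": c.probe_name,
            "snp_id": c.snp_id,
            "gene_symbol": c.gene_symbol,
            "consequence": c.consequence,
            "protein_effect": int(c.flags.protein_effect),
            "gerp_gt2": int(c.flags.gerp_gt2),
            "constrained": int(c.flags.constrained),
            "regulatory": int(c.flags.regulatory),
            "phenotype": int(c.phenotype_flag),
            "prioritized": int(c.prioritized),
        }
        for c in calls
    ]
    df = pd.DataFrame(
        recs,
        columns=[
            "chrom", "position", "probe_name", "snp_id", "gene_symbol",
            "consequence", "protein_effect", "gerp_gt2", "constrained",
            "regulatory", "phenotype", "prioritized",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["chrom", "position", "probe_name", "gene_symbol"],
            key=lambda s: s.map(lambda v: (0, int(v)) if str(v).isdigit() else (1, str(v)))
            if s.name == "chrom"
            else s,
        ).reset_index(drop=True)
    return df


def _write_reports(out, calls, contrasts, strong, summary) -> None:
    df = _calls_frame(calls)
    eio.write_tsv(out / "full_report.tsv", df)
    eio.write_tsv(out / "priority_table.tsv", df[df["prioritized"] == 1].drop(columns=["prioritized"]))

    strong_rows = [
        {
            "snp_id": r.snp_id,
            "genotype_a": "|".join(r.genotype_a) if r.genotype_a else ".",
            "genotype_b": "|".join(r.genotype_b) if r.genotype_b else ".",
            "differs": int(r.differs),
            "evaluable": int(r.evaluable),
        }
        for r in contrasts
    ]
    sdf = pd.DataFrame(
        strong_rows, columns=["snp_id", "genotype_a", "genotype_b", "differs", "evaluable"]
    )
    eio.write_tsv(out / "strong_candidates.tsv", sdf)

    payload = dict(summary)
    payload["strong_snp_ids"] = sorted(strong["snp_ids"])
    payload["strong_genes"] = sorted(strong["genes"])
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
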