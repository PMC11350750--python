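# equiprio

Prioritization of SNP-array markers for a data-poor species by transferring
trait knowledge from a data-rich one.

## The problem

Equine production traits (body size, body weight, meat yield) have almost no
QTL or marker-association records, while cattle have thousands. `equiprio`
implements the comparative screen that bridges the gap for the markers on a
commercial genotyping array (the GGP Equine chip, >70,000 SNPs):

1. **QTL → gene selection (source species).** Trait QTLs are grouped into
   categories; QTLs reported only as peaks are widened by ±5,000 bp. Genes
   overlapping QTLs of ≥ 2 categories survive (the multi-category rule).
2. **Ortholog transfer.** Surviving cattle genes are mapped to their horse
   orthologs through a precomputed ortholog table; genes without an
   ortholog drop out.
3. **Marker extraction.** Each candidate gene interval is extended by
   ±5,000 bp to capture proximal regulatory variants, array probes inside
   the extended intervals are collected (a probe between two overlapping
   genes is attributed to both), and probes assaying the same genomic
   position are collapsed to one locus.
4. **Four-criteria prioritization.** A marker is prioritized when **any** of
   the following holds for its SNP:
   - a predicted protein-altering consequence on *any* overlapping
     transcript (missense, stop gained/lost, start lost, frameshift,
     in-frame indel, splice acceptor/donor/donor-region);
   - GERP rejected-substitutions score **> 2** (strict; a missing score
     never qualifies);
   - position inside a constrained element (closed-interval overlap);
   - overlap with an orthologous regulatory feature of type promoter,
     enhancer or open chromatin.
5. **Validation.** Prioritized SNPs are contrasted between a very large
   breed (Percheron, `P`) and a very small one (American Miniature, `AM`):
   any genotype difference (allele multisets unequal, so het vs. hom
   counts) makes a *strong candidate*. Ortholog protein similarity ≥ 60 %
   (from the ortholog table, or computed as global-alignment percent
   identity) backs the cross-species transfer.

All coordinates are 1-based inclusive (Ensembl convention); BED inputs are
converted on read. Everything external — QTL exports, gene tables, the
chip manifest, VEP-style consequences, GERP scores, constrained/regulatory
BED tracks, breed genotypes (VCF or TSV), protein FASTA — is a file input:
the package performs no live database queries.

## Worked example

A packaged fixture transcribes the published 28-row priority table with its
raw evidence, the seven duplicate-probe groups, and the breed genotype
table:

```python
import equiprio as e

b = e.fixtures.published_bundle()
rows = e.annotate(b["loci"], b["annotations"], b["constrained"])
calls = e.prioritize(rows, b["phenotype_genes"])
print(e.summarize(calls))
# {'n_markers': 27, 'n_genes': 22, 'n_protein': 8, 'n_gerp': 8,
#  'n_constrained': 6, 'n_regulatory': 12, 'n_phenotype_genes': 8}

_, strong = e.contrast_breeds(calls, b["genotypes"], "P", "AM")
print(len(strong["snp_ids"]), len(strong["genes"]))   # 10 10

print(len(e.deduplicate_probes(b["appendix_probes"])))  # 268
```

28 table rows collapse to **27** unique marker–SNP pairs in **22** genes
(one intronic SNP sits inside two overlapping genes, *C18H2orf88* and
*MSTN*); **8** genes carry a screened mammalian-phenotype link; the breed
contrast leaves **10** strong candidate SNPs in **10** genes; and the
278-probe manifest dedups to **268** unique positions. (`n_constrained`
is 6 because the shared two-gene SNP counts once per marker–SNP pair.)

The same pipeline runs end-to-end from files via the CLI. On a synthetic
bundle with planted truth:

```console
$ prio simulate --seed 1 -o bundle
wrote bundle to bundle/ (65 candidate loci, 27 planted prioritized SNPs)
$ prio run -c config.yaml -o out
prioritized 29 marker-SNP pairs in 19 genes; 10 strong candidates in 9 genes -> out/
```

(29 pairs for 27 SNPs: two planted loci are assayed by duplicate probes,
and pairs are counted per probe.) `out/` contains `priority_table.tsv`,
`full_report.tsv`, `strong_candidates.tsv` and `summary.json`; reruns are
byte-identical. A config lists the input files under `inputs:` and may
override any parameter under `params:` (flank sizes, GERP threshold,
similarity threshold, enabled criteria, breed labels).

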