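# Methods

## Model and assumptions

The screen is a deterministic rule cascade, not a statistical model: every
stage is a set operation over genomic intervals and annotation tables, so
identical inputs always give identical outputs. Its scientific assumptions
are:

* **Synteny-free transfer.** Candidate genes move between species through
  an explicit ortholog table; no liftover or whole-genome alignment is
  performed, and orthologous regulatory/constrained annotations are
  consumed as precomputed per-position tables.
* **Closed 1-based intervals.** A point overlaps `[s, e]` iff
  `s ≤ p ≤ e`; two intervals overlap iff they share ≥ 1 bp. BED inputs
  (0-based half-open) are converted on read. A shared endpoint counts as
  overlap; ≥ 1 bp of gene–QTL overlap suffices (no minimum-fraction rule).
* **Strand-agnostic flanks.** The ±flank extension is symmetric in
  coordinate orientation regardless of gene strand; "upstream and
  downstream" is implemented as both sides of the coordinate span. The
  left end clamps at position 1; no right clamp is applied because
  chromosome lengths are not required inputs.
* **Union prioritization.** The verdict is a flat OR of the four criteria;
  no criterion dominates and survivors are not ranked.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `peak_flank` | 5000 | bp | window around peak-only QTLs, sized to catch proximal regulatory elements |
| `gene_flank` | 5000 | bp | candidate-gene extension, same rationale |
| `min_categories` (k) | 2 | categories | the multi-category rule; exposed because other screens may want k = 1 or 3 |
| `gerp_threshold` | 2.0 | rejected substitutions | strict `>`; missing score is distinct from 0 and never passes |
| `similarity_threshold` | 60 | % | inclusive `≥`; proteins above it are assumed functionally equivalent |
| `criteria` | all four | — | any subset can be enabled for sensitivity analyses |
| breeds | `P` / `AM` | — | the large-vs-small contrast pair; any two sample labels work |

Design choices where the convention was genuinely open:

* **Dedup key** is `(chrom, position)` only — alleles and probe chemistry
  are ignored, matching position-based duplicate reporting on the chip.
* **Marker identity** downstream is the `(probe_name, snp_id)` pair, not
  the probe name alone: one probe name can legitimately serve two SNPs,
  and one SNP inside two overlapping genes yields two report rows that
  count as one marker. Gene counts use distinct symbols, lncRNA ids
  included.
* **Protein-effect scan covers all transcripts**, not only the canonical
  one: a variant that is missense on the canonical transcript and 5′ UTR
  on another must flag, and so must one that is protein-altering only on a
  non-canonical transcript.
* **Qualifying regulatory types** are promoter, enhancer and open
  chromatin; CTCF-only and TF-binding-only features never flag.
* **One-to-many orthologs are all retained** (conservative for a candidate
  screen) and logged; sources without a target ortholog are dropped and
  logged.
* **"Genotypes differ"** means unequal unordered allele multisets — a
  heterozygote against a homozygote differs. A multi-sample variant of the
  rule (per-breed allele sets must be disjoint) is provided
  (`contrast_mode: allele_sets`) but off by default, since the default
  emulates one representative sample per breed.
* **Percent identity** of an ortholog pair, when computed from sequences
  rather than read from the table, is defined over global
  Needleman–Wunsch alignments at match +1 / mismatch 0 / linear gap −1:
  among all optimal-score alignments, take the one with the most matched
  columns (ties → fewest columns) and report `100·matches/columns`, gap
  columns included in the denominator. The tie-break makes the statistic
  deterministic; the scheme is the simplest one that reproduces the
  obvious reference cases, and database-derived similarities can always be
  supplied through the ortholog table instead.

## Numerical and degenerate-input behaviour

* Empty QTL input produces empty (header-only) reports with a warning, not
  an error. Loci with no annotation record get all-false flags and a log
  line. Two annotation records claiming one position under different SNP
  ids raise an error naming the conflict.
* Unknown consequence terms warn and are treated as non-protein-affecting.
* Reports are sorted by (chrom numeric-aware, position, probe name) and
  JSON keys are sorted, so reruns on identical inputs are byte-identical.
  On any stage failure the partially written reports are deleted.

## What the synthetic generator emulates — and what it does not

`equiprio.simulate.generate_scenario` writes a complete input bundle (QTL
TSV, both gene tables, ortholog TSV, manifest CSV, VEP-style TSV, GERP
TSV, constrained BED, typed regulatory BED, genotypes as both TSV and VCF,
protein FASTA, phenotype gene list) plus a truth file and a checksummed
scenario manifest. Defaults mirror the real screen's stated conditions:
3 trait categories and ~19 QTLs; 30 multi-category source genes placed in
one syntenic block that QTLs of two categories tile (the screen's source
data concentrate multi-category genes in one chromosome block); ortholog
coverage 0.73 (30 → 22 attrition); chip density 30 probes/Mb (the real
array's ~70k probes over ~2.5 Gb); a 4 % duplicate-probe fraction;
per-criterion planted counts {protein 8, conservation 8, constrained 7,
regulatory 12} equal to the published table tallies; and 10
breed-divergent prioritized SNPs. The genome itself is scaled down to
3 × 20 Mb chromosomes, which keeps a full scenario generation + pipeline
run around 0.2 s without changing any rule being tested.

Construction guarantees that planted markers satisfy exactly their
assigned criteria and all other markers satisfy none: conserved sites draw
GERP from U(2.5, 5) and neutral sites from U(−2, 1.5), so the > 2
threshold is never ambiguous under floating point; constrained and
regulatory elements are shrunk so they contain no other assayed position;
a few decoy CTCF features exercise the non-qualifying-type rule. Planted
breed-divergent SNPs are opposite homozygotes by default; a config switch
(`het_divergent`) adds het-vs-hom divergent cases. Geometric truth
(multi-category genes, ortholog targets, candidate loci) is re-derived by
brute-force scans of the emitted tables before writing, so the truth file
is consistent with the files by construction even when random placement
creates extra multi-category genes.

Not emulated: linkage disequilibrium, realistic allele-frequency spectra,
real chromosome lengths, assembly gaps, or annotation noise (every chip
position has exactly one VEP record). Passing the recovery tests therefore
shows the rule cascade is implemented correctly, not that the screen is
robust to noisy or conflicting real-world annotation — on real data the
all-false-flag fallback and the conflict error are the relevant behaviours,
and they are tested separately.

## Packaged reference fixture

The packaged fixture transcribes the published 28-row priority table, the
seven duplicate-probe groups (16 probes at 7 positions), and the breed
genotype contrast. Evidence values printed in the study (GERP scores,
regulatory feature types, five genomic positions) are used verbatim;
unprinted positions and sub-threshold GERP filler are synthetic and marked
as such in `equiprio/fixtures.py`. Two transcription choices follow the
table over the prose where they conflict: the shared two-gene SNP carries
no conservation checkmark (so its fixture GERP is sub-threshold even
though the prose elsewhere quotes a high score), and the bold
breed-differs set is taken from the table alone. The 278-probe appendix
manifest is reconstructed programmatically: its printed duplicate groups
account for 9 of the 10 surplus probes, so one additional synthetic
duplicate is included to honour the published 278 → 268 arithmetic.

## Problem sizes

The default test suite runs ~160 tests in about 15 s: the fixture checks
are instantaneous, property tests use hypothesis with bounded example
counts, and the 20-scenario recovery sweep uses the scaled-down genome
described above. `scripts/acceptance.py` (fixture quantities + a
20-scenario recovery sweep) completes in a few seconds.

## Known limitations

* No weighting or ranking among prioritized markers; the rule is binary.
* No population-genetic statistics (F_ST, allele-frequency tests); the
  breed contrast is a two-sample genotype comparison.
* Cross-species coordinate mapping is out of scope; orthologous
  regulatory/constrained annotations must be precomputed by the caller.
* The VCF genotype reader assumes one sample column per breed label.
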