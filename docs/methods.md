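# Methods

## Dialect harmonization

Each caller's VCF conventions are declared in a dialect table
(`callers.DIALECTS`), not hard-coded per call site: where the somatic
verdict lives (FILTER column for MuSE, Mutect2, SomaticSniper and
Strelka2; a somatic-status field for VarScan2, set `Somatic`; INFO
`STATUS` for VarDict, set `StrongSomatic`), which FORMAT tags carry
allele counts (AD; SB; DP4; Strelka's per-base AU/CU/GU/TU tier counts
and TAR/TIR for indels; VarDict's AD with RD/ALD strand splits), and
how tumor/normal genotype columns are recognized (sample-name regex,
overridable — dialects disagree on column order, and the Mutect2
dialect lists the normal first). Strelka2 counts use tier-1 tags; the
tier-2 alternative is not exposed because tier-1 is the caller's own
high-confidence tier.

Chromosome names are normalized to the `chr`-prefixed convention at
parse time so merge keys compare across dialects. Multi-alt lines are
split into per-alt canonical variants before filtering, with the
multiallelic flag taken from the pre-split record. Alleles are reduced
to minimal representation by shared suffix/prefix trimming only; full
indel left-alignment is deliberately not performed, because the merge
key is positional and caller-side normalization differences are
absorbed by it.

## Filter flags

Flags annotate; they never mutate or delete records. Partitioning into
PASS/flagged is a separate step, which is what makes per-caller,
per-flag accounting reports possible.

| flag | rule | default |
| --- | --- | --- |
| CommonSNP | population AF strictly greater than `common_af_max` | 0.01 |
| PoN | site (chrom, pos, alt) in the panel of normals | ≥2 reads in ≥2 normals |
| OxoG | C>A / G>T SNV with ≥ `oxog_min_alt` (3) alt reads and the artifact-consistent orientation carrying ≥ `oxog_orientation_fraction` | 0.9 |
| StrandBias | two-sided exact test on the ref/alt × fwd/rev 2×2 table | p < 0.005 |
| MultiallelicSite | source record carried ≥ 2 alt alleles | — |
| ClusteredEvents | ≥ `cluster_min_events` same-sample variants within any `cluster_window_bp` span | 3 in 50 bp |
| TAltLow | tumor alt reads < `t_alt_min` | 4 |
| NAltHigh | normal alt reads ≥ `n_alt_max` | 4 |

The CommonSNP bound is strictly greater than 1%, following the plain
reading of "AF > 1%". The PoN thresholds follow the conventional
"seen in at least two normals" rule; the upstream panel-building tools
do not document a fixed threshold, so both knobs are configurable. OxoG
detection is an orientation-bias approximation over stranded alt
counts: read-pair orientation (F1R2/F2R1) is not available in all
dialects, so the convention used is that C>A artifacts skew toward the
forward strand and G>T toward the reverse. MuSE and Strelka2 carry no
strand fields at all; for their records OxoG and StrandBias are
recorded *not evaluable* rather than silently passing. The strand-bias
significance level (0.005) and the clustered-events window (3 events
in 50 bp) are conventional choices; both are configurable.

## Merge, consensus and MNV reconstruction

The merge key is `(sample_id, chrom, pos)` — without alleles. Allele or
class disagreement between callers at one key is annotated
(`alt_discordant`, `class_discordant`) and a representative allele is
chosen by fixed caller priority (Mutect2 > Strelka2 > VarDict > MuSE >
SomaticSniper > VarScan2), so ties break deterministically. Consensus
retains keys hit by at least `min_callers` (default 2, configurable to
6 for agreement-tier accounting).

Only Mutect2 and VarDict emit dinucleotide substitutions as one 2-bp
MNV; the other four report two adjacent SNVs. Reconstruction runs after
merging and before the consensus filter: when an MNV-capable caller
reports `pos..pos+1`, other callers' SNVs at those positions whose alts
match the per-base substitution are folded into the MNV record, each
folding caller counted once. A conflicting alt leaves that caller
unfolded and logs the conflict. Folding never changes the set of
distinct mutated base positions. Tri-nucleotide and longer MNVs are out
of scope (logged, not folded).

## Automated review and blacklisting

The four review criteria on pileup evidence: (1) tumor alt ≥ 3 and
normal alt < 3; (2) at least one alt read on each strand; (3) at most 3
other mismatch positions within the 40-bp window centered on the site
(±20 bp; a mismatch is a non-ref, non-call column with more than one
supporting read); (4) allelic configuration. Criterion 4 as published
is ambiguous — it is listed among true-positive criteria yet reads as
requiring a multiallelic configuration, which the rest of the filtering
treats as an artifact. The default here is that exactly one distinct
alt allele passes; `ReviewConfig.multiallelic_passes` selects the
literal inverted reading.

Review is driven by gene recurrence: genes mutated in ≥ 7 of the cohort
(14% at n=50) are reviewed, per-gene failure rates computed, and genes
with rate ≥ 0.9 over ≥ 50 reviewed calls are blacklisted and removed.
Review consumes a pileup-evidence table; extracting that table from
alignments is an adapter concern, which keeps the classifier testable
without BAMs.

## Burden

TMB = non-synonymous mutations / merged target megabases. All
consequence classes except synonymous and stop-retained count as
non-synonymous — the class list (including dinucleotide and splice
site) follows the plain meaning of "non-synonymous"; membership is
configurable. Consequence classes are consumed from a VEP-style
annotation table through a declared term map; annotation itself is out
of scope. Median splits send ties to the low group. Because the
published per-patient burden figure does not pin down whether all
retained or only non-synonymous mutations entered it, the TMB table
reports both (`tmb` and `tmb_all`).

## Thresholds

ROC curves sweep the distinct observed scores with the fixed decision
rule "score ≥ threshold predicts review-pass"; ties collapse to one
step and AUC is the trapezoidal integral (equal to the Mann–Whitney
pair statistic). Because the direction is fixed, a discriminator that
runs backwards — read depth, when false positives concentrate at
kilobase depth — shows AUC < 0.5 rather than being silently flipped.
The 95% CI uses the Hanley–McNeil standard error. The operating point
maximizes Youden's J with ties resolved toward the smaller threshold,
and reported FPR/FNR use ≥ at the threshold.

## Statistics

Mann–Whitney U is exact (full null enumeration) for tie-free inputs
with `n_a·n_b ≤ 400`, otherwise the normal approximation with tie
correction. Contingency tables use Fisher's exact test for 2×2 tables
with any expected cell ≤ 5 and chi-square without continuity correction
otherwise; the choice is recorded in the output. Survival uses
Kaplan–Meier product-limit curves and the two-group log-rank test with
the standard hypergeometric variance at tied event times. Raw p-values
are reported, matching common practice for cohort descriptions;
Benjamini–Hochberg adjustment is available (`bh_adjust`).

## Synthetic cohort

The generator emulates a 50-tumor/normal-pair exome study on a
two-chromosome ~5 Mb mini-genome with a declared gene map: 17 driver
genes planted at realistic per-patient mutation frequencies (0.08–0.62),
two mucin-like FP-enriched genes, a titin-like large gene and 20 filler
genes. Defaults per patient: ~40 background SNVs (patient rate
log-normal, σ=0.45, giving cohort burden heterogeneity), ~6 indels,
exactly 3 dinucleotides, ~5 off-target somatics; artifact intensities of
~8 germline leaks (from a 30-site shared pool, alt-supported in 40–90%
of normals), ~3 common-SNP calls, ~5 oxoG, ~4 strand-bias, 2 clustered
bursts, ~3 multiallelic lines, ~10 repeat-locus FPs per blacklist gene
at 1000–1600× depth with dirty windows, and caller-private FPs weighted
toward Mutect2/SomaticSniper (mirroring their high non-PASS rates).
Caller sensitivities spread widely (0.25–0.90), reflecting the
near-order-of-magnitude call-count disagreement seen between real
callers; detection is Bernoulli per caller, so single-caller-only
detections — and therefore the recall gap between the caller union and
the ≥2 consensus — genuinely occur.

Two detection rules are deterministic by design: dinucleotides are
clonal, high-support events emitted by all six callers (as one MNV by
Mutect2/VarDict, as two SNVs by the rest), so planted-count recovery
after reconstruction is exact; and true somatic evidence is clean by
construction (balanced strands, ample tumor support, quiet normals,
≥200 bp spacing), so filter flags remove only planted artifacts.
Survival is exponential with a hazard ratio of 3.0 on the high-burden
half (base hazard 0.015/month, uniform 24–72-month censoring — chosen
to give roughly 60–70% event rates and ~90% log-rank power at n=50,
i.e. an effect of the same just-significant order the emulated study
reports); stage and age are shifted for the high-burden group.

What the generator does **not** emulate: read-level sequencing error,
mapping ambiguity, subclonal allele-fraction structure, caller-specific
systematic biases beyond marginal sensitivity/FP rates, and inter-gene
mutation-rate covariation. Passing tests therefore demonstrate the
pipeline's bookkeeping, rules and statistics are correct — not that the
specific thresholds are optimal on real sequencing data.

All randomness flows from one seeded generator; a fixed configuration
reproduces byte-identical output directories, and the pipeline itself
is deterministic given its inputs (re-runs are byte-identical).

## Problem sizes

The bundled tests run the generator at 4–10 patients for unit and
integration checks and at the full 50-patient design for parameter
recovery; the log-rank power calibration uses 200 survival-only
replicates at n=50. `scripts/acceptance.py` simulates one 50-patient
cohort per invocation.

## Known limitations

- The merge key ignores alleles, so SNVs and indels colliding at a
  position form one record (annotated, per the positional-key design).
- OxoG detection is strand-based, not read-pair-orientation-based.
- Only 2-bp MNVs are reconstructed.
- BAM/pileup extraction is not included; review consumes the
  pileup-evidence table schema.
- The published AUC values for DP/MAF derive from the original study's
  alignments and are not reproducible here; the package reproduces the
  analysis machinery and the direction of both discriminators.
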