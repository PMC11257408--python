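# Methods

## Scope and model

`editscan` implements the computational core of a replicated
RNA-editing study: given per-site base-count pileups for a control
condition and one or more depletion (knockdown) conditions, each in at
least duplicate, it identifies cytidines whose apparent C-to-U editing
is both statistically above the sequencing-error floor and concordantly
reduced when the candidate editing enzyme is depleted. Around this core
sit the motif, enrichment and screen statistics that such a study uses
to interpret its hits.

## Variant calling

At a reference C with depth *D* and U-count *k*, the caller computes
the one-sided exact binomial tail P(X ≥ *k*) with
X ~ Binomial(*D*, *e*/3), where *e* is the total per-base substitution
rate (default 1e-3) split uniformly over the three non-reference bases.
A call requires *D* strictly greater than `min_depth` (default 10, so
≥ 11 reads) and *p* < α (default 0.05).

Choices and their reasons:

- **Uniform error split.** The simplest null consistent with the
  count-only pileup dialect; the per-alt rate *e*/3 is configurable.
- **No base-quality weighting.** Qualities are absent from the pileup
  dialect; the caller is a declared simplification of quality-aware
  low-frequency callers, not a reconstruction of one.
- **One-sided upper tail.** Only an excess of alternate reads is
  evidence of editing.
- **No per-stage multiple-testing correction.** Replicate concordance
  downstream is the de facto error control; the per-replicate called
  fraction under the null is verified to stay below α.
- **Strand handling.** In strand-aware mode G>A events are also tested;
  `orient_strand` relabels minus-strand G>A as canonical C>U, drops
  orientation-inconsistent calls with a reason, and routes
  unknown-strand calls to an "unoriented" bucket rather than silently
  discarding them.

## Concordance filtering and tiers

`intersect_replicates` keeps sites called in **every** replicate of
**every** condition. Two decrease rules are provided because replicated
editing studies use both, on different transcript classes:

- `all_replicates_decrease`: every knockdown-replicate frequency lies
  below the control mean (per-replicate rule, used for small
  high-coverage site sets such as the pre-rRNA);
- `mean_decrease`: each knockdown condition's mean lies below the
  control mean (the transcriptome-wide rule).

Percent difference is 100·(f̄c − f̄kd)/f̄c with f̄kd the unweighted
mean over knockdown-condition means; tiers use strict inequalities
(> 33, > 66). Region annotation resolves overlaps by the fixed
precedence UTR > coding exon > non-coding exon > intron > intergenic.

Detection in a replicate means a significant call there, not mere
presence of alternate reads; this is the stricter reading and is what
the recovery simulations assume.

## Motif statistics

Windowed UC density uses consecutive non-overlapping windows (default
100 nt); an occurrence belongs to the window containing its start, so
window counts sum exactly to the full-sequence count. The analytic
expectation uses the **window-length convention** L·ΠP(base) — 6.25
per 100 nt for equiprobable bases — rather than (L−1)·p; the final
partial window is reported at its true length with a pro-rated
expectation. Edit contexts are ±10 nt, end-padded with `-`, aggregated
into a position-frequency matrix whose centre column is all C. The
preceding-base test is an exact binomial against p₀ = 0.25, two-sided
by doubling the smaller tail (capped at 1).

## Enrichment

Fisher's exact test (two-sided) on the 2×2 table, with fold
(k/n)/(K/N) and the set's baseline percent 100·K/N. The reporting
filter is strict fold > 2 with p < α. The ORA universe defaults to the
genes annotated in the run and is configurable, since published
baselines mix universes (a 19,670-protein proteome; 43,768 approved
genes). Benjamini–Hochberg adjustment is available but off by default,
matching the uncorrected reporting convention the filter mirrors.

## Screen statistics

- **Percent effect** is computed per replicate and then averaged, which
  matches the mean ± SD error structure of triplicate screens; pooled
  computation is possible by passing pooled summaries directly.
- **Hit calling** uses the SD of negative-control *well* effects within
  each replicate (whether the original rule used well-level or
  replicate-level SD is unstated; well-level is chosen and recorded
  here). The overall decision compares the mean effect across
  replicates with the mean of per-replicate 3-SD thresholds, inclusive
  (≥); with identical negative wells (SD = 0) any positive effect is a
  hit. Per-replicate pass flags are returned for inspection.
- **Percent inhibition** classes: > 80 transcription, 50–80 inclusive
  processing/maturation, < 50 not required.
- **DNA-content normalisation** finds the control G1 peak as the global
  mode of a Gaussian-kernel-smoothed histogram of log2 intensities
  (bandwidth 0.05 log2 units, configurable) and the G2 peak as the
  strongest mode within 1 ± 0.3 log2 units above it, then maps the two
  affinely to 1.0 and 2.0. Fewer than two modes raises an error naming
  the histogram. Cell-cycle bins are half-open and left-closed
  (sub-G1 < 0.75; G1 [0.75, 1.25); S [1.25, 1.75); G2/M [1.75, 2.5];
  >4n > 2.5) so each nucleus lands in exactly one phase; where printed
  interval sets overlap at a boundary (1.25/1.26 in some renderings of
  the same assay), the procedural definition with the 1.25 boundary is
  used.
- **RAMP** reports, for each precursor→product edge of a declared
  pathway (default 47S→45S→32S→12S, the ITS2-probe-visible LSU route),
  log2[(d_t/u_t)/(d_c/u_c)]. Zero or missing intensities raise an error
  listing the species; the statistic is antisymmetric under exchanging
  test and control.

## Synthetic data

The generator reproduces the structure the statistics assume, not raw
reads: no FASTQ simulation, alignment, quality modelling or PCR
duplicates.

- **Study conditions.** Defaults are one control plus two knockdown
  conditions in duplicate; planted control frequencies uniform on
  0.34–23.39% (the observed span at depletion-sensitive pre-rRNA
  sites); knockdown frequencies f·(1 − reduction) with reduction 0.5 by
  default; error floor 1e-3; screen controls at 19.2% (negative) and
  29.2% (positive) one-nucleolus fractions, the printed control values
  of the assay emulated.
- **Read sampling.** Per site, counts are one multinomial draw of size
  `depth`: a read reports U with probability f·(1−e) + (1−f)·e/3, each
  other non-reference base at e/3, remainder the reference base. Counts
  therefore always sum to depth, and the observed alternate fraction
  converges to f plus the error contribution.
- **Seed hierarchy.** Sub-generators derive from the master seed plus a
  purpose tag and (sample, replicate) indices via `SeedSequence` spawn
  keys: identical seeds give bit-identical studies, replicates are
  mutually independent.
- **Annotations.** Non-overlapping multi-exon transcripts packed along
  the reference with coding flags and terminal UTRs; gene-set
  membership Bernoulli at a configurable baseline (0.177 for the
  synthetic nucleolar set).
- **DNA intensities.** G1 at 2^x0, G2/M one log2 unit above, S uniform
  between 1.30 and 1.70 normalised units (kept inside the S bin so the
  planted fractions are recoverable), sub-G1 and >4n outside the
  diploid–tetraploid span, log-normal noise with CV 0.05 by default.
- **Spacing.** Planted sites are ≥ 2 nt apart so per-site truths and
  motif contexts do not interact.

What passing tests on these data do **not** show: robustness to
alignment artefacts, strand bias, position-dependent error profiles,
non-uniform coverage, isoform ambiguity or cell-segmentation noise —
none of which the generator emulates.

## Problem sizes and determinism

Simulation-based tests use references of 3–10 kb, depths 200–1000 (10⁴
for calibration checks), 10⁴ cells for cell-cycle round trips and 10⁴
sites for null calibration — sizes at which the binomial confidence
intervals behind each tolerance are meaningful while the whole suite
runs in well under a minute of compute. All stochastic tests run on
fixed seeds; property tests are derandomised.

## Known limitations

- The caller's error model is a single global rate; real error floors
  vary by position, context and cycle.
- Frequencies at extremely low depth are coarse (f·D is integral), so
  percent differences near tier boundaries are depth-sensitive.
- The KDE peak finder assumes the G1 mode dominates the control
  histogram; heavily perturbed controls (e.g. strong G2 arrest) would
  need an explicit G1 prior.
- Region annotation uses the first containing transcript; overlapping
  genes on opposite strands are resolved by input order, not expression.
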