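# Methods

`mirfsh` re-implements, as a tested pipeline, the computational chain of a
GnRH-stimulation study in primary porcine anterior pituitary cells: from a
dual-channel miRNA microarray to differentially expressed miRNAs, qPCR
validation, FSH hormone-response statistics, seed/energy-based prediction of
miRNA sites in 3'-UTRs (FSHβ in particular), genomic mapping of precursor
hairpins, and KEGG-style pathway over-representation. Because the original
study deposited no raw data, a synthetic-data generator supplies every input
with planted ground truth, so each stage can be verified against what was
planted.

## Two-color array normalization and differential calling

A probe enters analysis when both channel intensities (Hy3 = treatment,
Hy5 = control) are positive and the signal-to-noise gate passes: both
SNR > 1, or at least one channel SNR > 2. Retention reasons are logged per
probe.

Normalization is MA-based. With M = log2(Hy3/Hy5) and
A = (log2 Hy3 + log2 Hy5)/2, an intensity-dependent dye bias f(A) is
estimated by robust locally weighted linear regression of M on A and
subtracted: M_norm = M − f̂(A). The smoother uses, per evaluation point, the
k = round(span·n) nearest neighbors in A (contiguous after sorting), tricube
distance weights (1 − u³)³ with u = |A − A_i|/max-window-distance, a local
*linear* weighted least-squares fit, and bisquare robustness reweighting
(1 − (e/6s)²)² with s the median absolute residual, for `iterations`
refits after the initial pass.

Numerical choices:

- **Degenerate robustness branch.** When s is numerically zero (a noise-free
  majority trend), the bisquare weights are replaced by an indicator that
  keeps only points with ~zero residual (falling back to uniform weights if
  fewer than two remain). Outlying probes — i.e. genuinely differential
  ones — are then excluded from the trend fit exactly, so a noise-free
  linear bias is removed perfectly and planted log-ratios are recovered to
  floating-point accuracy. With noise the branch never triggers and the
  estimator is the ordinary robust LOWESS.
- Defaults: span 0.4, 3 robustness iterations, minimum 10 probes. The
  vendor pipeline's settings are not published; these are conventional
  two-color values and fully configurable.
- Local-linear fits degrade to the weighted mean when the weighted x-spread
  underflows (ties in A).

The design is a single slide (both groups pooled from six animals), so
differential calling is fold-change-only: per miRNA, fold = 2^mean(M_norm)
over its probes, up-regulated at fold ≥ 1.3 and down-regulated at
fold ≤ 0.77. Both cut-offs are inclusive; the published boundary values
(1.35 minimum up, 0.76 maximum down) are interior either way. The down
threshold is 0.77 as stated in the source protocol, not 1/1.3 = 0.769…
No per-probe p-values exist at this stage by design.

Families group the called miRNAs by their identical 7-mer seed string; the
seed itself is the family identifier (published family labels, which come
from an external registry, are carried through as annotation when supplied).

## qPCR relative quantification

The Livak 2^−ΔΔCt procedure with amplification efficiency fixed at 2:
replicate Ct values are arithmetically averaged per gene and group,
ΔCt = Ct(target) − Ct(reference) within each group (U6 for miRNAs, β-actin
for the FSHβ mRNA), ΔΔCt = ΔCt(treatment) − ΔCt(control), RQ = 2^−ΔΔCt.
Significance is a two-sided pooled-variance t-test on per-replicate ΔCt
values (replicate i target minus replicate i reference) at α = 0.05; with a
single replicate the RQ is reported without a p-value.

Array/qPCR concordance is the Pearson correlation between log2 array fold
change and log2 RQ over shared miRNAs (log2 so up- and down-regulation are
symmetric; requires ≥ 3 shared miRNAs), plus per-miRNA direction agreement
split into significant-concordant, discordant and non-significant.

## Hormone statistics

FSH concentrations are calibrated to mIU per mg total protein. Group
contrasts against a named baseline report the fold ratio
mean(group)/mean(baseline) and the percent change
100·(mean(group) − mean(baseline))/mean(baseline), both at one decimal in
the reporting columns with full precision retained. This single orientation
reproduces the published one-decimal values from the published group means:
1.4-fold (3 h), 1.8-fold (6 h), −14.1 % (mimic vs its duplex control),
+15.1 % (inhibitor vs its control). Two-group designs use a pooled-variance
Student's t-test (Welch by flag); multi-group designs use one-way ANOVA with
Tukey HSD pairwise p-values. All-constant groups yield a NaN p-value with a
degeneracy flag rather than a fabricated number.

## Target prediction

A candidate site is a UTR window whose antiparallel pairing with the miRNA
seed consists only of Watson–Crick pairs, with up to `max_gu` G:U wobbles
(default 1; setting `max_gu` to the seed length reproduces the unlimited
reading). The seed window default is mature positions 2–8: the protocol
text says bases 2–7, but every published seed is a 7-mer equal to positions
2–8, so 2–8 is the default and 2–7 remains available by configuration.

Candidates are scored with an intermolecular-only duplex model (no
intramolecular structure): nearest-neighbor stacking energies for adjacent
pairs, an affine penalty (3.0 + 0.5/nt kcal/mol) for bulges and internal
loops capped at 10 unpaired bases per strand, and a +4.1 kcal/mol
initiation term. The stacking table is a simplified GC-content-tiered
scheme (G:C/G:C −3.3, G:C/A:U −2.2, A:U/A:U −1.1, one wobble −1.0, two
wobbles −0.4 kcal/mol) shipped as a documented data file
(`mirfsh/data/stack_energies.tsv`); it preserves the orderings the
analysis depends on (GC-rich duplexes are more stable, wobbles are weak)
without claiming to reproduce any external tool's absolute energies — all
acceptance checks are threshold- or oracle-based.

Two scoring routines share this model:

- `duplex_mfe` optimizes freely over all antiparallel non-crossing pairings
  (dynamic programming over pair-ending states; a duplex requires at least
  two base pairs, otherwise a no-duplex sentinel is returned). It is tested
  for exact equality against exhaustive enumeration on random short pairs.
- `predict_targets` scores each seed match with the seed helix *fixed* at
  the matched register and optimal 5'/3' extensions found by an anchored
  DP restricted to 30 UTR bases on each side of the match (a ~60-nt local
  hybridization window). Anchoring guarantees that every accepted site's
  pairing covers the full seed, and bounds the DP cost.

A site is accepted when its anchored MFE is strictly below the threshold
(default −20 kcal/mol). Per miRNA–transcript pair the best site is the
lowest MFE, ties broken by smallest start coordinate; output ordering is
deterministic by (miRNA, transcript, start). Coordinates are 1-based
inclusive on the UTR 5'→3'; DNA input is transparently converted to RNA.

Conservation of a site across species is presence/absence of an exact
all-Watson–Crick seed complement in each ortholog UTR (≥ 2 species
required); the site is conserved when present in all.

## Genomic mapping and clusters

Precursor hairpins are located by exact string search against both genome
strands (U/T and case transparent); every copy is reported with 1-based
inclusive coordinates and precursors with zero hits are listed as unmapped.
Loci are attributed to each mature product of a hairpin (the two 5p/3p arm
pairs share their precursors), and per-chromosome summaries count distinct
miRNAs (two copies on one chromosome count once). Clusters are
single-linkage chains of same-chromosome loci whose intergenic gap —
defined as next.start − current.end − 1, so the planted miR-133b/miR-206
pair measures exactly 3766 bp — is at most 10 kb by default (no threshold
is published; the 3.8 kb pair motivates the conventional 10 kb).
Singletons are not clusters.

## Pathway enrichment

Over-representation only (upper tail): p = P[X ≥ observed] under
hypergeometric sampling without replacement, where "observed" is the
overlap between predicted-target genes and the pathway. Sets with overlap
below 20 (the screening rule this pipeline reproduces) are excluded before
testing; survivors are Benjamini–Hochberg adjusted (the source says only
"FDR"; BH is the documented choice) and flagged at adjusted p < 0.05. The
universe defaults to the union of all gene-set members and the query, since
the original universe (all porcine transcripts with 3'-UTRs) is not
packaged; an explicit universe file overrides it, and query genes outside
the universe are dropped and logged.

## Synthetic-data generator

One integer seed drives named substreams (array, qPCR, hormone, genome,
UTR, mature synthesis); identical configurations give byte-identical files.
What it emulates, and how:

- **Matures.** Only one mature sequence appears in the source material, so
  matures are synthesized as U + published 7-mer seed + random 14-nt tail
  (miR-361-3p keeps its known suffix, giving UCCCCCAGGUGUGAUUCUGAUU); seed
  extraction at 2–8 therefore reproduces every published seed verbatim.
- **Array.** Per probe, A ~ U(6, 14); observed M = planted log2 ratio
  (0 for null probes) + polynomial dye bias in A (default −0.3 + 0.05·A,
  linear so the local-linear smoother can remove it exactly at noise 0) +
  N(0, noise_sd) (default 0 — the planted-recovery condition). Intensities
  are reconstructed as Hy3 = 2^(A+M/2), Hy5 = 2^(A−M/2). A configurable
  fraction of *null* probes (default 5 %) fails the QC gate, alternating
  low-SNR and dead-channel modes; planted probes always pass. Defaults
  plant the 31 published fold changes among 800 null probes.
- **qPCR.** Triplicate Ct per group and gene; planted ΔΔCt for the ten
  re-measured miRNAs equals −log2(array fold) with miR-708-5p set to 0
  (its reported non-significance), plus FSHβ at −log2(1.6) against β-actin.
  Ct noise defaults to 0.05 cycles — within the typical technical-replicate
  range and chosen so the smallest planted effect (≈ 0.38 Ct) is detected
  with near-1 power in triplicate, which is the validation outcome the
  fixture is specified to emulate.
- **Hormone.** Six wells per group at the published means and SDs. Samples
  are drawn normally and then standardized to the exact requested sample
  mean and SD ("exact moments", default on), so the printed-mean contracts
  hold for any seed; a flag disables this for null-calibration simulations,
  where exact moments would distort the t statistic. Raw FSH is per-mg
  value × a random protein mass, so the calibration step is exercised.
- **Genome.** A locus plan embeds 25 hairpins across 12 chromosomes with
  15 kb spacing (so no spurious clusters), the miR-133b/miR-206 pair at an
  exact 3766 bp intergenic gap, let-7a as two identical copies on one
  chromosome, miR-340 on two chromosomes, three hairpins on the reverse
  strand, and four precursors absent from the genome. Chromosome
  assignments are synthetic but reproduce the published aggregate: 27 of
  31 miRNAs mapped, 8 on chromosome 12, 4 on X (including both mir-361
  arms).
- **UTRs and gene sets.** Planted sites embed the full reverse complement
  of the mature, so the seed complement sits exactly at the declared
  position and the anchored MFE clears the filter with margin (verified
  < −25 kcal/mol at generation). Decoy UTRs carry bare 7-mer seed
  complements whose flanks are resampled until the anchored MFE stays
  above −18 kcal/mol, giving the strict −20 rule real margin on both
  sides. FSHβ ortholog UTRs for pig, sheep, cattle, mouse and human each
  carry the all-WC miR-361-3p site (CUGGGGG). The GMT contains one set
  enriched in planted target genes (22 of 24), a broad background set, two
  mid-size sets, and one undersized set that the overlap filter must drop.

What the generator does **not** emulate: array image artifacts, spatial or
print-tip effects, probe cross-hybridization, background subtraction
(foreground-only intensities; the original background-correction method is
unstated), qPCR efficiency differences, ELISA curve fitting, genome
assembly gaps, or realistic UTR base composition and site accessibility.
Passing tests therefore demonstrate correctness of the computational chain
under its stated model, not robustness to those real-data phenomena.

## Problem sizes

Defaults were chosen so a full demo run is seconds on one core: 831 probes
(31 planted + 800 null), 24 planted target genes + 16 decoy UTRs of 500 nt,
a ~0.5 Mb mini-genome, triplicate qPCR for 13 genes, six wells × eight
hormone groups. Monte-Carlo checks in the test suite use 200–2000
replicates, sized so that 3-standard-error acceptance bands are meaningful.

## Known limitations

- The energy model is intentionally simplified; absolute MFE values are not
  comparable to Turner-parameter tools, only orderings and thresholds
  within this model are meaningful.
- Exact-match genomic search cannot tolerate assembly mismatches; that is
  out of scope by design.
- The single-slide design admits no probe-level variance model, so the
  fold-change thresholds are descriptive filters, not hypothesis tests.
- Published genome-scale counts (6174 predicted transcripts, 25 pathways,
  etc.) depend on 2012 database snapshots and are not reproduced here; the
  pipeline reproduces the *procedures* and verifies them on planted truth.
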