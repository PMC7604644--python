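# Methods

This note documents the statistical model, the numerical choices, and the
known limits of `bafcnv`. It is written for users deciding whether the
method's assumptions fit their data and for maintainers wondering why a
design decision was made.

## Model and assumptions

The unit of evidence is a germline heterozygous SNP observed in a matched
case/control pair as two (depth, alt-count) pairs. Assumptions:

* allele counts are binomial given depth (no overdispersion model;
  beta-binomial extensions are out of scope),
* the control is diploid at every gated SNP (expected VAF 0.5),
* an event is a single-copy gain or loss of one haplotype, present in a
  fraction CF of cells; copy numbers outside [1, 3] are not modelled, and
  CF transforms that imply them are clamped to [0, 1],
* per-site depth is approximately log-normal (used only by the simulation
  approach of the quality analysis; the exact approach uses observed depths).

All VAF arithmetic happens on the folded scale min(v, 1 − v), since an
unphased heterozygous site cannot identify the affected haplotype. The
folded expectations are (1 − CF)/(2 − CF) for deletions and 1/(2 + CF) for
duplications; both are strictly decreasing in CF, so their inverses are
well defined on [0, 0.5]. The duplication inverse diverges at folded VAF 0;
that limit (and any folded VAF below 1/3, which implies copy number > 3) is
clamped to CF 1. Copy-neutral LOH shifts VAFs exactly like a deletion and
is reported as one; the coverage indicator (below) is the disambiguator.

## Step 1 — detection thresholds

For each CNV type and every cell fraction on a grid (default 5–100% in 5%
steps), the smallest SNP count min_SNP is sought whose one-tailed
coverage-weighted t-test (case CF > control CF, α = 0.0125) rejects in at
least `target_sens` (default 0.95) of simulated windows (default 500 per
grid point). Control allele counts are Binomial(depth, 0.5), case counts
Binomial(depth, E[VAF | type, CF]); depths come from a log-normal model
fitted by maximum likelihood to each sample's observed positive depths (at
least 30 required; zeros are excluded). The exact approach instead slides
over every run of n consecutive observed SNPs per chromosome, using
observed depths on both sides and observed control VAFs, simulating only
the case counts; each SNP's simulated count is drawn once and shared by the
windows containing it.

**Crossing estimation.** The raw Monte-Carlo rate curve is noisy while true
power is monotone in n. Stopping at the first raw crossing of the target
selects on upward noise: in measurement, the true power at the stopped n
was as low as 0.935 for duplications at CF 0.4, where the power curve gains
only ~1% per SNP. The scanned rates are therefore pooled by isotonic
regression (PAVA), and min_SNP is the smallest n whose pooled rate minus
one binomial standard error reaches the target, confirmed by two further
grid points. This is slightly conservative (≤ ~2 SNPs), which is the
correct side to err on for a sensitivity guarantee.

min_SNP is translated to a window size W as the 95th percentile (default)
of the genomic lengths pos[i+n−1] − pos[i] + 1 of all runs of n consecutive
heterozygous SNPs, pooled over chromosomes: a window of W bp then contains
≥ min_SNP SNPs with 95% probability under the sample's own SNP spacing.

**Operating point.** Reachable grid entries trade a low detectable cell
fraction against a small window. By default the window sizes are min–max
normalised to [0, 1] and the entry minimising |CF − W_norm| is selected
(ties toward smaller CF); `min_cf` and `min_w` modes force either extreme.
Samples with no reachable entry are reported as not apt for calling that
CNV type.

**Randomness.** Every (type, CF, n) grid point derives its generator from
`SeedSequence([seed, type, round(cf·100), n])`, so results are independent
of evaluation order and fully reproducible from one integer seed.

## Step 2 — calling

SNPs are gated by the control's exact Clopper–Pearson 99% CI covering 0.5
(the exact construction is what makes "99 of 100" honest at low depth);
duplication support additionally requires the case CI to cover folded 1/3.
One window of size W is anchored at each gated SNP (windows anchored
between SNPs would contain identical SNP sets) and never crosses a
chromosome. Case and control per-SNP CFs are compared twice (alternatives
"CNV" and "no CNV") with a weighted Welch t-test using reliability weights
w = depth: weighted mean Σwx/Σw, unbiased weighted variance
Σw(x−m)²/(Σw − Σw²/Σw), effective sample size n_eff = (Σw)²/Σw², and
Welch–Satterthwaite degrees of freedom on n_eff. With equal weights this
reduces exactly to Welch's t-test (tested against an independent
implementation). Windows with fewer than two usable SNPs, or an effective
sample size below 2, are not testable. Zero-variance windows are decided
by the sign of the mean difference; no jitter is added.

**Region CF estimate.** The reported CF is the inverse-transform of the
depth-weighted *pooled* folded case VAF (equivalently, of Σalt/Σdepth when
all sites lie on one side of 0.5), with a delta-method standard error. Two
tempting alternatives were measured and rejected: averaging per-SNP CFs
case-minus-control is biased by −0.13 to −0.30 at 100× depth, because the
folding of null control VAFs puts E[per-SNP control CF] near 0.15 rather
than 0, and because the duplication transform amplifies per-SNP noise near
VAF 1/3. Control CFs still enter the significance tests — only the point
estimate bypasses them.

**Support trimming.** A window straddling an event boundary legitimately
rejects while covering SNPs outside the event; untrimmed, those SNPs
dilute CF estimates by up to ~0.25 and stretch call coordinates by up to
W. Each call's supporting run is therefore trimmed to its maximum-evidence
contiguous core: per SNP the score is the observed folded-VAF shift
(0.5 − fold(v)) minus a penalty of 1.5·(0.5/√depth) (the expected shift
under no event is ≈ 0.8 of that scale), and the maximum-sum contiguous
subarray wins. This is boundary refinement at SNP resolution — calls can
never be located more precisely than the SNPs that carry the evidence.

Raw calls are significant "CNV" windows whose (untrimmed) support reaches
min_SNP; their interval is the trimmed supporting-SNP span, and calls with
estimated CF below the type's threshold minus a 5% margin are excluded.
Each call carries a coverage indicator: the 99% normal-approximation CI on
the mean log2 of (case depth / case median depth) / (control depth /
control median depth) over the supporting SNPs, classed negative /
spans_zero / positive. Medians over all gated SNPs act as library-size
factors, so a global sequencing-depth difference does not masquerade as a
CNV.

## Steps 3 & 4 — merging and filtration

Two calls merge iff they share chromosome and type, their CFs agree within
3 pooled standard deviations (√(sd_a² + sd_b²)), and they overlap or are
separated by < 20 Mb with no significant same-type "no CNV" window wholly
inside the gap (a "no duplication" verdict says nothing about deletions;
the 20 Mb default bridges centromeres, which span at most ~7.4 Mb). The
merge is the transitive closure of this relation (union–find), so the
result is order-independent and idempotent. Merged CF, sd and the coverage
indicator are recomputed over the re-trimmed union of supporting SNPs; a
merged CF that falls below the detection threshold is flagged rather than
dropped (such regions always contain ≥ 2 raw calls that individually
passed).

Quality is −log10 of the best constituent window p-value, capped at 300.
The shipped default filtration threshold of 10.76 is a configuration value
(`quality_threshold`); its separation of true from false calls should be
re-established on data resembling yours — the synthetic harness
(`recovery_harness`) does exactly that, and on the panels used in the test
suite false calls score < ~6 while implanted events score > ~14.

## Synthetic data

The generator emulates what the caller actually consumes: exon-like
clustered SNP positions (Poisson cluster centres, geometric cluster sizes
and within-cluster gaps; default density 3.5 SNPs/Mb, matching the
~10,000 heterozygous SNPs per exome of typical cohorts), log-normal depths
drawn independently per sample (default 100×, sdlog 0.5), binomial allele
counts, and implanted events whose affected haplotype is drawn once per
event, producing the realistic mixture of 33%- and 67%-centred tracks.

Not emulated — and therefore not demonstrated by passing tests: read-level
errors and mapping artefacts, GC/mappability coverage waves, germline CNVs
or contamination in the control, and the depth change a real CNV causes.
The last point means the coverage indicator reads `spans_zero` on
synthetic panels (as for LOH); its directional behaviour is exercised by
dedicated constructions in the unit tests instead.

The recovery harness scores a call as true when it overlaps an implanted
event of the same type, and counts an event as *detectable* only when the
sample's own thresholds admit it (CF ≥ CF_min and span ≥ W) — sensitivity
is reported over detectable events, mirroring how detection-aware callers
should be judged.

## Problem sizes and runtime

The default grid (20 cell fractions × up to 100 SNP counts × 500
replicates, vectorised over replicates) profiles a sample in ~5–10 s on
one core. The test suite's recovery experiments use 20 replicates of
2-chromosome, ~220 Mb panels at 3.5 SNPs/Mb and 100× depth — small enough
to run routinely, large enough that each event spans dozens of SNPs and
each panel yields several hundred windows per type.

## Known limitations

* Only simple single-copy gains and losses; no sub-clonal copy-number
  mixtures within one region, no copy numbers beyond [1, 3].
* Type ambiguity is inherent: a duplication in CF cells equals a deletion
  in CF/(1+CF) cells on the VAF scale, so both interpretations can be
  reported for one region; the coverage indicator (real data only)
  disambiguates.
* The duplication candidate rule (case CI covers 1/3 or 2/3) excludes the
  most-null VAF band and thus makes the duplication null slightly
  anti-conservative at high depth; false duplication windows are rare and
  score far below the quality threshold, but the duplication type-I rate
  is not exactly α.
* Y and (by default) X chromosomes are not evaluated; hemizygous SNPs
  carry no heterozygous signal.
* Calls cannot be smaller than the window W nor sharper than the local SNP
  spacing.
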