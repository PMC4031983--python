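# Methods

## Scope and model

The package implements two computational procedures around miRNA-mediated
suppression of homologous recombination (HR), plus the synthetic data needed
to test them end to end.

### Screen model

A gain-of-function mimic screen reads out cell viability (luminescence, ATP
proxy) with and without a PARP inhibitor. The analysis model is
deliberately minimal:

* **Per-plate, per-arm normalization.** Plate effects are real (transfection
  efficiency, reagent batches, reader drift), so the negative-control mean μ
  and sample SD σ (ddof = 1) are estimated per plate and per treatment arm,
  never pooled. `%viability = 100·x/μ` and `z = (x−μ)/σ`.
* **Replicate averaging.** Screens are run in triplicate; replicate wells of
  a mimic are averaged per arm *before* thresholding. A raw-per-well mode is
  retained behind `average_replicates=False`.
* **Hit rule.** Not toxic ∧ z < −2 ∧ drug-arm %viability < 75. Both
  inequalities are strict. The screen literature also supports using the
  per-plate BRCA2-siRNA Z as the cutoff instead of the constant −2; that
  reading is available via `z_reference="brca2"`, with the reproducible
  numeric constant as the default.
* **Toxicity.** A mimic whose vehicle-arm %viability is ≤ that of the
  BRCA2-siRNA control is excluded — BRCA2 depletion already costs viability
  without any PARP inhibition, so such mimics kill for drug-independent
  reasons. Equality counts as toxic. No additional statistical test is
  applied; the comparator is the whole rule.
* **Ranking.** Hits sort by ascending %viability; ties break by ascending z,
  then lexicographic mimic id, making output order deterministic.

`fold_enrichment(A_pd, B_pd, A_in, B_in) = (A_pd/B_pd)/(A_in/B_in)` covers
the pull-down enrichment ratio used in mimic-capture experiments.

### LOH classification

Loss of heterozygosity can arise by physically losing one allele
(deletion-mediated, copy number < 2) or by mitotic recombination that leaves
two copies of one parental allele (copy-neutral). Copy-neutral LOH is the
scar ectopic HR leaves behind, so the association analysis counts exactly
those events. Two platform-specific rules are implemented:

* **aCGH rule** (`classify_acgh`): deletion segments are copy-number
  segments with log2 ratio strictly < −0.20. An event is deletion-mediated
  iff the union of deletion segments covers ≥ 80% of its length. Union
  coverage is used (overlapping segments counted once): "overlap with
  deletion events" is naturally a property of the covered base set, and the
  union is testable against a per-base oracle. Copy-neutral events are
  retained iff strictly > 1 Mb; deletion-mediated events are never retained.
* **SNP rule** (`classify_snp`): events strictly > 10 kb are scored by
  n/N, the fraction of marker SNPs inside the event (half-open interval;
  markers on the start boundary count, on the end boundary do not) with
  allelic copy number strictly < 1.9. n/N ≥ 0.8 (non-strict) is
  deletion-mediated; the 0.75 cutoff is exposed for sensitivity reruns.
  Events with no marker (N = 0) are excluded with a logged warning rather
  than guessed — the rule is undefined there.

The strict/non-strict placement of every inequality is pinned by boundary
fixtures in the test suite (`boundary_fixtures()`).

### Locus genotyping and groups

Loci are tens of bp, so the aCGH representative value is the log2 ratio of
the single segment overlapping the locus midpoint (not a length-weighted
mean; if several segments overlap the midpoint, the smallest-start one wins
deterministically). The SNP path uses the nearest marker, distance 0 inside
the locus, equidistant ties to the lower genomic position. Bands are closed:
log2 in [−0.2, 0.2] and copy number in [1.9, 2.1] are neutral.

miR-1255b has two genomic loci; the combined call is deletion if either
interval is deleted, else amplification if either is amplified, else neutral
if both are neutral, otherwise unknown. WT requires neutrality at all three
miRNAs; a sample joins every deletion group whose miRNA is deleted (groups
are not mutually exclusive — each group is compared to WT independently);
samples that are neither (amplification-only, or any unknown) are excluded.
Only the two miR-1255b interval coordinates ship as defaults — the
miR-148b*/miR-193b* coordinates are genome-build dependent and must be
supplied (the synthetic cohort carries its own locus set, with synthetic
placements for those two).

### Association

One-tailed Mann–Whitney U, alternative fixed a priori as deletion > WT for
every metric (copy-neutral LOH count, SCNΔ count, BRCA1 expression) — the
direction is the scientific hypothesis, not estimated from data. P-value
regimes, chosen for determinism:

* no ties and n_a·n_b ≤ 400 — exact distribution of U (scipy);
* ties and n_a + n_b ≤ 12 — exhaustive enumeration of all C(n, n_a)
  group assignments over pooled midranks;
* otherwise — normal approximation with midranks, tie correction and
  continuity correction.

Identical pooled values give p = 0.5 with a warning; an empty group yields
an untestable result row, not an exception. No multiple-testing correction
is applied across the three deletion groups by default (none is part of the
procedure being implemented); `alpha` is configurable.

SCNΔ counting merges adjacent (touching or overlapping) same-sign
out-of-band segments (log2 < −0.2 or > 0.2) per chromosome into one event;
neutral segments or sign flips split runs.

## Synthetic data: what it emulates, what it does not

### Screen generator

Defaults: 880 mimics, 20 planted sensitizers with drug-arm effect 0.5, 10
drug-independently toxic mimics, triplicate wells, multiplicative log-normal
well noise with CV 10% (mean exactly 1), per-(plate, arm) log-normal scale
factors (σ_log = 0.15), 384-well plates with 32 negative-control and 6
BRCA2-siRNA wells. The BRCA2 control sits at 55% viability in vehicle and
20% under drug; toxic mimics at 40% in both arms. With these settings a
planted hit averages ~50% viability (z ≈ −5) while a null mimic's
replicate-averaged z has SD ≈ 0.6, so the designed scenario separates
cleanly; the control count was chosen from these analytics so that the
σ-estimation noise of the plate does not produce spurious hits.

### Cohort generator

Defaults: 40 WT + 10 samples per deletion group on a scaled six-chromosome
genome (6 × 200 Mb). Per sample:

* Poisson(60 | 80) **large copy-neutral events**, sizes log-uniform
  (1 Mb, 10 Mb]. The rates are calibrated as *retained* (> 1 Mb)
  copy-neutral events per sample, matching the ~60 per-tumor burden of a
  high-grade serous ovarian cohort; WT vs deletion-group rates 60 vs 80.
* Poisson(15) small copy-neutral events (1 kb–1 Mb) and Poisson(25 | 35)
  deletion-mediated events (1 kb–10 Mb), so both size filters are exercised
  from both sides and SCNΔ burden also differs between groups.
* Each deletion-mediated event carries a deletion segment (log2 in
  [−0.8, −0.3]) covering a fraction drawn from [0.92, 1.0] of its length —
  comfortably away from the 0.80 coverage boundary, which keeps planted
  labels unambiguous. Boundary behaviour is tested with dedicated fixtures
  instead of random near-boundary events.
* Events never overlap within a sample and keep a 3 Mb guard zone around
  every miRNA locus, so a copy-neutral event can never be shadowed by
  another event's deletion segment.
* Deletion-group samples get a 2 Mb deletion segment over the assigned
  locus (for miR-1255b, one of its two loci at random); neutral background
  segments (log2 in [−0.05, 0.05]) tile the rest of every chromosome.
* Markers: a 200 kb grid plus 10–40 in-fill markers per LOH event; a
  marker's allelic copy number is 0.8–1.2 under any deletion segment and
  1.92–2.08 otherwise. The in-fill guarantees N ≥ 10 for scored events, so
  n/N tracks the planted coverage fraction deterministically.
* BRCA1 expression ~ Normal(8, 1) plus +1.0 in deletion groups (log2
  microarray-like units; a modest effect, by design — with n = 10 per group
  some expression comparisons land near the significance edge, as real
  cohorts do).

All randomness flows from one root seed through per-stage child generators
(`numpy.random.SeedSequence.spawn`), so each layer is individually
reproducible. The generator does **not** model allele-specific intensities,
GC waves, segmentation noise, marker dropout, subclonality or purity; a
passing planted-truth test shows the rules are implemented correctly, not
that they are robust to real array noise. The per-sample event-count
distribution (Poisson) and the log-uniform size law are generator choices,
recorded in the truth sidecar.

## Problem sizes and runtimes

The test suite runs the full designed scenarios: the 880-mimic screen, ten
70-sample cohorts for planted-truth recovery (three of them with the full
marker layer), 100 replicate 50-sample cohorts for the power estimate
(generated without the marker layer, which the aCGH association path does
not read), and 1,000 null burden cohorts drawn at the counts level — the
generator's retained-event counts are Poisson by construction, so the null
distribution of the burden metric is sampled directly. The complete suite
finishes in about a minute on one core; `scripts/acceptance.py` in under
half a minute.

## Known limitations

* Coverage and n/N rules assume segments/markers and events come from the
  same coordinate system and sample; no liftover, no germline/somatic
  disambiguation.
* The aCGH midpoint rule ignores loci that straddle a segment breakpoint
  (real loci are 62–67 bp; the fallback is the documented smallest-start
  tie rule).
* Cross-library confirmation of screen hits (a second mimic library) is a
  qualitative join, not a thresholded procedure, and is not modelled.
* Expression values are taken as provided; no array preprocessing or
  normalization is performed.
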