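# Methods

This note records the models, conventions and numerical choices behind
`meiomap`, and what the synthetic-data validations do and do not show.

## Data model

A meiosis is represented per chromosome as an 8 × markers matrix of
binary parental genotypes (1 = reference parent, S288c-like; 0 =
variant parent, SK1-like). Rows are ordered as chromatid pairs: rows
2k and 2k+1 are the mother and daughter strands of chromatid k;
chromatids 0–1 start the chromosome as the reference parent and 2–3 as
the variant parent. All marker coordinates are 1-based inclusive; BED
input/output is converted at the file boundary.

## Genotype calling

Calls follow fixed read-fraction thresholds, all ≥-inclusive: minimum
depth 5; SNPs are variant at ≥ 0.70 variant reads, reference at ≥ 0.90
reference reads, heteroduplex when reference+variant ≥ 0.90 of all
reads *and* the two counts are within 70% of each other; indels are
variant at ≥ 0.30, reference at ≥ 0.95 with fewer than two variant
reads, and never heteroduplex (alignment around indels is
reference-biased, so mixed indel counts are uninformative). "Within
70% of each other" is read as min/max ≥ 0.70; the alternative reading
|ref−var|/depth ≤ 0.30 is available via
`CallerConfig(het_balance_mode="diff")` but is not the default. In true
octads heteroduplex calls are artefacts of a single-strand sample and
are discarded; markers heteroduplex in more than two samples of a
tetrad are removed as presumed marker-table errors.

Mocktads fix the arbitrary polarity mother → variant parent, daughter
→ reference parent, and carry a per-spore "polarity unknown" flag until
a resequenced single colony resolves it. Phasing assigns the colony's
call to its declared strand and the complement to the other, and never
touches non-heteroduplex positions.

## Segmentation and event calling

Chromosomes are split into maximal runs of identical 8-strand vectors;
columns containing missing calls are excluded and bridged (depth gaps
must not split events). A column is Mendelian when it is 4:4 with
concordant strand pairs in any chromatid arrangement; starred patterns
mark discordant pairs (retained hDNA) or, for 4:4, an arrangement
differing from a supplied reference configuration.

Events are groups of anomalies: non-Mendelian segments plus haplotype
switch points between adjacent Mendelian segments (a crossover with no
detectable strand transfer, or the boundary of a perfectly overlapping
double conversion). Two anomalies separate into distinct events only
when an intervening Mendelian run spans at least 1500 bp between their
outermost non-Mendelian markers ("at least 1.5 kb of 4:4"); anomalies
with no Mendelian marker between them always share an event, whatever
the bp distance (marker deserts do not split events). Events reaching
a chromosome end without returning to 4:4 are type U and enter no
CO/NCO tally. CO count is the number of chromatids whose parental
identity differs between the two flanking Mendelian segments, divided
by two; an odd number marks the event irregular and the count is the
best even fit.

Mid-length — the tract-length estimate — is the distance between the
midpoints of the two inter-marker intervals flanking the event;
multi-DSB events are excluded from length statistics, as the
per-component attribution is ambiguous.

## Classification

Multi-DSB classes are deliberately conservative: dCO only for a
four-chromatid double reciprocal exchange; CO+NCO only when the
conversion lies on a third chromatid; double NCOs only on two sister
chromatids (sisterhood = same flanking parental identity) or on two
homologues with perfectly overlapping tracts (identical first and last
converted marker indices — one marker short of perfect is class
"none"). 8:0/7:1 segments are trans-DSB evidence; an 8:0 run with no
adjacent heteroduplex-bearing segment is instead flagged as a suspected
premeiotic conversion, and in MMR-proficient tetrads (where 7:1 cannot
arise) the assay reports not-applicable rather than negative.

Strand-transfer subcategories are read from observable patterns:

* conversion *direction* comes from the column ratio itself — a 5:3
  column donates toward the five-count parent — which remains
  computable in unphased mocktads;
* *trans* hDNA (two half-conversion tracts of opposite polarity on one
  chromatid) is detected as a mother/daughter orientation flip, which
  genuinely requires strand polarity: in an unphased mocktad the
  arbitrary polarity is constant, such events fall into the one-sided
  class, and the event carries a `polarity_limited` flag;
* for crossovers, a single joint switch point is fitted for the two
  recombining chromatids (heteroduplex columns neutral; homozygous
  columns violating the fitted expectation are full-conversion
  tracts). Two-sidedness means transfer on both recombining
  chromatids, an orientation flip, or restoration-separated tracts;
  bidirectionality means converted markers from both parents; a 4:4*
  segment inside a CO is symmetric hDNA and takes precedence.

QC across meioses drops isolated 8:0-only events, drops 8:0 loci
recurring at the identical position in more than one meiosis, and
flags meioses carrying >100 kb 8:0 blocks or chromosomes heteroduplex
in exactly two spores over >80% of markers (disomy signature) as
premeiotic suspects, to be excluded from count statistics but not from
length statistics.

## Statistics

The non-exchange null allocates N crossovers multinomially with
chromosome weights p_i = L_i/ΣL and records zero-CO chromosomes;
10,000 replicates per N over a 1–200 grid. Its mean has the closed
form Σ_i (1−p_i)^N, used as the analytic oracle. Per-genotype
aggregation is the published median-of-probabilities raised to the
number of meioses; the implementation emits a warning that this is a
robust summary, not a calibrated combined p-value. Non-exchange is
zero-CO by default; the stricter zero-CO-and-NCO tally is reported
alongside.

Inter-crossover distances are computed in bp within chromosomes,
CO-to-CO only, pooled across meioses per genotype. Each crossover is
anchored at the mean of its two chromatids' haplotype switch positions
(midpoint of the inter-marker interval at the best monotone split); a
double CO resolves its two exchange points separately so that closely
spaced double COs contribute their internal distance. Event midpoints
are the fallback for irregular events. The gamma MLE solves
log(a) − ψ(a) = log(mean) − mean(log x) by bracketed root finding
(xtol 1e-12) with the scale from the mean identity γα·γβ = sample
mean; near-constant data cap the shape at 10⁶ with a warning. The
matched random reference draws, per simulated cell, as many
exponential ICDs as the matched experimental cell, with the
experimental mean (10,000 cells). Hypothesis tests delegate to
scipy/statsmodels with the conventions used throughout: two-sided
Fisher exact, Wilcoxon rank-sum with normal approximation and
continuity correction, Welch t, two-sample KS, Benjamini–Hochberg
adjustment.

## Synthetic meioses

The generator emulates an S288c × SK1 hybrid: 16 chromosomes at their
R64 lengths (centromere midpoints approximate), ~65,000–71,000 markers
with exponential inter-marker spacing of mean 169 bp and a 5.8% indel
fraction. Crossovers follow a gamma renewal process along each
chromosome (shape = interference strength, 1 = Poisson/random; scale
set so the genome-wide expectation is `mean_co`, which reproduces
length-proportional allocation); each CO reciprocally exchanges the
distal arms of one chromatid per parent and deposits the canonical
trans pair of hDNA tracts (donor = the partner homologue) with
normal(mean 1500, sd 300) bp lengths, matching wild-type resection
scale. NCOs are one-sided single-chromatid hDNA tracts placed
length-proportionally at a default NCO:CO ratio of 1:3. Multi-DSB
clusters (dCO, dNCO on sisters, perfectly overlapping dNCO on
homologues, CO+NCO on a third chromatid; ~5 per meiosis by default,
spacing < 1.5 kb) reproduce the conservative multi-DSB categories.
Under MMR deficiency hDNA is retained; under proficiency each tract
resolves wholesale to conversion or restoration with probability 0.5
each — a free parameter, not an empirical claim, since no generative
restoration:conversion ratio is established; per-marker resolution is
available (`mmr_resolution="marker"`) but produces speckled tracts
unlike real conversion tracts and is not the default. Pileup counts
draw Poisson depth (default 45×) with a symmetric per-read error rate
(0.002), octad samples from single strands and tetrad colonies from
50:50 strand mixtures.

Two placement constraints keep planted truth observationally
well-defined: initiations stay clear of the chromosome ends by the
tract mean + 4 sd (an initiation in the terminal marker desert is
undetectable in principle), and recovery experiments may set
`min_event_sep` (rejection of inter-CO gaps below ~7 kb) so that no
two planted crossovers merge ambiguously into one event. The
separation guard distorts the inter-CO distance distribution and is
therefore *off* by default and never used in interference experiments.

## Validation experiments: sizes and rationale

* Truth recovery runs 50 meioses (90 COs, 30 NCOs, tract mean 1.5 kb,
  error-free 40× counts, separation guard on) through the full
  pipeline; it recovers ≈ 98–99% of planted simple events (losses are
  events merging within 1.5 kb of another, which the calling rule
  dictates) and per-chromosome CO counts exactly.
* The interference experiment simulates 30 meioses each at gamma shape
  1 and 4 (90 COs, compact 300 bp tracts chosen to minimise
  event-merging censoring of short inter-CO distances — tract length
  is irrelevant to the position statistics under study). Fitted shapes
  order strictly (≈1.1 vs ≈4.0) and the KS comparison against the
  matched exponential separates the two. Two small method-level biases
  keep the shape-1 fit slightly above 1: crossover pairs closer than
  the 1.5 kb event separation merge (censoring short distances; double
  COs are recovered via their two switch anchors, but pairs sharing a
  chromatid are genuinely unrecoverable), and finite chromosomes
  right-censor long gaps. Together they contribute a KS distance of
  ≈ 0.01–0.02 at pooled n ≈ 2,100, so the "random" run's KS p-value,
  while usually comfortably non-significant, can dip low for unlucky
  simulation seeds; this is a property of the measurement process, not
  of the fitter.
* The mocktad round trip uses a SNP-only map: indel sites cannot be
  called heteroduplex (by design of the caller), so mocktads are blind
  to hDNA at indels and exact octad/mocktad agreement is only defined
  over SNPs. Sequencing is simulated at 150× because the heteroduplex
  balance rule stochastically drops ~20% of mixed markers at 45×
  (caller-faithful behaviour that fragments marker-level identity
  while leaving event-level calls intact).
* The statistics layer is checked against R (`fisher.test`,
  `wilcox.test` with `exact=FALSE, correct=TRUE`, `t.test`, `ks.test`,
  `p.adjust(method="BH")`) to 1e-8 on 100 random inputs.

## What the synthetic validations do not show

The generator plants canonical event architectures; it does not model
chromatin-driven DSB hotspot landscapes (hotspots are consumed as a
generic interval track), resection-length heterogeneity, branch
migration, template switching, mismatch-repair patchiness, mapping
artefacts near repeats, or aneuploidy. Passing recovery tests
demonstrate that the calling and classification logic inverts the
generative model faithfully at realistic marker density and coverage —
not that real libraries are free of the alignment- and
reference-quality failure modes the QC layer exists to catch.
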