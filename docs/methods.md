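# Methods

## Consensus model

A CNV call is a tuple (sample, caller, chromosome, start, end, type,
quality) with 0-based half-open coordinates; VCF POS is interpreted as the
1-based first affected base and INFO/END as the last, so `start = POS − 1`,
`end = END`, and event length is `end − start`. All comparisons are exact
string matches on chromosome names after optional `chr`-prefix
normalization.

Two calls are *compatible* when they share chromosome and type and both
breakpoints lie within `d_max` (default 1000 bp, inclusive). Within a
sample, clusters are the connected components of the pairwise-compatibility
graph, computed per (chromosome, type). Connected components were chosen
over seeded/greedy merging because they are order-independent — the
retained set is invariant under permutation of the input — and directly
checkable against a brute-force O(n²) oracle. The known cost is that a
chain of calls can span more than `d_max` end-to-end; this is accepted and
tested. Within a component at most one call per caller is kept (highest
quality, ties to the leftmost start), so "three supporting callers" always
means three *distinct* callers. The merged event takes the member-wise
median start and end (lower median for even counts), a deterministic,
outlier-robust representative.

Filters, in order, with the first failing rule logged per event:

* **support**: ≥ `min_callers` distinct callers (default 3 of 4);
* **size**: length ≥ `min_size` (default 10 000 bp). The size rule is
  applied inclusively; the boundary semantics are config-exposed;
* **quality**: every member call from a caller with a floor must meet it
  (MANTA ≥ 100, DELLY ≥ 1000; CNVnator and LUMPY have no floor). A
  sub-floor member vetoes the whole event rather than being dropped and
  support recounted — the stricter reading of "further filtered"; clearing
  `qual_floor` switches the behavior off;
* **carrier frequency**: merged events are re-clustered *across* samples
  with the same compatibility rule (re-using `d_max` rather than a
  reciprocal-overlap criterion keeps one notion of locus identity
  throughout), each cluster's carrier frequency is distinct carriers over
  all samples in the cohort table (all three cohorts), and events with
  frequency ≥ `max_carrier_freq` (default 5%) are removed in every carrier.
  Retention is strict (<), matching the rare-variant reading of an
  "alt allele count < 5%" rule for germline events: carriers of samples,
  not diploid allele counts, are what a multi-caller consensus can observe.

## Gene impact

A gene wholly contained in a CNV (`cnv.start ≤ gene.start` and
`gene.end ≤ cnv.end`, both inclusive in half-open arithmetic) is a full
deletion/duplication; any other positive overlap is partial. A CNV exactly
matching the gene span counts as full. Classification is per (gene, CNV)
pair at whole-gene granularity, strand ignored; multiple partial hits on
one gene in one patient are *not* unioned into a synthetic full call —
partial recurrence stays visible, and the sub-locus comparison below needs
the individual intervals.

## Case-exclusive genes

Exclusivity is enforced at gene × superclass level: a gene is
deletion-exclusive when ≥ 1 BD-cancer patient has any DEL-class impact on
it and no BD-only or control sample has any DEL-class impact — a control
duplication does not disqualify a deletion gene, since deletion and
duplication gene lists are reported separately. The same machinery also
runs at fine granularity (full vs partial) for the stratified lists.
Reports are ordered by recurrence (descending), then gene id, for
deterministic output. For genes partially hit in both case cohorts, the
per-cohort unions of gene∩CNV intervals are intersected; the pair of
sub-loci is "different" exactly when the intersection is 0 bp.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k | N, K, n) (the standard ORA test; computed via `scipy`'s stable
survival function and verified against exact rational summation to 1e-12
for all N ≤ 60), with Benjamini–Hochberg FDR applied within each gene-set
collection separately, mirroring per-category FDR reporting. The default
universe is the gene-model file intersected with the collection's
annotated genes (a "reference set" universe); using the full gene-model
list instead is a flag. Terms with fewer than 2 universe members are
skipped, and only terms with non-zero overlap are reported.

## Phenotype clustering

Cancer diagnosis codes (ICD-10 chapter C, or ICD-9 140–208) are mapped to
seven subtype groups by an ordered prefix table shipped as editable YAML.
The seven-group scheme fixes the category names, not the code ranges; the
default ranges are a documented reconstruction and should be edited per
study. Patients matching several groups are counted in each for
subtype-level summaries (multi-membership), with the first match in rule
order as the primary single assignment. The patient × term matrix counts a
patient under a term when at least one of their impacted genes of the
requested CNV class is in the term's overlap set; percentages always use
the recorded denominator — patients with ≥ 1 retained CNV of that class.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
desk scale: 60 BD-cancer / 80 BD-only / 40 control samples on a 5 × 10 Mb
genome with 800 non-overlapping genes (10% lncRNA, 2.5% other ncRNA, sizes
log-uniform 2–50 kb). Per sample, Poisson(8) true CNVs sized log-uniform
10 kb–1 Mb (deletion probability 0.5); each true CNV is emitted by each
caller with probability 0.92, with start and end independently jittered by
N(0, 150 bp) clipped to ±900 bp, and Poisson(5) false calls per caller per
sample, half deliberately under the 10 kb floor. Quality scores are
Normal per caller and per truth status (MANTA true ~ N(300, 80), false ~
N(40, 20); DELLY 2000/400 and 300/150; CNVnator and LUMPY 50/10 and 10/5),
rounded to two decimals so they survive the VCF QUAL column exactly.
These scales put true-call means well above the MANTA/DELLY floors (each
~0.6% sub-floor) and false means well below, so expected filter behavior
is computable in closed form.

Planted structure:

* **Exclusive genes**: 12 protein-coding genes, 80% drawn from one planted
  pathway of the simulated GMT, mutually ≥ 200 kb apart. Each gets at
  least 3 BD-cancer carriers plus Bernoulli(0.08) additional case
  carriers; the carrier's deletion fully spans the gene with 5–30 kb pads.
  The minimum-carrier floor keeps the exclusivity ground truth informative
  (a gene whose only carrier is lost to caller false negatives would make
  "recovery" undefined rather than measure anything). Background CNVs of
  BD-only and control samples are rejection-sampled away from the planted
  gene spans, so exclusivity is exact by construction; planted events for
  the same gene are kept breakpoint-incompatible across carriers (> 3 kb
  on at least one side) so the rare-variant frequency filter cannot
  cluster them.
* **Common CNV**: one 50 kb deletion locus carried by exactly
  round(0.10 · n) samples drawn without replacement — an exact count, not
  per-sample Bernoulli, so the planted frequency sits deterministically
  above the 5% threshold. Background CNVs stay breakpoint-clear of the
  locus.
* **Jitter clip < d_max**: all calls derived from one truth event are
  pairwise compatible by construction, so the closed-form detection
  probability — the sum over caller subsets of size ≥ 3 of detection ×
  quality-floor pass probabilities, ≈ 0.954 under defaults — predicts
  consensus recall; false negatives and false positives, not jitter,
  drive merge failures.

`SimConfig.noise_free()` is the analytic limit (sensitivity 1, no false
positives, no jitter, zero-variance qualities at the caller means): there
the full pipeline must reproduce the truth set *exactly*, which the test
suite asserts event-by-event. Zeroing the quality variance is part of the
limit's definition: with Gaussian scores even perfect detection would
occasionally draw a sub-floor MANTA score and veto a true event.

What the generator does **not** emulate: read-level noise and coverage
artifacts, realistic human gene density or segmental duplications,
caller-specific breakpoint biases, LD/inheritance between probands and
their related controls, and cohort-scale event counts. Passing recovery
tests therefore validates the pipeline's logic and statistics, not the
behavior of real callers on real genomes.

## Numerical and determinism choices

* All randomness flows from one `numpy` Generator seeded by `SimConfig.seed`;
  coordinates live on the integer grid and jitter is rounded before use,
  so outputs are platform-stable and byte-identical across runs.
* Lower median on even-sized clusters avoids fractional coordinates.
* Tie-breaks are always lexicographic after the primary sort key.
* Degenerate inputs: empty call sets produce valid empty outputs; an empty
  universe or zero samples is a hard error; a sample with fewer callers
  than `min_callers` is warned about, not silently dropped.
* Problem sizes in the validation suite: 50 random merge instances of
  ≤ 500 calls against the brute-force oracle, 20 random impact instances
  of 200 genes × 100 CNVs against the all-pairs oracle, 10 default-noise
  cohort simulations for recovery, 200 null batches for ORA type-I
  control. These sizes give stable statistics while keeping the suite
  fast.

## Known limitations

* Gene-level granularity only; no exon/transcript awareness and no
  dosage-sensitivity weighting.
* Exclusivity is a presence/absence contrast, not a burden test; no
  significance is attached to case-exclusive counts.
* The carrier-frequency rule needs cohorts of ≳ 20 samples to be
  meaningful — below that, even private events exceed 5%.
* The curated-target fixtures cover the packaged tables only; genome-scale
  target mapping requires a user-supplied LncTarD download.
* The ICD subtype ranges are a reconstruction; studies with different
  coding practice should edit the YAML map.
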