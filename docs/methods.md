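# Methods

This note documents the statistical model behind `regiongsea`, the
choices made where the procedure is underdetermined, what the synthetic
generator does and does not emulate, and known limitations.

## Study design and data model

The pipeline analyses a normalised, log-scale expression matrix (probes
or genes × samples) with each sample annotated by clinical group
(A = uninfected controls; B = HIV without neurocognitive impairment;
C = HIV with NCI, no encephalitis; D = HIV with NCI and encephalitis)
and brain region (WM = white matter, FC = frontal cortex, BG = basal
ganglia). Upstream array QC and normalisation are out of scope; the
package starts from the normalised matrix. The default comparison
design covers the disease transitions B−A, C−A, C−B, D−B and D−C, each
run independently per region. Contrasts are named "test−ref": the
first-named group is the test group and a positive metric/NES means
higher expression in it.

### Probe collapse

When the matrix is probe-level, one representative probe per gene is
kept: the probe with the highest coefficient of variation across all
samples, CV = sd/mean with the sample (n−1) standard deviation. CV is
computed on the values as given (the pipeline never sees linear-scale
data). Ties take the lexicographically smallest probe id, making the
argmax deterministic. Zero-mean probes (|mean| < 1e−12) with positive
sd get CV = +∞ and are used only when no probe of that gene has a
finite CV; a gene whose probes are all constant at zero mean has no
defined CV and is an error. These cases cannot occur on positive
log-intensity data but make behaviour on centred inputs well defined.

### Region marker sanity check

WM and FC samples can be cross-checked against a neuronal marker
(RBFOX3) and an oligodendrocyte marker (MBP): a WM sample whose
z(RBFOX3) − z(MBP) exceeds a threshold (default 1.0 z-unit) looks
cortical and is flagged, and symmetrically for FC. The flag list is
advisory — exclusion is the caller's decision — and the threshold is a
configuration knob, since no principled cut exists; BG samples are
never flagged.

## Gene ranking

Per gene, a Welch two-sample t statistic S (test minus reference,
sample variances, Welch–Satterthwaite dof) and two-sided p-value feed
the ranking metric −1·sign(S)·log10(p). p-values are two-sided because
sign(S) already carries direction. Degenerate genes (both group
variances zero) get S = 0, p = 1 when the means agree and an infinite
statistic with p clamped to the smallest positive float otherwise; the
same clamp guards against p underflow generally. Metric ties are broken
by gene symbol ascending so ranked lists — and therefore enrichment
scores — are reproducible.

## Enrichment score

Walking the ranked list of N genes, members of a set (k genes)
increment the running sum by |metric|^w / N_R (N_R the sum of |metric|^w
over in-list members) and non-members decrement it by 1/(N−k). The ES
is the running-sum value of maximal absolute deviation from zero, so
ES ∈ [−1, 1] always. The weight exponent w defaults to 1 (the weighted
statistic of standard GSEA); w = 0 gives the classic unweighted
Kolmogorov–Smirnov-style form and is available everywhere. If every
in-list member has metric zero (N_R = 0), the set falls back to w = 0
with a warning rather than dividing by zero.

Tie handling at the peak: among positions attaining the maximum the
smallest index is taken for positive candidates, the largest for
negative candidates, and an exact cross-sign tie resolves positive.
Ties are measure-zero with weighted increments but the rules make the
unweighted form deterministic too. The leading edge is the set members
at or before the peak for ES > 0, at or after it for ES < 0.

The permutation engine evaluates the same statistic in a vectorised
closed form (running-sum extrema reconstructed from the sorted hit
positions) rather than walking all N positions; the test suite asserts
the two paths agree to 1e−12 and that both match an exhaustive
enumeration oracle and an independent pre-ranked GSEA implementation.

## Permutation null, NES, FDR

The null is phenotype permutation: sample group labels are shuffled
with group sizes preserved, the full Welch ranking is recomputed, and
every set is scored on each permuted list. The same shuffled label
vectors are shared by all sets, which preserves inter-gene correlation
in the null — the property that makes pathway-level inference valid on
co-expressed sets. The default is 1,000 shufflings (500 in the test
suite's simulations to keep runtimes short). When fewer distinct label
assignments exist than requested (e.g. 3 vs 3 gives C(6,3) = 20), all
distinct assignments are enumerated instead, identity included; in
sampled mode the identity permutation is allowed, as in standard GSEA.
A single seeded generator drives each run; per-contrast × region child
seeds are derived as SeedSequence([seed, contrast_idx, region_idx]) so
a multi-contrast run is reproducible and its parts independent.

NES = ES / mean(|same-sign null ES|), computed per set. The nominal p
is the same-sign tail fraction, floored at 1/(n_perm+1) to avoid
claiming p = 0 from finite permutations. If no same-sign null value
exists, NES is reported as a signed infinity sentinel at the p floor.
The FDR q of a set with NES* ≥ 0 is the ratio of the tail fraction of
the pooled null NES (all sets × permutations, each permutation ES
normalised by its own set's same-sign null mean) to the tail fraction
of the observed NES, clipped to [0, 1] and mirrored for negative NES*.
Within each sign, q is made non-increasing in |NES| by a running
minimum taken from the least extreme set toward the most extreme, so a
more enriched set is never reported as less significant.

## Per-sample activity

Pathway activity in a sample is the same running-sum ES computed within
that sample: genes are first z-transformed across samples (population
sd, so each row is exactly mean 0, sd 1; constant genes are dropped
with a warning), then ranked within each sample by z-value, and the set
is scored with |z|^w hit weights. The weight exponent defaults to 1 to
mirror the contrast-level engine; whether a weighted or unweighted form
is preferable per sample is genuinely open, so the exponent is exposed.
Within-sample ties are broken by gene symbol. The input gate (row means
within 1e−6 of 0, sd within 1e−6 of 1) exists because activity values
are only interpretable relative to the cohort used for standardisation.

## Cross-region consensus

Per contrast, a pathway is **common** when q < 0.01 in at least 2 of
the 3 regions and — by default — the qualifying regions' NES share one
sign ("concordant"); the shared sign is the call's direction, and the
concordance requirement can be disabled. A pathway is **specific** to a
region when q < 0.01 there and q > 0.25 in both other regions. The
inequalities are strict exactly as written: q = 0.01 never qualifies as
significant and q = 0.25 never qualifies as null. Common and specific
are mutually exclusive whenever fdr_in ≤ fdr_threshold ≤ fdr_out
(property-tested).

The leading-edge gene table pools, over all qualifying pathways, the
leading-edge genes from each region where the pathway qualified; each
gene is annotated with its per-region Welch p, retained when p < 0.01
in at least one qualifying region, and sorted by its best qualifying p.
Pooling across regions (rather than testing one pooled contrast) was
chosen because the per-region rankings are the objects the calls are
made from.

## Synthetic generator

`generate_dataset` emulates the target design: configurable groups ×
regions × samples-per-cell (default 4 × 3 × 8, mirroring small
post-mortem cohort cells), Gaussian log-scale expression with baseline
7.0 and noise sd 1.0 (typical of normalised log2 array intensities),
disjoint gene sets, and within-set correlation rho (default 0.1, a
modest co-expression level) induced by a single shared standard-normal
factor per set per sample. The correlation matters: the phenotype
permutation exists precisely to stay calibrated under inter-gene
correlation, so the generator must produce it. Injections add
delta × noise_sd × direction to all genes of one set in one group ×
region cell. Probes replicate their gene with independent noise (sd
0.2 × noise_sd); with ≥ 2 probes per gene, one randomly chosen probe
gets triple noise so the CV collapse has a non-trivial argmax (with a
single probe there is nothing to choose, so no inflation).

What the generator does **not** emulate: heavy-tailed or skewed
expression, batch effects, missing values, dispersion (variance)
changes under disease, overlapping gene sets, sample-size imbalance
between cells, and probe-level saturation. Passing the recovery tests
therefore demonstrates correctness and calibration of the machinery
under a faithful null and clean mean-shift alternatives — not
robustness to every artefact of real array data.

## Simulation sizes used by tests and the acceptance script

Null calibration uses 2000 genes, 100 disjoint sets of 15, a 10 vs 10
contrast and 500 shufflings over 20 replicate seeds (5 in the
acceptance script); shift recovery uses 1.5-SD injections into sets of
50/2000 genes at 10 vs 10, 500 shufflings, 10 seeds. These sizes give
stable pass/fail behaviour while keeping a full run in minutes on one
CPU. At the generator's default 8 samples per cell a 1.5-SD injection
sits near the q < 0.01 boundary — single-region specific calls at that
size are genuinely borderline, which the full-design summary of the
acceptance script reflects.

## Known limitations

- Gene identity is exact, case-sensitive symbol match; alias resolution
  is upstream.
- No moderated/shrinkage t statistics and no covariate adjustment; with
  2–3 samples per group the Welch test is valid but weak.
- Gene-set permutation is not offered as an inference path (phenotype
  permutation is the point of the design); sets larger than the
  configurable cap are simply dropped, not split.
- FDR q-values are the GSEA ratio estimator, which is conservative or
  anti-conservative in small collections; with very few sets the pooled
  null is grainy.
- The per-sample activity score is relative to the cohort in the
  matrix: scores are not comparable across separately standardised
  datasets.
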