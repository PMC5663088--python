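# Methods

This note documents the statistical model behind `comapper`, the default
parameters and the reasoning behind them, the scope of the built-in data
generator, the numerical choices made in the implementation, and known
limitations. Nothing here is an empirical claim beyond what the test suite
and `scripts/acceptance.py` compute.

## 1. Genetic model

**Design.** A pseudo-testcross: parent 1 is heterozygous at every analysed
SNV, parent 2 homozygous reference. Parent 1's two haplotypes carry
complementary alleles at each SNV, so an offspring's genotype (hom-ref vs
het) identifies the inherited parental haplotype. Crossovers in parent 1's
meioses appear as switches of the inherited haplotype along a chromosome.
Genotype codes throughout: `0` hom-ref, `1` het, `2` hom-alt, `-1` missing.

**Read model at low coverage.** With sequencing depth *d* ~ Poisson(*c*) at
a site and per-read error *e*:

- at a truly heterozygous site, each read shows the ALT allele with
  probability 1/2 (read errors flip symmetrically and are absorbed into the
  1/2 at realistic *e*); observing zero ALT reads in *d* draws yields a
  *wrong hom-ref call* with probability 2^−d — the dominant artifact at 2×;
- at a truly hom-ref site each read errs to ALT with probability *e*;
  a mixture of alleles is called het, and all-reads-ALT yields a spurious
  hom-alt call with probability *e*^d.

Conditioning on at least one read and 1:1 segregation, the spurious hom-alt
rate has the closed form

    E_T = 1/2 · (e^{c(e−1)} − e^{−c}) / (1 − e^{−c}),

implemented as `simdata.expected_homalt_rate` and verified against
simulation in the test suite. In a testcross hom-alt calls are impossible
without error, so their empirical frequency after filtering estimates the
genotyping error rate E_T used by the window caller.

## 2. Pipeline stages and parameters

### 2.1 Filter cascade (`variants.run_cascade`)

Fixed order: repeat mask → segregation test → LD filter → depth floor →
missingness cap → hom-alt conversion.

- **Repeat mask** — sites whose position falls in a supplied BED interval
  are dropped (0-based half-open convention everywhere).
- **Segregation test** — per site, a 1-df chi-square of hom-ref vs
  het(+hom-alt) call counts against a null ratio, Benjamini–Hochberg
  corrected at FDR 0.05. Hom-alt calls are pooled with het because under the
  testcross model they are het mis-calls. The null ratio is configurable:
  `"1:1"` is the Mendelian expectation for error-free calls; the default in
  `run_cascade` is `"auto"`, which estimates the genome-wide mean hom-ref
  call fraction and tests each site against it. The reason: one-sided allele
  dropout at 2× coverage shifts *raw call* ratios genome-wide (to roughly
  0.63:0.37 at c=2), so a literal 1:1 null would flag nearly every site even
  though segregation of the underlying haplotypes is perfectly Mendelian;
  biological distortion then manifests as *local* deviation from the
  genome-wide ratio, which is what the auto null detects.
- **LD filter** — for each site, up to 25 partner sites are sampled on the
  same chromosome within a distance band and the median pairwise r²
  (squared Pearson correlation of allele indicators, pairwise-complete over
  individuals, ≥10 shared observations) must reach 0.2. The band's physical
  limits should match the genetic scale of the data: for the default
  simulated study (5-Mb chromosomes at ~100 cM each) the shipped
  configuration uses 1–100 kb (≈ 2 cM); on genomes with ~100 cM per tens of
  Mb a correspondingly wider band is appropriate. Partnerless sites are
  retained and flagged rather than silently dropped.
- **Depth floor** — hom-ref calls with depth < 2 become missing: a single
  reference read cannot distinguish hom-ref from het-with-dropout.
- **Missingness cap** — sites missing in more than 40% of individuals are
  removed.
- **Hom-alt conversion** — remaining hom-alt calls are recoded het; their
  pre-conversion fraction among non-missing calls is E_T.

### 2.2 Phasing (`phasing.phase`)

The first SNV of each chromosome is oriented arbitrarily (ALT on
haplotype 1). Each subsequent SNV is compared against the already-phased
SNVs in the trailing window of 99 (window 100, shift 1); the partner with
the highest r² decides the orientation via the sign of the allele
covariance. The result is defined up to a global flip per chromosome; all
downstream quantities (crossovers, maps) are invariant under it, which the
tests verify. The phasing switch-error rate on error-free simulations is
exactly 0, and < 1% at 4× with 1% read error.

### 2.3 Bayesian window calling (`window_caller`)

For one individual and a window of *n* non-missing haplotype labels with *k*
discordant from haplotype 1:

    P(k | hap1) = C(n, k) · E_T^k (1 − E_T)^{n−k}
    P(k | hap2) = C(n, n−k) · E_T^{n−k} (1 − E_T)^k

With flat prior 1/2 each, the posterior of hap1 is L1/(L1+L2) and the call
is the argmax. Defaults: window 50 SNVs, step 5, at least 5 non-missing
labels (else missing). Exactly symmetric evidence (k = n/2) carries no
information and is called missing. Windows advance in SNV index space; a
final window is always placed flush with the chromosome end so the tail is
covered. Likelihoods are computed in log space with a stable softmax;
brute-force Bayes equivalence is tested to 1e-12 across an (n, k, E_T) grid.

Adjacent windows with identical cross-individual call vectors merge into
**skeleton bins**; per-individual missing calls are bridged by the last
confident call (flagged) so low-coverage windows do not fragment bins.

### 2.4 Crossover detection and localization (`crossover`)

A candidate is an individual whose call differs between adjacent bins.
Within the two flanking bins, the individual's SNV labels are fit by
logistic regression on position (L2 ridge 1e-4 to tame perfect separation;
positions standardized internally and coefficients de-standardized). Since
a crossover can only fall between adjacent SNVs, the crossover probability
of an SNV pair is |Δ fitted probability|; starting from the maximal pair the
interval grows toward whichever side raises the endpoint-pair probability,
stopping above the 0.95 threshold. If the threshold is unreachable the
event is flagged `low_confidence` and reported with the widest candidate
pair — it is still counted and its interval still contains the breakpoint
in simulation. Resolution = interval width in bp. Tables from several
populations can be concatenated and filtered to fine events
(resolution < 5 kb) by `merge_fine`.

### 2.5 Genetic maps (`recomb_map`)

Each window is a marker at its physical midpoint. The recombination
fraction r between adjacent markers is the fraction of informative
individuals whose (per-individual forward-filled) calls differ; forward
filling bridges windows where an individual is missing or tied so one
haplotype switch is counted exactly once. Map functions: Haldane
d = −50 ln(1 − 2r) (default, no interference) or Kosambi
d = 25 ln((1+2r)/(1−2r)); r is clipped just below 0.5. The Marey map
(cumulative cM vs bp) is interpolated with a cubic spline — the
*interpolating* spline by default, which conserves total map length exactly
up to clipping of negative wiggles to zero; a smoothing-spline knob is
exposed. Rates are reported as cM/Mb on fixed 100-kb windows. Chromosomes
with < 4 markers fall back to linear interpolation.

### 2.6 Enrichment statistics (`enrichment`)

- Overlap counting uses ≥1-bp overlap on 0-based half-open intervals; a
  query touching several feature classes counts toward each.
- Shuffle Monte-Carlo re-places each query uniformly on its own chromosome,
  length preserved (default 10,000 permutations); empirical p-values use
  the add-one estimator (1+r)/(1+N), bounded below by 1/(N+1).
- Matched **cold regions**: per crossover interval, a control of identical
  length on the same chromosome, 10 kb–1 Mb away from any crossover, with
  GC and SNV density within 10% (relative) — rejection-sampled, failing
  loudly with the most-violated criterion named; an independent validator
  re-checks every criterion.
- TE-family two-sided Fisher tests (crossovers vs cold regions, Bonferroni
  across families), metagene-style aggregate profiles (50 body bins, 10-bp
  flank bins to ±5 kb, strand-flipped, optional permutation band), Spearman
  correlations on shared bins, a Poisson goodness-of-fit of per-individual
  crossover counts (λ̂ = mean; categories 0/1/2/≥3), and a Poisson log-link
  GLM with sequential-deviance ANOVA and a reported Pearson overdispersion
  ratio.

## 3. Data generator: scope and defaults

The simulator is the package's only source of truth-labelled data and
defines its standard study conditions:

- genome: 12 chromosomes × 5 Mb (configurable);
- SNV density 1000/Mb (Poisson per chromosome, uniform positions);
- crossovers per chromosome per meiosis ~ Poisson(λ=1), positions from a
  mild symmetric U-shaped density u(x) = 0.5 + 1.5(2x−1)² (edge density 4×
  the centromeric minimum), standing in for the distal bias of crossover
  landscapes in large plant genomes; a uniform profile and custom curves
  are available;
- coverage 2×, per-read error 1%, optional i.i.d. missingness.

Recorded truth contains only *observable* crossovers: events outside the
terminal SNVs, or an even number of events within one inter-SNV gap, do not
change any marker and are excluded, keeping the invariant
"haplotype switches = recorded crossovers" exact. The annotation generator
places non-overlapping genes on a jittered grid with an exact
5'UTR | exon/intron | 3'UTR partition, 1-kb promoters/downstream regions,
Stowaway-like TEs (lognormal lengths, median 224 bp) with a configurable
promoter bias, and intergenic space ≥ 2 kb from genes. It is a geometric
fixture generator for exercising the enrichment statistics, not a model of
any real genome.

## 4. Numerical choices

- Posteriors in log space with max-subtraction; zero-likelihood degeneracy
  returns the prior with a warning.
- Interval arithmetic via sorted-array binary search
  (`#overlaps = #(t_start < q_end) − #(t_end ≤ q_start)`), oracle-tested
  against brute force.
- Signal tracks as step functions with prefix-sum integrals: interval
  integrals and means are O(log n) and exact.
- r² computations are pairwise-complete over missing data with explicit
  minimum-overlap guards; degenerate variances yield NaN, never silent 0.
- Logistic fits standardize positions to avoid overflow on Mb coordinates
  (scikit-learn L-BFGS, C = 1/ridge).
- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  identical seeds give byte-identical pipeline artifacts, checksummed in
  the run manifest.

## 5. Limitations

- **Chromosome-end losses.** Windowed calling cannot form a bin on both
  sides of a switch within ~1 window (50 SNVs) of a chromosome end; on the
  standard 5-Mb simulation ~3.5% of true crossovers are missed, almost all
  in these edge zones. A flush tail window mitigates but does not remove
  the effect; it shrinks with chromosome length and SNV density.
- **Noise-limited resolution at 2×.** Allele dropout leaves ~8% effective
  label noise at 2× coverage, flattening the logistic transition; a
  sizeable fraction of events cannot reach the 0.95 endpoint criterion and
  are flagged `low_confidence` with wide intervals. Containment is
  unaffected (the intervals still cover the true breakpoint in simulation);
  median resolution improves rapidly with coverage.
- **Map inflation by residual noise** is controlled, not zero: tiny
  spurious recombination fractions between adjacent markers accumulate; on
  the standard simulation the net bias of total map length is within a few
  percent.
- The Haldane function assumes no interference; Kosambi partially models
  it. The simulator itself draws interference-free (Poisson) crossovers.
- The segregation `"auto"` null assumes distortion is local. A genome where
  *most* sites are biologically distorted in the same direction would be
  indistinguishable from a calling artifact at this stage.
- `sample_cold_regions` is rejection sampling; in feature-dense or short
  genomes matching can fail, which is reported loudly rather than padded.
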