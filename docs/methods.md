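# Methods

This note documents the models implemented in `heartqtl`, the parameter
conventions, the numerical choices that affect results, and the limitations
we are aware of. Coordinates are 0-based half-open everywhere except the
VCF/GFF3 readers and writers, which convert to and from the native 1-based
conventions of those formats.

## 1. Synthetic cohort generator (`heartqtl.simulate`)

**Genome and markers.** A genome is a list of `(chromosome, length)` pairs.
Marker counts per chromosome are Poisson(`marker_density` × length) with
positions uniform and deduplicated; every marker is biallelic and
homozygous-divergent between the two founders (allele A = founder-A state,
allele B = the reference-strain state).

**F2 recombination.** Each F2 individual inherits two independent gametes per
chromosome. A gamete starts in a random founder phase and carries
Poisson(`crossover_rate`) crossovers placed uniformly along the chromosome —
no interference, consistent with the Haldane map function and with the
Markov assumption of the decoding HMM. Genotype dosage at any position is the
number of A-phase gametes (0, 1 or 2); the full truth (gamete phases and
breakpoints) is stored so downstream recovery can be scored exactly.

**Read sampling.** Depth at each individual × marker is
Poisson(`coverage`); default coverage is 0.78. Each read supports allele A
with probability `clamp(base + δ)` where base is 1 − e (AA), 0.5 (AB) or e
(BB), e is the per-read error rate and δ is a signed reference-bias shift
toward allele A. Bias is implemented in read sampling, not as post-hoc call
flipping, so it propagates mechanistically through windowing and decoding.

**Phenotypes.** Latent heart rate at temperature t is
`baseline(t) + Σ_q a_q(t)·dosage + d_q(t)·[het] + N(0, noise_sd)`. With
probability `arrhythmia_rate` an individual's recorded rate is latent/2 at
all temperatures (2:1 atrioventricular conduction block) and a truth flag is
set. An additive QTL explaining a fraction v of phenotypic variance uses
`a = sqrt(v/(1−v) · σ²/0.5)` since var(dosage) = 1/2 in an F2.

## 2. Windowed genotype HMM (`heartqtl.hmm`)

Allele counts are summed into fixed windows (default 5 kb, half-open;
a marker at position p belongs to window `p // window_size`). Each
chromosome of each individual is decoded by a three-state HMM over windows:

- **States** AA, AB, BB (encoded 0/1/2; dosage of A = 2 − state).
- **Emissions** Binomial: window A-count ~ Bin(depth, p_state) with
  p = (1 − e, 0.5, e) and HMM error e (default 0.02). Empty windows emit
  log-likelihood 0 (no information), so the path through them is governed by
  transitions only.
- **Initial distribution** the Mendelian prior (¼, ½, ¼).
- **Transitions** from the two-gamete structure with per-window
  recombination fraction r: AA→(AA, AB, BB) = ((1−r)², 2r(1−r), r²);
  AB→AB = (1−r)² + r², AB→AA = AB→BB = r(1−r). r is derived per chromosome
  as `crossover_rate × window_size / chrom_length` and clamped to ≥ 1e−9;
  r ≥ 0.5 is rejected.
- **Decoding** exact Viterbi, vectorised across individuals. Ties between
  predecessors are broken in favour of staying in the current state, so a
  tie never fabricates a crossover. The binomial coefficient is computed
  with `gammaln`, and `xlogy` handles the p = 0/1 corner cases exactly.

Crossovers are called at every state change between adjacent windows and
placed at the shared window boundary. A change of ±1 in dosage is a single
crossover; AA↔BB changes (distance 2) are flagged as double crossovers.

At 0.78× coverage, 1 marker/kb, 1% read error and n = 300 over 2 × 25 Mb,
decoding concordance with truth on constant-truth windows is ≈ 0.9999 and
the median distance from a true breakpoint to the nearest called crossover
is ≈ 2 kb — under half a window.

A note on resolution: a pair of true breakpoints of the same individual that
fall within one window of each other flips dosage up and back within a
single window and is invisible at window resolution. Recovery is therefore
scored against *resolvable* breakpoints (no same-individual neighbour within
one window, not within one window of a chromosome end).

A note on robustness: small reference bias (δ ≈ 0.1) shifts read counts
measurably but is almost entirely absorbed by the emission model — decoded
genotype frequencies barely move. Only larger bias (δ ≳ 0.2) leaks into the
calls as an AA excess, which is why the calibration tests assert read-level
monotonicity for any δ but call-level monotonicity across δ = 0, 0.2, 0.35.

## 3. Recombination blocks (`heartqtl.blocks`)

All called crossover positions are snapped to a grid (default 10 kb, round
to nearest multiple); the union of snapped positions per chromosome, plus the
chromosome ends, defines a cohort-wide tiling into blocks. A terminal
fragment shorter than the grid is merged into its left neighbour. Block ids
are `chrom:start-end`.

Within a block an individual's windows are constant by construction only
when the grid equals the window size. With the default grid (10 kb) over
5 kb windows a block can straddle one state change, so block genotypes are
assigned by majority vote over the covered windows (ties go to the first
window). A `strict` mode instead raises on any non-constant block; the
round-trip property (blocks re-expand to the exact window paths) is exact
and is asserted when grid = window size.

Per-block segregation diagnostics report the χ² statistic (df = 2) against
the Mendelian 1:2:1 expectation and the cohort mean AA-fraction excess over
0.25. Adjacent blocks share recombination history, so the per-block p-values
are not independent: uniformity under the null is checked on blocks thinned
to one per 2 Mb, which are effectively independent.

## 4. Mixed-model association (`heartqtl.assoc`)

**Phenotypes.** The three per-temperature heart rates, plus a variance
phenotype — by default the mean absolute pairwise difference of the three
measurements (range and sample-variance modes are available).

**Kinship.** K = ZZᵀ/m from column-standardised block dosages
(zero-variance blocks are skipped); mean diagonal ≈ 1.

**Model.** y = μ + x_b β + g + ε with g ~ N(0, σ²_g K), ε ~ N(0, σ²_e I);
h² = σ²_g/(σ²_g + σ²_e) is estimated once per phenotype by REML under the
null (grid search over 100 points refined by bounded scalar minimisation,
after a single eigendecomposition of K). Each block is then tested by GLS in
the whitened (rotated) space with per-sample weights d_i = h²·s_i + (1 − h²),
using the closed-form two-predictor solution vectorised over blocks; the
Wald t-test uses n − 2 degrees of freedom. At K = 0 this reduces exactly to
OLS simple regression (verified to 1e−8 against an independent
implementation), and results are invariant to jointly relabelling
individuals (1e−10).

**Permutation FDR.** The raw phenotype vector is permuted (the null
variance components are reused), the scan is recomputed for each of
`n_perm` permutations, and for each candidate −log10 p threshold t the FDR
is estimated as (mean permutation discoveries at t) / max(1, observed
discoveries at t). The reported threshold at level α is the most permissive
(largest-p) threshold whose estimated FDR is ≤ α, which guarantees
threshold(1%) ≥ threshold(5%). If no threshold qualifies, the threshold is
set above the best observed statistic so nothing passes.

Calibration under the study regime: with pure-noise phenotypes, no block
passes the 5% threshold in ~98% of replicates; a planted additive QTL
explaining 15% of variance is detected within 1 Mb in ~100% of replicates
(n = 300).

## 5. Fine-mapping and candidate ranking (`heartqtl.finemap`)

Blocks passing the per-phenotype FDR threshold (best p across phenotypes per
block) are collapsed greedily: the most significant remaining block seeds a
region and absorbs every significant block with dosage r² ≥ 0.5 to the lead
or within 500 kb on the same chromosome; absorption iterates to a fixpoint
for blocks falling inside the growing interval, and overlapping regions are
merged in a final pass. Region ids (`R000`, …) are assigned after sorting by
position. Regions are annotated with every gene whose interval overlaps the
region (any overlap, half-open semantics).

Candidate genes in regions with lead −log10 p strictly greater than 3 are
scored as

```
score = w1 · min(lead −log10 p, 10)
      + w2 · [DE: adjusted p < 0.01 and |fold change| ≥ 2]
      + w3 · [≥ 1 predicted loss-of-function variant]
```

with default weights (1, 1, 1); ties break by association strength, then
gene id. DE and LoF evidence are consumed as plain tables.

## 6. Determinism and numerics

- Every random draw flows from a single config seed; stages use fixed
  offsets (seed+1 … seed+6) and no stage touches the wall clock.
  Derived seeds are always < 2³¹.
- All artifacts are text (TSV/BED/GFF3/VCF/JSON); floats are written with
  10 significant digits (`%.10g`). Reruns with identical configs produce
  byte-identical files; the pipeline manifest records SHA-256 hashes.
- p-values are clipped to [1e−300, 1] before taking logs; degenerate
  (zero-variance) predictors get p = 1 rather than NaN.

## 7. Limitations

- No crossover interference and uniform recombination rate along the
  chromosome; real genomes have hotspots.
- Per-marker depths are independent Poisson draws; no mapping artifacts,
  duplicated reads or copy-number structure.
- One variance component; no covariates (plate, batch) in the LMM.
- The HMM assumes known, homozygous-divergent markers; marker
  misclassification is only covered by the read-error parameter.
- LD clumping uses a fixed r²/distance rule, not conditional analysis, so a
  region can contain more than one causal variant.
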