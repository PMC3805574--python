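# Methods

## Problem and data model

We observe unphased genotypes `g_1..g_n` of `n` unrelated individuals at
`L` tightly linked biallelic SNPs (alleles coded 1/2). The SNPs are
assumed recombination-free within the block, so each chromosome carries
one of `H = 2^L` haplotypes. A genotype heterozygous at `s` SNPs is
compatible with `max(1, 2^(s−1))` unordered haplotype pairs; the observed
likelihood for a pair-probability model `P_φ` is

    l(φ) = Σ_i log Σ_j P_φ(z_ij),

the inner sum running over the compatible pairs `z_ij` of individual `i`.

Three models for the unordered pair `{h_k, h_l}` are implemented
(`haphwe.models`): HWE (`p_k²` / `2 p_k p_l`), Niu's model
(`θ p_k²/C` / `2 p_k p_l/C`, `C = 1 + (θ−1) Σ p_h²`) and the inbreeding
model (`f p_k + (1−f) p_k²` / `(1−f) 2 p_k p_l`). Both alternatives
inflate total homozygosity relative to HWE, which is the alternative the
two likelihood-ratio tests are aimed at. The normalizer closed form
`C = 1 + (θ−1)S` is verified against the explicit sum over all unordered
pairs in the test suite.

## Fitting algorithms

All three fitters start from the uniform distribution over the `H₀`
haplotypes appearing in at least one compatible pair of the sample (all
other haplotypes have MLE 0 under all three models, since they enter no
likelihood term), with `θ₀ = 1` and `f₀ = 0.01`, and stop when the
observed log-likelihood changes by less than `tol` (default `1e-6`,
configurable) or after `max_iter = 1000` iterations (non-convergence is
flagged on the result, not raised).

**EM under HWE** is plain gene counting: posterior pair weights
`w_ij ∝ P(z_ij)`, then `p_h ← Σ_ij w_ij n_ij(h) / 2n` with `n_ij(h)` the
number of copies of `h` in pair `z_ij`.

**ECM under Niu's model** alternates one E-step with `H₀` conditional
maximizations of the Q-function. With `m = Σ_i Σ_{j hom} w_ij` the
expected number of haplotype-homozygous individuals and `S = Σ p_h²`,

    dQ/dθ = m/θ − nS/(1 + (θ−1)S) = 0  ⇒  θ = m(1−S) / (S(n−m)),

the first CM-step. The frequency CM-steps hold all but one free frequency
fixed; the designated absorbing haplotype (the one with the highest
expected frequency at initialization — a choice that keeps the absorbed
coordinate away from the zero boundary) carries the simplex constraint
`p_H = r − x`. Writing `A = Σ w n(h)`, `B = Σ w n(H)`,
`D = θ−1`, `K = 1 + D(r² + S_rest)`, the stationarity condition
`A/x − B/(r−x) − 2nD(2x−r)/(K + 2Dx² − 2Drx) = 0` clears to the cubic

    2D(2n−A−B) x³ + 2Dr(2A+B−3n) x² + [−K(A+B) + 2Dr²(n−A)] x + ArK = 0.

The update evaluates Q at every real root in `[0, r]` (boundaries are
admissible only when the corresponding log coefficient vanishes), takes
the maximizer, and breaks near-ties toward the previous value; a bounded
1-D numeric maximization backs the cubic up if no root improves Q. Both
the θ formula and the cubic step are validated against independent
numeric/grid maximizers in the test suite (agreement to 1e-6). At `θ = 1`
the cubic degenerates to the gene-counting split `x = rA/(A+B)`.

**IEM under the inbreeding model** augments the pair indicator with a
Bernoulli(f) identity-by-descent (IBD) latent variable per individual.
For a homozygous pair `(k,k)` the posterior IBD probability is
`b = f p_k / (f p_k + (1−f) p_k²)`; heterozygous pairs have `b = 0`. The
M-step follows from the complete-data likelihood: `f ← (1/n) Σ w b`, and
haplotype counts weight an IBD individual as a *single* draw of its shared
haplotype (contribution `w(2−b)` to `h_k` for homozygous pairs, `w` to
each haplotype otherwise), normalized by the total expected number of
draws `2n − Σ w b`. With `f` started (or driven) to 0 the update is
exactly the HWE EM, which the tests assert as a fixed point. `f` is
clipped to `[0, 1−1e-9]` and `θ` to `[1e-6, 1e3]`; clips are flagged.

θ is deliberately *not* truncated at 1: under null data the estimator
scatters on both sides of 1 (the null mean near 1 with symmetric spread
depends on this), whereas `f ≥ 0` is a hard model constraint.

All expectation sums are computed over distinct genotype classes with
multiplicities (at most `3^L` classes) rather than per individual — an
exactness-preserving rearrangement that makes a full fit on `n = 1000`
take milliseconds and the replicate studies feasible.

## The tests

`LRT_NM` and `LRT_IM` are `2(l_alt − l_HWE)`, clamped at 0 and referred
to χ²₁, following the original proposal. For `LRT_IM` the null value
`f = 0` lies on the boundary, so the χ²₁ reference is conservative (the
asymptotic null is the mixture `½χ²₀ + ½χ²₁`); the conservatism is a
documented property of the published test and is reproduced here, with
`mixture=True` available as an off-by-default option for the more
accurate reference. Because fits stop at a finite tolerance, the
alternative's log-likelihood may end a few tolerances below the null's
when the truth is at the boundary; differences above `−1e-2` are treated
as a zero statistic and anything lower is raised as a fitting failure.

## Simulation engine and study conditions

`haphwe.simulate` draws each individual's unordered haplotype pair
*exactly* from the model's pair distribution (enumerated over the support;
no rejection sampling) and emits the induced genotype. The generating
conditions are fixed study constants: a 5-haplotype distribution over 3
SNPs (`122: .082, 221: .525, 121: .283, 211: .004, 111: .106`,
homozygosity `S = 0.37369`) for the HWE/NM/IM conditions, and a
two-subpopulation stratification model with 7-haplotype subpopulation
distributions mixed with proportion λ (HWE within each subpopulation).
Study grids: θ from 1.0 to 1.5 in steps of 0.05, f from 0 to 0.1 in steps
of 0.01, λ ∈ {0.6, 0.8}, n ∈ {500, 1000, 1500}, 1000 replicates, α = 5%.

Estimation accuracy is the sum of absolute differences
`SAD = Σ_h |p_h − p̂_h|` over the union of the true and estimated
supports, with no ½ factor: under HWE at `n = 1000` the asymptotic
expected SAD of the EM estimate for the study distribution is ≈ 0.029,
matching the published scale, while a ½-scaled definition would predict
half that. Zero-truth haplotypes that receive estimated mass count fully.

Randomness is driven by one master seed; each replicate gets a
deterministically spawned child seed, so any study row is bit-reproducible
from its seed.

What the generator does *not* emulate: genotyping error, missingness,
linkage-disequilibrium decay or recombination within blocks, relatedness
beyond the IBD model, and more than two subpopulations. Passing the
reproduction tests therefore demonstrates correctness of the estimators
and tests under the stated models, not robustness to real-data artifacts
(real blocks with heavy missingness lose individuals to the complete-case
rule below).

## Pedigree input and block-wise analysis

`haphwe.io` reads standard 6-column linkage PED files (whitespace
delimited, missing allele token "0"), keeps founders only (both parent
ids "0"), and analyzes haplotype blocks one by one from a block file (one
block of SNP names or 1-based indices per line). Arbitrary allele labels
are mapped to {1, 2} per SNP in order of first appearance, and the
mapping is reported so results are label-stable (both tests are invariant
to allele relabeling). Within a block, individuals missing any in-block
genotype are excluded — a complete-case policy chosen over imputation to
avoid inflating the compatible-pair count; exclusion counts are reported.
Blocks with fewer than `min_individuals` (default 20) usable founders are
skipped with a reason. Bonferroni adjustment across blocks is applied to
the significance flags (configurable, on by default). Output is a
human-readable `results.txt` (convergence summary, per-algorithm
haplotype frequencies above a reporting threshold of `1e-3`, θ̂ and f̂
with test statistics and P values) plus a `.tsv` sidecar holding the same
numbers at full precision.

## Problem sizes used in the shipped checks

The pytest reproduction suite uses 500 replicates per study condition
(Monte-Carlo tolerances widened to 3 standard errors at that count);
`scripts/acceptance.py` runs the full 1000 replicates of each headline
condition at `n = 1000`. Property tests run on small random instances
(up to 4 SNPs, n ≤ 50–400) where independent grid/numeric oracles are
affordable.

## Known limitations

* No standard errors for `p̂` (no Louis-type supplemented EM) and no
  per-individual phase calls.
* The χ²₁ reference for `LRT_IM` is conservative by construction; use
  `mixture=True` when calibrated size matters more than comparability.
* Very rare haplotypes can converge slowly near the simplex boundary;
  the iteration cap flags, rather than hides, such cases.
* PED parsing assumes biallelic SNPs; multiallelic markers are rejected.
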