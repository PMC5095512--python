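# Methods

## Observation model

Each biallelic site is treated as an independent coin: a variant with
population alternate-allele frequency `x` appears in `i` of `k` sampled
alleles with probability `bin(x, k, i)`, the Binomial(k, x) pmf. The data
reduce to the site-frequency spectrum `{F_i}` (variants seen in exactly `i`
alleles, `1 ≤ i ≤ k`); `F_0` — the unseen variants — is the inferential
target. The frequency histogram `h(x)` is stored as an *unnormalised variant
count* per grid frequency, not a fraction of variants: the expected SFS
`E[F_i] = Σ_x h(x)·bin(x,k,i)` and the discovery curve
`U(N) = Σ_x h(x)·(1−(1−x)^N)` then need no separate total-variant symbol.
The two conventions are mathematically equivalent (divide by `T = Σ h` to
get fractions).

Numerics: `1−(1−x)^N` is computed as `-expm1(N·log1p(−x))` so that
frequencies down to 1e-9 lose no precision; the binomial kernel switches to
the Poisson(k·x) pmf when `k > 10,000` and `k·x ≤ 10` (entrywise), which
agrees with the exact binomial to better than 1e-3 absolute in that regime
and stays stable at biobank-scale `k`.

## The linear programme

Stage 1 minimises the weighted L1 discrepancy
`Σ_{i=1..i_fit} w_i·|E[F_i] − F_i|` over non-negative grid masses, with
absolute values linearised through auxiliary variables and solved by HiGHS
(`scipy.optimize.linprog`). Defaults and why:

- **Grid**: geometric, ratio 1.05 (uniform relative resolution), from
  `x_min = 1/(r·k)` with `r = 50` — unseen variants must be representable
  well below `1/k`, and `r` bounds the extrapolation factor the grid can
  support — up to `x_max = i_fit/k`. The upper cap matters: columns with
  `x ≫ i_fit/k` have `bin(x,k,i) ≈ 0` for every fitted row, so the solver
  could park arbitrary mass on them without affecting the objective,
  which corrupts the mass-minimisation stage below. Variants above the cap
  are represented empirically instead (next paragraph).
- **Fitted range** `i_fit = min(k, 50)`: a count of 50+ pins a variant's
  frequency to a few percent relative, so those variants are carried as an
  empirical "frequent part" at `x = i/k` with weight `F_i`. Their leakage
  into the fitted rows (`E[F_{i≤i_fit}]` from frequencies near the cap) is
  subtracted from the observed counts before solving.
- **Weights** `w_i = 1/√(1+F_i)`: Poisson-scale variance stabilisation —
  each count's noise is ∼√F_i, so this makes residuals comparable across
  `i`. Uniform weights are available for ablation.

Stage 2 resolves the remaining degeneracy — many rare-frequency tails
produce nearly identical expected spectra — by minimising the total mass
`T = Σ h(x)` subject to the discrepancy staying within a relative `slack`
(default 1e-6) of the stage-1 optimum plus a small absolute floor tied to
the solver's feasibility tolerance. Two consequences, both deliberate:

- the returned histogram is the *smallest* variant inventory consistent
  with the data — extrapolations are conservative by construction;
- the returned histogram is an exact stage-1 optimum up to numerical
  tolerance, so its discrepancy is provably no larger than that of any
  feasible histogram, including the generating truth when the truth lies on
  the grid. A larger slack (several percent) would break this certificate
  and is therefore not the default, although the knob exists.

If stage 2 fails numerically the stage-1 optimum is returned with a
warning. Masses within solver tolerance below zero are clipped to zero. An
optional `mass_cap` bounds `T` (used at gene level, where a genome-wide
gene count is a hard ceiling). An all-zero SFS yields the zero histogram
with a warning; `i_fit > k` is lowered to `k`.

## Uncertainty: allele partitions

No closed-form confidence intervals are attempted. The `k` alleles are
randomly divided into `G` disjoint groups (default 10; remainder alleles go
one-per-group to the first groups); each variant's count is split by a
multivariate hypergeometric draw with the group sizes as colours, so counts
are conserved exactly. Each group's SFS is fitted independently and the
standard deviation of the per-group predictions is the reported band. The
same machinery implements the validation protocol: train on one group (10%
of alleles), predict the full cohort's distinct count and SFS, compare with
the observed values.

## Jackknife baseline

The third-order jackknife predicts richness directly,
`U(N) = D + g₁(N,k)F₁ + g₂(N,k)F₂ + g₃(N,k)F₃`, without modelling `h`.
The coefficient functions are pluggable; the shipped default assumes the
accumulation curve is a cubic polynomial in `1/M` (sample size `M`) and
determines it from the exact finite-difference identities
`ΔU(k) = F₁/C(k,1)`, `Δ²U(k) = −F₂/C(k,2)`, `Δ³U(k) = F₃/C(k,3)`, which
hold in expectation for any frequency distribution. This reconstruction is
exact on curves that really are cubic in `1/M` and satisfies the
self-consistency requirement `g_m(k,k) = 0` by construction (predictions
at `N = k` return the observed `D` exactly; rules violating this are
rejected). The 4×4 system is solved in a `(k/M)^j` basis to keep entries
O(1); `k ≥ 4` is required. Only contract properties and the qualitative
direction of bias are asserted about this rule — the historical published
coefficient values are not reproduced here.

## Variant input and classes

Sites-only VCFs with per-population `AC_<pop>/AN_<pop>` INFO fields and
VEP-style `CSQ` annotations (format parsed from the header `Description`,
LOFTEE confidence as the `LoF` subfield) are read with cyvcf2. LoF means a
single-nucleotide substitution annotated `stop_gained`,
`splice_donor_variant` or `splice_acceptor_variant`; high-confidence (`HC`)
is required by default. Multi-allelic sites are split per alternate allele;
indels and non-SNV alleles are skipped and counted. Mutation classes follow
the purine/pyrimidine rule, with CpG transitions requiring the reference
trinucleotide context (supplied via a `CONTEXT` INFO tag in fixtures);
reverse-complement symmetry is honoured (G→A preceded by C is CpG).

Real call sets have per-site missingness, so AN varies while the SFS needs
one `k`. Policy: `k` is a configured nominal allele number (default the
modal AN of the selection); sites with `AN > k` are hypergeometrically
downsampled and sites with `AN < 0.8·k` are dropped, echoing the
at-least-80%-of-individuals coverage rule used by large exome releases.
Coverage masks are BED (0-based half-open) against VCF's 1-based positions;
the conversion is tested explicitly.

Census-matched cohorts downsample each ancestry group to
`round(weight·ploidy·total)` alleles and sum per-site counts across groups.
AC/AN downsampling is used rather than individual-level resampling — with
sites-only input no genotypes exist; for rare variants the two coincide in
distribution. The shipped demography weights are explicit placeholders.

## Gene-level LoF

A gene's LoF allele count is the *sum* of its sites' LoF counts, capped at
`k`: rare LoF alleles essentially never co-occur on one haplotype, and
sites-only data carries no phase, so the sum approximates the number of
carrying alleles; the cap guards the bookkeeping where it would overflow.
The same LP fitted to the gene SFS yields a histogram counting genes by LoF
allele frequency, binned by default at 10⁻⁵/10⁻⁴/10⁻³. Projections use
`Σ h(x)·P(Binomial(N, x) ≥ t)`; the threshold `t` counts *alleles*
(`N = 2 × individuals`) — "t individuals" and "t alleles" are conflated in
informal usage, and the allele convention is the one computed here. At
`t = 1` the projection reduces exactly to the discovery curve (same code
path, same stable formula).

## Synthetic study conditions

The generator defines the conditions everything is tested under:

- `neutral_like`: density ∝ 1/x (the constant-size coalescent shape),
  integrated per geometric grid cell over (1e-5, 1], standing in for
  synonymous-like variation. The reference condition uses T = 50,000
  variants at k = 2,000 alleles.
- `lof_like`: Beta(0.5, 5000) discretised onto the same grid — mean
  frequency 1e-4 with the bulk of variants below 1e-3, standing in for
  strongly deleterious variation that segregates rarely.
- `pointmass` and `mixture` for exact algebraic checks.

Histogram masses are rounded to whole variants (largest-remainder, total
preserved); each variant's count is one Binomial(k, x) draw from a single
seeded generator, so identical scenario + seed reproduces cohorts and
fixture VCFs byte-for-byte. Fixture VCFs carry exact class quotas
(consequence, Ti/Tv/CpG, LOFTEE HC/LC) and per-population counts drawn
multivariate-hypergeometrically so population counts always sum back to the
pooled count.

What the simulations do *not* emulate: linkage between sites, genotype- and
coverage-level artefacts, population substructure beyond fixed per-group
allele pools, insertions/deletions, and frequency–consequence correlation
(annotations are assigned independently of frequency). Passing tests
therefore demonstrate the estimator's statistical behaviour under the
stated sampling model, not robustness to call-set artefacts.

## Measured behaviour and limitations

At the reference condition, training on 10% of the alleles and predicting
the full cohort's distinct count is accurate to a few percent (the
acceptance script recomputes this each run); a single 5%-allele subsample
has ~25% prediction SD, so 20× extrapolation is assessed by the mean over
all 20 disjoint partitions. On the rare-skewed condition the jackknife
underestimates 10×-extrapolated richness by ~25-30% while the LP stays
substantially closer — but LP errors of ±15% across realisations show that
deep extrapolation from modest cohorts remains noisy. The smallest-
consistent-inventory rule means totals `T` are best read as lower-bound
flavoured estimates; discovery-curve values at moderate extrapolation are
much better determined than `T` itself. Extrapolation beyond the grid's
design factor (`r = 50`) is unsupported, and folded/minor-allele spectra
are out of scope (counts must be alternate-allele counts).
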