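# Methods

## Finite-lattice binding isotherm

The core model treats nonspecific binding as large-ligand adsorption on a
one-dimensional lattice: a protein occludes `n` base pairs of a duplex of
`N` base pairs, with association constant `Ka` (per molar) and no
cooperativity. The McGhee–von Hippel closed form accounts for the
overlap-exclusion entropy of the infinite lattice; the finite-lattice end
correction multiplies the right-hand side by `(N − n + 1)/N`, the fraction of
start positions available to an `n`-mer on a short duplex:

```
v/L = Ka (1 − nv) [(1 − nv)/(1 − (n−1)v)]^(n−1) (N − n + 1)/N
```

Assumptions: equilibrium, one ligand class, no cooperativity (ω = 1), and
free concentration `L` equal to the injected concentration (the protein is in
vast excess over immobilized DNA, so ligand depletion is negligible; no
correction is applied).

**Inversion.** `v(L)` is the unique root of `g(v) = L·rhs(v) − v` on
`[0, 1/n)`. Because `rhs` is strictly decreasing and `g(0) ≥ 0`, bisection on
`[0, (1/n)(1 − 1e−12)]` is guaranteed to converge; 80 iterations drive the
bracket below float64 resolution (interval ≤ 2⁻⁸⁰/n). The solver is
vectorized over `L`, which keeps grid fitting fast without changing results.

**Exact oracle.** For `N ≤ 400` the grand partition function is enumerated
exactly: `c_k = C(N − kn + k, k)` ways to place `k` non-overlapping `n`-mers,
`v = (1/N) Σ k c_k x^k / Σ c_k x^k` with `x = Ka·L`. Binomials are exact
Python integers; the sums are evaluated in log space to avoid overflow at
large `x`. The closed form is *exact* at `n = 1` (it reduces to the Langmuir
isotherm for every `N`) and an approximation otherwise.

**Accuracy of the end correction.** The absolute deviation between the
closed form and the oracle is a few ×10⁻³ in `v` at `N ≈ 4n`, decays roughly
as `1/N`, and is below 3.5×10⁻⁴ by `N = 60n`. Two non-asymptotic quirks are
worth knowing: the signed error can cross zero on very short lattices (the
deviation happens to vanish at `N = 2n` for `n = 2`, `Ka·L = 1`, while it is
~6.5×10⁻³ at `N = 6`, `n = 3`), and near saturation the |error| is not
monotone in `N` below roughly `N ≈ 8n` — it peaks before entering the `1/N`
regime. Convergence tests therefore sample commensurate lattices
`N = n·{8, 16, 32, 60}`, past the peak.

## SPR response transform and equilibrium fitting

Protein and DNA have similar refractive-index increments, so the equilibrium
response relative to the immobilization response approximates the
bound-protein/immobilized-DNA mass ratio:

```
v = M_DNA / (N · M_protein) · R_eq / R_L
```

`density_to_response` is its algebraic inverse; the pair round-trips to
machine precision.

Fitting minimizes `Σ (v_obs − v_model)²` over `log10 Ka ∈ [0, 12]` with
L-BFGS-B, seeded from a 25-point coarse grid scan of the same interval (the
objective is smooth but can be flat at extreme `Ka`; the scan makes the
polish step reliable). This is repeated for each integer candidate site size
(default grid 1–10 bp, spanning plausible small-domain footprints with
margin), and the candidate with the smallest residual sum of squares wins;
exact ties go to the smaller `n` (parsimony). Reported diagnostics per
candidate: `Ka`, `Kd`, a linearized standard error of `Kd` (from the
finite-difference Jacobian of the model densities with respect to `Ka`,
`σ² = rss/(m−1)`), `rss`, and the standard error of regression
`s_reg = sqrt(rss/(m−1))` with `m` data points and one fitted parameter.
Both `rss` and `s_reg` are reported so model selection is reproducible under
either divisor convention. Negative double-referenced responses are retained
unclamped for fitting (clamping would bias least squares); density *reports*
clamp at zero. At least 4 distinct concentrations are required — below that
the (n, Kd) pair is badly underdetermined.

## Segment screening statistics

Screens probe a genome region tiled into overlapping duplex segments
(default 30-bp windows stepping 25 bp; positions are 0-based offsets signed
relative to the first base of the small-terminase start codon) at a single
protein concentration. Per cycle, replicate responses are normalized to that
cycle's annealed-DNA response through the mass-ratio transform and scaled by
the duplex length to give proteins per DNA; a per-bp density is also reported
for comparing segments of different length.

*Drift correction*: a standard duplex re-measured at intervals defines a
multiplicative correction `grand_mean(standard)/nearest_standard`; the
nearest occurrence is chosen by cycle index, so standards themselves map to
their grand mean. *ANOVA*: standard fixed-effects one-way ANOVA on replicate
densities (or per-cycle means via a flag, for designs where replicates share
cycle-level systematics); groups with one observation are excluded. *Tukey
HSD*: studentized-range critical values computed from the distribution at
the requested α (default 0.05), Tukey–Kramer correction for unequal group
sizes (via `scipy.stats.tukey_hsd`). *Enhanced-site flagging*: segments with
mean density strictly above the grand mean + 1 sample SD over segment means.

## AUC stoichiometry

Molar mass follows from the Svedberg relation with the Stokes friction of
the equivalent anhydrous sphere scaled by the frictional ratio:

```
M(1 − v̄ρ) = s · N_A · f,   f = (f/f₀) · 6πη · (3Mv̄ / 4πN_A)^(1/3)
⇒ M = [ s N_A (f/f₀) 6πη (3v̄/4πN_A)^(1/3) / (1 − v̄ρ) ]^(3/2)
```

in CGS units. Solvent constants default to pure water at 20 °C
(η = 1.002×10⁻² g cm⁻¹ s⁻¹, ρ = 0.99823 g/cm³) because s₂₀,w is by
definition standardized to those conditions. Defaults v̄ = 0.73 cm³/g
(protein, configurable) and 0.56 cm³/g (duplex DNA); fluorophore label mass
is folded into the DNA mass by the caller.

For complex stoichiometry, the v̄ of the complex depends on the composition
being inferred. Candidate bound states k = 0..k_max therefore each get the
mass-weighted v̄ `Σ M_i v̄_i / Σ M_i` of their own composition; when the
measurement is an (s₂₀,w, f/f₀) pair, the measured mass is recomputed per k
with that v̄ before ranking by `|M_measured − M_predicted|`. Site size is
bounded from the duplex length: a saturated duplex seen with k_low..k_high
proteins bounds it to `[⌈N/k_high⌉, ⌊N/k_low⌋]` bp; an unsaturated complex
gives only the upper bound `⌊N/k⌋`.

## Chemical-shift perturbation

Combined differences `√(ΔδH² + (α ΔδN)²)` with α = 0.20 for glycine and
0.14 otherwise. Endpoint differencing (final titration point minus free
state) is used rather than per-step tracking, matching how fast-exchange
titrations are usually summarized; residues missing at either end are marked
unassigned. The significance threshold is the mean + 1 *sample* (n−1)
standard deviation over assigned, non-proline residues — the SD convention
is recorded in the output metadata since the population convention differs
by a few percent at typical counts; the comparison is strict, so the
degenerate all-equal case flags nothing.

## Synthetic data

Generators are pure functions of a `SimConfig` (seed + design + noise);
per-generator streams are derived as `default_rng([seed, stream_id])` so
adding one generator call never perturbs another's output. At zero noise
every generator reduces exactly to the forward model of its consuming
analysis.

Default conditions: SPR panels use 16 two-fold dilutions from 1500 µM
(lowest ~0.046 µM) in triplicate with additive SD 1 RU plus 1%
multiplicative noise — typical double-referenced scatter on a T200-class
instrument; screens use 32 segments at 20 µM probe concentration, R_L =
450 RU; sedimentation coefficients get 2% CV (routine c(s)-level
reproducibility); NMR peaks get 0.005 ppm background scatter, and the
titration covers DNA/protein ratios 0–19.2 at 300 µM protein with a 1:1
ligand-depletion-exact bound fraction. The CSP generator draws per-residue
maximal shifts in [0.5, 1]×δ_max per dimension (default δ_max = 0.3 ppm) on
surface residues.

What the generators do **not** emulate: mass-transport and surface-occlusion
artefacts in SPR, baseline drift other than the explicit linear drift
option, heteroscedastic noise across the dilution series, boundary-shape
information and back-diffusion in AUC (only s₂₀,w and f/f₀ are simulated),
and intermediate-exchange line broadening or peak overlap in NMR. Passing
recovery tests therefore demonstrate correctness of the estimators under the
stated statistical model, not robustness to every instrument artefact.

## Numerical choices and degenerate inputs

- Bisection (not Brent) for the isotherm root: monotonicity guarantees the
  bracket; fixed 80 iterations reach float64 resolution and vectorize.
- Exact integer binomials in the oracle; log-sum-exp for the partition sums;
  `N > 400` refused with a pointer to the closed form.
- `L = 0` returns `v = 0` without solving; `R_L = 0` raises a division error
  at context construction; `v̄ρ ≥ 1` raises a buoyancy error.
- ANOVA on all-identical observations returns F = 0, p = 1 (scipy emits
  NaN for constant input).
- Stoichiometry ties (equal residuals) rank the smaller k first.
- Drift correction with fewer than two standard occurrences warns and passes
  the panel through unchanged.

## Problem sizes

The recovery harnesses use 100 seeded SPR panels (48 observations each,
site-size grid 1–10), 200 sedimentation trials across k = 1–6, and 500 null
screening panels of 32 segments × 3 replicates — sizes at which the Monte
Carlo error on the measured rates (binomial SE ≈ 1–3%) is small relative to
the margins being tested, while the full suite completes in about a minute.

## Known limitations

- Single-class, non-cooperative binding only; no ω ≠ 1 variants, no mixed
  specific + nonspecific models, no kinetic (sensorgram) analysis.
- The free-ligand approximation breaks down if immobilization density is
  high relative to injected protein.
- The linearized `Kd` standard error understates uncertainty when the top of
  the isotherm is unsampled (weak binders cannot be saturated); the per-n
  table and `s_reg` should be inspected rather than the SE alone.
- c(s) distribution fitting, buffer corrections to s₂₀,w, and NMR spectral
  processing are upstream of this package: it consumes their outputs.
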