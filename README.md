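# latticebind

Quantitative analysis of **weak, sequence-independent protein–DNA binding**,
built for the kind of system exemplified by the DNA-binding domain (DBD) of a
pac-type phage small terminase: a small helix-turn-helix protein that binds
duplex DNA with millimolar affinity, no appreciable sequence preference, and
superstoichiometric coverage of the lattice. The package is aimed at
biophysicists combining surface plasmon resonance (SPR), sedimentation-velocity
analytical ultracentrifugation (AUC) and NMR titrations to characterize such
interactions.

## What it computes

**Finite-lattice binding isotherm.** A ligand occluding *n* base pairs on a
duplex of *N* base pairs follows the McGhee–von Hippel isotherm with the
finite-lattice (Tsodikov) end correction:

```
v / L = Ka (1 − nv) [ (1 − nv) / (1 − (n−1)v) ]^(n−1) · (N − n + 1) / N
```

where *v* is bound proteins per bp and *L* the free protein concentration.
The implicit relation is inverted by guaranteed-bracket bisection, and an
**exact combinatorial oracle** (grand-partition enumeration of non-overlapping
*n*-mers, exact integer binomials) quantifies the end-correction error on
short lattices.

**Equilibrium SPR fitting.** Observed responses are converted to densities via
the mass-ratio transform `v = M_DNA/(N·M_protein) · R_eq/R_L`; for each integer
candidate site size, the residual sum of squares in *v* is minimized over
log₁₀ Ka by L-BFGS-B, and the (n, K_d) with the smallest RSS is reported with
per-candidate diagnostics.

**Tiled-segment (ReDCaT-style) screening.** Binding levels normalized per
cycle to the annealed DNA, drift correction against a repeated standard,
one-way ANOVA, Tukey HSD post-hoc comparisons, and flagging of segments more
than one standard deviation above the grand mean.

**AUC stoichiometry.** Molar mass from (s₂₀,w, f/f₀, v̄) through the Svedberg
relation in closed form, mass-weighted partial specific volumes, enumeration
of candidate bound states k (with per-k v̄ recomputation when starting from
s₂₀,w), and site-size bounds from saturated/unsaturated complexes.

**NMR chemical-shift perturbation.** Combined ¹H/¹⁵N differences
`√(ΔδH² + (α·ΔδN)²)` (α = 0.20 for Gly, 0.14 otherwise) and mean + 1 SD
significance mapping over titration endpoints.

**Synthetic data.** Seeded generators emit every input table above from the
exact forward models plus configurable noise, with ground truth recorded, so
every analysis is testable end to end by parameter recovery.

## Worked example

Simulate an equilibrium SPR panel (2-fold dilution series, 1500 µM down to
~0.046 µM, triplicate, generated at n = 3 bp, K_d = 0.92 mM on a 20-bp
duplex with 1% noise) and fit it:

```
$ latticebind simulate --kind spr --seed 7 --out-dir sim
$ latticebind fit-spr sim/spr_panel.csv --out-dir fit
best site size n = 3 bp, Kd = 0.901 mM (s_reg = 0.000884)
```

The fitted site size matches the generating 3 bp and K_d is recovered within
~2%. `fit/per_n_table.csv` shows why n = 3 wins — its residual sum of squares
is ~300-fold smaller than the neighbouring candidates:

```
n,Ka,Kd,...,rss,s_reg,converged
2,536.15,1.865e-03,...,1.04e-02,1.49e-02,True
3,1109.50,9.013e-04,...,3.67e-05,8.84e-04,True
4,1977.42,5.057e-04,...,7.06e-03,1.23e-02,True
```

Likewise for AUC species planted at 0–3 proteins per 11-bp duplex:

```
$ latticebind simulate --kind auc --seed 7 --out-dir simauc
$ latticebind auc-stoich simauc/auc_species.csv --out-dir auc
k0: k = 0 (M = 7.5 kDa)
k1: k = 1 (M = 15.2 kDa)
k2: k = 2 (M = 24.4 kDa)
k3: k = 3 (M = 32.9 kDa)
```

Each measured mass (recomputed per hypothesis with that state's weighted v̄)
ranks the planted stoichiometry first. Other subcommands: `screen-redcat`,
`csp-map`, `tile`, each writing CSV outputs plus a `run_manifest.json` with
input hashes and echoed parameters.

As a library:

```python
from latticebind import LatticeModel, solve_binding_density, mass_from_sedimentation

model = LatticeModel(Ka=1/0.92e-3, n=3, N=20)
v = solve_binding_density(20e-6, model)          # proteins per bp at 20 uM
m = mass_from_sedimentation(1.3, 1.33, 0.56)     # 5-bp hairpin: ~4437 g/mol
```

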