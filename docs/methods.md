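# Methods

This note records the models implemented in `primex`, the defaults and
units, what the synthetic-data generator does and does not emulate, and
the numerical and design choices that were genuinely open.

## Units and conventions

Concentrations are millimolar, time is hours, rate constants are h⁻¹
(first order) or h⁻¹ mM⁻¹ (second order), masses are daltons
(monoisotopic), mass-match errors are ppm. Oligomers are written 5′→3′.

## Activation-chemistry network

Six elementary mass-action reactions over the species \*N (2AI-activated
monomer), N\*N (imidazolium-bridged dinucleotide), NMP (hydrolyzed
monomer), free 2AI, and the primer ladder P, P₊₁, …:

| reaction | constant | default | source |
|---|---|---|---|
| 2 \*N → N\*N + 2AI | k_form | 4.5×10⁻³ h⁻¹ mM⁻¹ | measured (ribo-C) |
| N\*N + 2AI → 2 \*N | k_rev | 0.0668 h⁻¹ mM⁻¹ | calibrated, see below |
| N\*N → \*N + NMP | k_hyd_bridged | 0.105 h⁻¹ | measured |
| \*N → NMP + 2AI | k_hyd_mono | 1.96×10⁻³ h⁻¹ | measured |
| P₊ₖ + N\*N → P₊ₖ₊₁ + \*N | k_ext_bridged | 1.25×10⁻³ h⁻¹ mM⁻¹ | derived: k_obs 2.5×10⁻² h⁻¹ at 20 mM N\*N |
| P₊ₖ + \*N → P₊ₖ₊₁ + 2AI | k_ext_mono | 1×10⁻⁵ h⁻¹ mM⁻¹ | derived from the <2×10⁻⁴ h⁻¹ bound at 20 mM |

Formation is second order in \*N (the printed unit h⁻¹ mM⁻¹ implies a
bimolecular step). Reversal by 2AI attack is included because excess 2AI
measurably suppresses the bridged species; its constant is not published,
so it is **calibrated once by bisection** as the smallest k_rev that keeps
N\*N below 0.25 mM when 100 mM 2AI is present with 20 mM \*N — the
measured suppression bound — giving 0.0668 h⁻¹ mM⁻¹, frozen as the
default. Primer concentrations are 10³-fold below monomer pools, so
extension never perturbs the monomer balance, but it is modeled explicitly
so the conservation laws close. The deepest primer class is absorbing,
keeping chain counts exact.

Two linear invariants are conserved by construction and verified to
<10⁻⁹ relative drift over 100 h: nucleotide units
(\*N + 2·N\*N + NMP + Σ k·P₊ₖ) and 2AI units (2AI + \*N + N\*N).
Integration uses LSODA with rtol 10⁻¹⁰ / atol 10⁻¹², tight enough that
integration error stays below the conservation tolerance; for stiffer
user-supplied constants, shorten the grid or relax tolerances and expect
conservation to track rtol.

`steady_state_bridged` solves formation = reversal + hydrolysis under the
mass balance \*N + 2·N\*N = total with free 2AI = added + N\*N. With both
hydrolysis constants zero this is the exact equilibrium and matches long
simulations to 10⁻⁶ mM; with hydrolysis on, the pool drains before the
transient peaks, so the root overestimates the simulated peak by ~15%
(2.96 vs 2.55 mM at the defaults) and is documented as a quasi-steady
approximation, not a fixed point.

pH is not a state variable. The pH dependence of extension enters only as
alternative rate-constant sets (the pH 7/8/9 presets).

## Rate estimation

P/P₀ decays as exp(−k_obs·t) under pseudo-first-order kinetics, so the
default estimator fits ln(P/P₀) against t by OLS **with a free intercept**,
per replicate, then reports k_obs = −mean(slope) and
stderr = SD(slopes)/√n (n = 2–6 replicates as generated). The raw-fraction
initial-slope alternative and a zero-intercept variant are available
behind `space=`/`intercept=` flags; log-space/free-intercept is the
default because reported rates are pseudo-first-order and gel
normalization errors land in the intercept. Fractions above 1 are clipped
to 1 and non-positive fractions are dropped (log undefined), both counted
on the estimate. Rates below a detectability floor of 2×10⁻⁴ h⁻¹ — the
scale reported only as an upper bound in the source measurements — carry a
`below_floor` flag. Decay fits for species series use the same log-linear
scheme; a numerically flat series reports k = 0 with infinite half-life.

The clip-at-1 rule biases the estimator upward when the sampling window
covers little decay (all points near 1). Recovery is unbiased to <2% when
the window spans ~2.5 decay constants, which is how the generator presets
are laid out: fast conditions (10⁻² h⁻¹ scale) sample 0–52 h, slow
conditions (10⁻³–10⁻⁴ h⁻¹: the guanosine series, the pH series) sample
0–500 h, the window a bench experiment of that rate would in fact need.

## Mass engine

Residue compositions are free-nucleoside formulas; arabino equals ribo
exactly (epimers), threo is ribo − CH₂ (no 5′-methylene), deoxy/dideoxy
subtract one/two oxygens. A phosphodiester linkage adds H₃PO₄ − 2 H₂O. A
uniform ¹³C/¹⁵N label substitutes every C and N in the residue (+12.0213
Da for cytidine), which lifts labeled-ribo products ≥9 Da above their
unlabeled arabino isobars — the disambiguation the labeling strategy
exists to provide. TNA's 3′→2′ linkage regiochemistry does not alter
elemental composition and is deliberately not modeled as mass-bearing;
LC–MS cannot resolve linkage regioisomers. Atomic monoisotopic masses are
pinned (AME2020) for bit-reproducible matching; negative-mode m/z is
(M + n·21.98194 − z·1.007276)/z, sodium being the only adduct series
implemented (potassium would be an extension point). Fluorophore end
groups are out of scope — the competition measurements used unlabeled or
hexynyl primers.

## LC–MS matching and quantification

Candidates are every terminal monomer sequence to the requested depth,
plus single-addition internal-branch products when the primer has free
internal 2′-OHs (suppressed for the DNA-body, 3′-terminal-ribo primer).
Records are assigned to the candidate (and sodium count ≤3) with the
smallest absolute ppm error within a 10 ppm default tolerance — TOF-class
accuracy; assignment is per record (best-ppm, not globally optimal)
because candidate masses are ≥9–14 Da apart by design. Ties between
candidates at genuinely different masses are flagged ambiguous and
excluded; ties between isobars (terminal vs internal branch) resolve to
the terminal candidate deterministically. Retention time is never used
for identity. Quantification sums all matched abundance per terminal
sugar — sodium adducts and co-eluting doublet peaks included — normalizes
per replicate to 100% (equal ionization across terminal sugars, the
stated measurement assumption; per-sugar response factors are available
for sensitivity analysis), and reports mean ± SD (ddof = 1) across
replicates. Site reactivity divides total internal and terminal product
fractions by their site counts (5 internal 2′-OHs, 2 terminal hydroxyls
for an RNA 6-mer).

## Chain-growth model

Memoryless per-step incorporation: f_i = w_i·x_i / Σ_j w_j·x_j. Weights
are fitted from an observed composition by w_i ∝ f_i/x_i (exact algebraic
inverse). Continuation past a terminus s occurs with probability e(s):
e(ribo) = 1, e(arabino) = 0 (measured chain termination), and
e(threo) = 0.17 by default — the ~6-fold threo extension-rate penalty
mapped onto a relative continuation probability, an assumption exposed in
the model config. Terminated short chains are reported as their own
outcome class, not renormalized away, since gels and LC–MS observe them;
conditional-on-full-depth distributions are also available because the
measured +2 profile conditions on products that reached +2. No
longer-range sequence context is modeled — nothing in the data constrains
it.

## Synthetic-data generator

* **Gel**: P/P₀ = clip(exp(−k t)·(1+ε), 0, 1), ε ~ N(0, cv), cv = 5%
  default; 3 replicates (2 for the guanosine series), matching the
  reported replicate counts. A piecewise-rate variant emulates the
  fast-then-slow course of reactions started from preformed N\*N
  (2.5×10⁻² h⁻¹ over 0–8 h, 1.2×10⁻² h⁻¹ after).
* **NMR-like series**: network trajectories with multiplicative noise
  (cv 3%) and an optional renormalization pinning
  \*N + 2·N\*N + NMP to the known 20 mM total, as peak integrals are
  converted to concentrations in practice.
* **LC–MS compound lists**: per replicate and depth, product fractions ~
  Dirichlet(c·truth) with c = 200, chosen so the replicate SD at the
  largest equimolar component (~44.7%) approximates the measured ±3.5
  points; a single concentration cannot reproduce all three printed SDs
  (1.1/3.5/2.5), a documented limit of the Dirichlet choice. Total
  abundance is lognormal (σ = 0.2); abundance splits 80/15/5% across the
  0/1/2-sodium adduct records; each record's mass is the true mass ×
  (1 + δ), δ ~ N(0, 5 ppm) truncated at 4σ. Primers with free internal
  2′-OHs emit each +1 product as a chromatographic doublet (terminal and
  isobaric internal-branch peak, 1.6:1 — the measured internal:terminal
  product ratio); terminal-only primers emit single peaks, as observed.
  Replicates default to n = 6.

With 5 ppm mass error and 10 ppm matching, ~4.6% of records fall outside
tolerance and are (correctly) unmatched; losing a high-abundance record
occasionally skews one replicate's composition, which is the dominant
source of run-to-run scatter in pipeline recovery. Not emulated: raw
chromatograms/spectra/gel images, retention modeling, ionization
suppression, charge-state deconvolution (inputs are already-deconvoluted
neutral-mass lists), cross-batch dry-down variability (drying enters only
as an effective-rate multiplier), and hetero-bridged dinucleotide
kinetics (the network accepts extra species via config but ships no
constants for them, as none are published). Passing tests on these
synthetic data demonstrate correctness of the estimators and pipeline
under the stated noise models — not robustness to the instrument and
batch effects listed above.

## Problem sizes

The test suite and the acceptance script run small, fixed problem sizes:
ODE grids of ≤209 points over ≤100 h, 6-replicate LC–MS datasets (plus a
600-replicate convergence check), 200-dataset bias scans, and 2×10⁴
Monte-Carlo chains; everything completes in a few seconds on one CPU.
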