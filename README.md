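# primex

Kinetics and LC–MS informatics for **non-templated primer extension** with
2-aminoimidazole (2AI)-activated ribo-, arabino- and threo-nucleotides.

Before templates existed, the first oligonucleotides must have grown by
untemplated addition of activated monomers — from a chemically heterogeneous
pool in which RNA's building blocks (rN) coexisted with their arabino (araN,
the 2′-epimer) and threo (tN, one backbone carbon short) congeners. Whether
that chemistry already filtered the pool toward RNA is a quantitative
question, and answering it takes four kinds of analysis that this package
implements as a tested, reusable library:

1. **Activation-chemistry network** (`primex.network`). A mass-action model
   of the 2AI reaction system: activated monomers \*N dimerize to the
   imidazolium-bridged dinucleotide N\*N (rate k_f·[\*N]², k_f in
   h⁻¹ mM⁻¹), 2AI attack reverses it (k_r·[N\*N]·[2AI]), both species
   hydrolyze (N\*N → \*N + NMP at k_h; \*N → NMP + 2AI), and a primer P is
   extended through either species (P + N\*N → P₊₁ + \*N dominating).
   Simulation, quasi-steady-state analysis and a calibration routine for
   the unprinted reverse constant are included.
2. **Rate estimation** (`primex.rates`). Pseudo-first-order k_obs from gel
   band fractions: per-replicate ordinary least squares of ln(P/P₀) vs t
   with free intercept, aggregated as k_obs = −mean(slopes) ±
   SD(slopes)/√n, with time windowing (e.g. 0–8 h vs 8–52 h), exponential
   decay fits for NMR-derived species series, and fold-ratio helpers.
3. **Oligonucleotide mass engine and LC–MS matching** (`primex.chemistry`,
   `primex.lcms`). Elemental formulas and monoisotopic masses for chimeric
   oligomers (ribo/arabino/threo/deoxy residues, uniform ¹³C/¹⁵N labels,
   5′-hexynyl/phosphate ends), negative-mode m/z and sodium-adduct ladders;
   candidate-product enumeration, best-ppm record assignment at a 10 ppm
   TOF tolerance, and normalized incorporation percentages per terminal
   sugar under the equal-ionization assumption, with internal-vs-terminal
   hydroxyl site-reactivity deconvolution
   r = (f_int/n_int)/(f_term/n_term).
4. **Chain-growth competition model** (`primex.chain`). A memoryless
   copolymerization model: step fractions f_i = w_i·x_i / Σ w_j·x_j over
   pool fractions x and propensities w, with terminal-sugar-dependent
   extendability e(s) — e(arabino) = 0 encodes arabino chain termination —
   plus exact sequence enumeration and Monte-Carlo sampling.

A synthetic-data module (`primex.synth`) generates gel time courses,
³¹P-NMR-like concentration series and vendor-style deconvoluted LC–MS
compound lists with explicit noise models and seeds, so the whole pipeline
runs and is tested without any instrument data.

## Worked example

```bash
python examples/competition_lcms.py
```

```
108 compound records across 6 replicates

+1 incorporation (mean ± SD, % of summed +1 abundance):
  arabino   43.8 ± 1.2
  ribo      32.0 ± 0.6
  threo     24.2 ± 1.6

per-site internal 2'-OH reactivity, free primer:  25%
per-site reactivity with complement annealed:     10.6%
```

Six replicate compound lists are generated for an equimolar
\*rC:\*araC:\*tC competition on an RNA 6-mer primer, matched against all
enumerated +1 products (the ribo monomer is ¹³C/¹⁵N-labeled so the
otherwise isobaric ribo/arabino products separate by ~12 Da), and
normalized: arabino incorporation ranks highest, threo lowest — the
pool's composition is roughly mirrored with a bias against threo. The
site-reactivity lines show that an internal 2′-OH is on average a quarter
as reactive as a terminal hydroxyl, dropping to ~10% when a complementary
oligomer is annealed.

Other examples: `mass_ladder.py` (masses and m/z ladders),
`activation_network.py` (bridged-dinucleotide transient and 2AI
suppression), `rate_fitting.py` (windowed k_obs and fold ratios),
`chain_termination.py` (propensity fitting, cross-pool prediction, +2
sequence distribution under arabino termination).

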