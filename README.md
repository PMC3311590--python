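# aawsim

Simulation and composition-only modelling of antibody binding to
random-sequence peptide microarrays.

Serological peptide arrays measure how the antibody repertoire in a serum
sample binds hundreds of random peptides. A striking property of such data
is that for diverse (polyclonal) repertoires the binding profile is largely
predictable from each peptide's *amino-acid composition alone* — the order
of residues barely matters — while single monoclonal antibodies are not
composition-predictable. `aawsim` is a tool for exploring when and why this
happens. It is aimed at people working on array-based serology,
immunoinformatics and repertoire modelling.

It provides:

* a **generator for random peptide libraries** (default: 255 peptides,
  14-mers over the 20 proteinogenic amino acids, no runs of three identical
  residues) and their composition matrices `X`;
* a **Langmuir binding simulator**: each amino acid gets a weight
  `h[aa] ~ U[0,1]`; a peptide is the vector `p` of its residues' weights; an
  antibody is a unit-norm vector `a` with U[-1,1] components; the
  association constant is `K = exp((β₀ + β₁ aᵀp)/(RT))` (defaults
  `β₀ = 0`, `β₁ = RT`, so `K = exp(aᵀp)`), and a mixture with
  concentrations `c` (Σc = 1) yields the bound fraction
  `S = Σ c_k K_k / (1 + Σ c_k K_k)`, optionally with multiplicative noise
  `S·(1+ε)`, `ε ~ N(0, 0.01)`, before the log transform;
* a **composition-only PLS regression** `s = Xw + ε` estimating the 20
  amino-acid-associated weights (AAWS) `w`, with predictive performance
  `Q² = 1 − Σ(ŝ_out − s_out)²/Σ s_out²` from seeded 10-fold
  cross-validation, plus secondary-antibody signal correction for measured
  intensities;
* **ensemble experiments**: antibody-diversity sweeps (1 → 16384 variants),
  noise/dominance scenarios (a single antibody at 10× or 1000× excess in a
  16000-antibody mixture), pairwise AAWS correlations, recovery of the
  generative `h`, PCA of AAWS collections, correlation with user-supplied
  amino-acid property scales, and Wilcoxon rank-sum group comparisons.

## Worked example

```python
import aawsim as aw

lib = aw.generate_library(n_pep=255, l=14, seed=7)
X = aw.composition_matrix(lib)
h = aw.sample_assigned_aaws(seed=1)            # generative weights
mix = aw.make_mixture(n_ab=150, l=14, seed=2)  # 150-antibody mixture
s = aw.simulate_profile(lib, mix, h)           # simulate + log + normalize

cv = aw.q2_cross_validation(s, X, folds=10, seed=3)
est = aw.fit_aaws(s, X, seed=3)
print(f"first peptide: {lib.ids[0]} {lib.sequences[0]}")
print(f"Q2 (10-fold CV): {cv.q2:.3f}")
print(f"PLS components used: {est.n_components}")
print(f"corr(w, h): {aw.h_recovery(est, h):.3f}")
```

prints

```
first peptide: pep0001 WPQVNSTFCHGVWA
Q2 (10-fold CV): 0.613
PLS components used: 5
corr(w, h): 0.934
```

Even though the simulator binds antibodies to peptides in a strictly
position-dependent way, the position-blind composition model predicts 61%
of the held-out signal variance for this 150-antibody mixture, and the
fitted weights correlate at r = 0.93 with the generative per-residue
weights. Both numbers rise towards 1 as the mixture becomes more diverse
and fall under measurement noise or clonal dominance — run
`aawsim sweep --seed 0 --reps 20 --out sweep.tsv` and
`aawsim dominance --seed 0 --reps 20 --out dom.tsv` to see both effects.

The same functionality is available from the shell (`aawsim
generate-library | simulate | fit | sweep | dominance | pca |
correlate-scale`); every subcommand takes explicit seeds and writes a
manifest of all parameters, so runs are byte-reproducible.

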