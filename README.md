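# metamorph

Conformational thermodynamics of fold-switching (metamorphic) proteins from
molecular-dynamics trajectories.

Metamorphic proteins such as the human chemokine XCL1 interconvert between
two well-defined folds: the canonical chemokine fold (*Chemfold*) and an
alternative all-β fold (*Altfold*). This package quantifies the two sides of
that equilibrium from sampled Cα trajectories of each fold, and compares
evolutionary variants (e.g. XCL1 against a resurrected ancestor) to ask
*how* evolution shifted the fold-switch equilibrium — by enlarging the
accessible conformational space, by flattening the free-energy landscape,
or by moving the landscape minimum.

## The model

For each conformer, essential dynamics (PCA of the Cα positional
fluctuations after iterative least-squares superposition) splits the
internal motion into a few large, non-Gaussian **essential modes** ξ and
many small Gaussian near-constraints. A per-mode deviation-from-gaussianity
score selects the essential dimensionality *d*. The essential space is
discretised into hyper-rectangles of volume δ; cell occupancies give

    ΔG_l = −k_B T ln(P_l / P_0)          (Landau free energy per cell)

and the conformer's partition function factorises into the accessible
volume V = N·δ over the N populated cells and the landscape average
⟨e^{−βΔG_l}⟩₀ = (1/N) Σ_l e^{−βΔG_l}. For the Altfold → Chemfold transition

    ΔG ≅ ΔA₀ + ΔG_S + ΔG_L
    ΔG_S = −k_B T ln(V_Chem / V_Alt)                       (entropic, volume)
    ΔG_L = −k_B T ln(⟨e^{−βΔG_l}⟩₀^Chem / ⟨e^{−βΔG_l}⟩₀^Alt)  (landscape)

with the Landau-minimum offset ΔA₀ unresolvable from within-fold sampling.
Between two variants the differences ΔΔG_S, ΔΔG_L combine with an
experimental ΔΔG_exp to estimate ΔΔA₀; within one variant,
ΔG_exp − ΔG_S − ΔG_L isolates the combined dimerization + minimum offset.

Because real microsecond MD trajectories of these systems are large and not
redistributable, the package ships a synthetic-trajectory generator that
plants known essential-mode distributions (uniform boxes, Gaussian
mixtures) in a random orthonormal embedding, together with a closed-form
oracle (`analytic_thermo`) for the exact ΔG_S/ΔG_L of any two-spec
comparison — the basis of the test suite.

## Worked example

Two synthetic conformers whose essential spaces are 2-D uniform boxes, the
"Chemfold" box having 10× the area of the "Altfold" one:

```python
from metamorph import SyntheticSpec, generate_trajectory, FoldSwitchModel, analytic_thermo

common = dict(n_atoms=10, n_frames=100_000, constraint_sigmas=[0.02] * 5, basis_seed=101)
alt = SyntheticSpec(essential_modes=["uniform(0,1)", "uniform(0,0.5)"], sample_seed=201, **common)
chem = SyntheticSpec(essential_modes=["uniform(0,2.5)", "uniform(0,2)"], sample_seed=202, **common)

t_alt, _ = generate_trajectory(alt)
t_chem, _ = generate_trajectory(chem)
res = FoldSwitchModel(t_alt, t_chem, selection=None, n_essential=2, superpose=False).fit()
print(res.summary())
```

prints

```
Fold-switch conformational thermodynamics (Altfold -> Chemfold)
================================================================
essential dimensionality d = 2, T = 310 K, 10 bins/dim

conformer  n_cells  delta_nm_d  volume_nm_d  landscape_avg
  Altfold      100  0.00501278     0.501278       0.914077
 Chemfold      100   0.0509203      5.09203       0.914077

dG_S (accessible volume) =   -5.975 kJ/mol
dG_L (landscape)         =   -0.000 kJ/mol
dG_S + dG_L              =   -5.975 kJ/mol
```

The fitted entropic term tracks the exact value for a 10-fold volume ratio,
`analytic_thermo(alt, chem)` → ΔG_S = −k_B·310·ln 10 = −5.935 kJ/mol with a
flat-landscape ΔG_L = 0: the negative sign says the larger box (the
"Chemfold") is entropically favoured. On real data you would read the four
trajectories (`read_trajectory`, multi-model PDB or plain matrix), keep the
Cα atoms, and let the model superpose and select d for you; the
`metamorph run study.yaml --out dir` CLI drives the full two-variant ×
two-conformer comparison from one config, and `metamorph simulate / ed /
thermo / compare / rmsf / hbond` expose the single steps.

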