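# Methods

## Model and assumptions

The package treats a protein conformer (one fold state of one sequence
variant) as a distribution over a low-dimensional essential space ξ of
collective Cα coordinates, with all remaining internal degrees of freedom
("near-constraints") assumed small, Gaussian, statistically independent and
— crucially — independent of the position in essential space. Under that
assumption the near-constraints contribute identically to both fold states
and cancel from the Altfold → Chemfold free-energy difference, which then
decomposes as ΔG ≅ ΔA₀ + ΔG_S + ΔG_L:

- **ΔG_S = −k_B T ln(V_C2/V_C1)** — purely entropic; V = N·δ is the number
  of populated essential-space grid cells times the cell volume.
- **ΔG_L = −k_B T ln(⟨e^{−βΔG_l}⟩₀^C2 / ⟨e^{−βΔG_l}⟩₀^C1)** — the effect of
  the free-energy landscape within the accessible region, via
  ΔG_l = −k_B T ln(P_l/P₀) relative to the most populated cell.
- **ΔA₀** — the offset between the two landscape minima. It cannot be
  estimated from within-fold sampling (the folds never interconvert inside
  a trajectory); it is carried symbolically and only its *between-variant
  difference* ΔΔA₀ ≈ ΔΔG_exp − ΔΔG_S − ΔΔG_L is estimated, assuming the
  Altfold dimerization penalty is conserved between variants. The
  within-variant combination ΔG_exp − ΔG_S − ΔG_L reported by
  `dimer_offset` is the combined −ΔG_Dim + ΔA₀ offset. ΔA_l is identified
  with ΔG_l (fixed-pressure reading); no volume/pressure correction is
  applied.

Experimental occupancies enter through ΔG_exp = −k_B T ln(f/(1−f)) with f
the Chemfold fraction. The stated occupancies for the reference systems
(f = 0.5 for XCL1, 0.9 for the ancestor) are config inputs, not constants:
published sources quote the ancestor both as 0.9 and as 92/8, so the
fraction is always supplied explicitly.

## Pipeline and parameter choices

1. **Superposition** — iterative unweighted least-squares (Kabsch) fit of
   every frame to the running mean, initialised at the raw coordinate mean
   (falling back to frame 0 if rotational averaging collapsed it),
   iterating fit → re-average until the mean moves < 1e−10 nm RMS (max 50
   passes). Initialising at the mean makes superposition a fixed point on
   already-aligned input.
2. **Covariance** — population covariance (denominator = frame count) of
   the flattened Cα coordinates, unweighted (no masses). Cα-only analysis
   is the default because all-atom covariances of proteins this size
   converge far too slowly to support volume estimates.
3. **Eigendecomposition** — `numpy.linalg.eigh`, eigenvalues descending and
   clipped at 0, eigenvector sign fixed by making each vector's
   largest-magnitude component positive (reproducible projections).
4. **Gaussianity score** — per mode, the projection histogram over
   [μ−4σ, μ+4σ] with 50 equal bins (mass = fraction of *all* frames per
   bin; the ~6e−5 Gaussian tail mass outside ±4σ is treated consistently
   on both sides) minus the bin masses of a Gaussian with the sample
   moments, aggregated as the mean absolute per-bin difference. Sample
   moments, not fitted ones, define the reference; the score is averaged
   per bin, which fixes its scale but not the mode ranking. The default
   threshold ε = 3e−3 sits an order of magnitude above the binomial noise
   floor of a 50-bin histogram at ~5·10⁴ frames (≈5e−4) and an order of
   magnitude below typical scores of genuinely bimodal or box-like modes
   (≳1e−2). Zero-variance modes score 0 with a warning.
5. **Dimensionality** — default `fixed(6)`, matching what the deviation
   score shows for the reference chemokine systems; `threshold(ε)` returns
   the smallest d with every later mode sub-threshold, for new systems.
   Both conformers of a transition must use the same d (volumes must share
   units of nm^d); in threshold mode the model takes the larger of the two
   per-conformer selections.
6. **Grid** — per conformer, in its own essential space: equal-width bins
   spanning the sample range of each dimension, default 10 bins/dim, outer
   edges padded by 1e−9 nm so extreme samples bin inside; δ is the product
   of the nominal widths. Ten bins per dimension balances occupancy
   statistics against resolution for 10⁵–10⁶ frames in up to 6-D. Distinct
   δ per conformer is intentional — the theory permits different grids as
   long as d matches.
7. **Landscape** — cells with fewer than `min_count` (default 1) frames are
   dropped and probabilities renormalised; the reference cell ξ₀ is the
   most populated one, ties broken by lexicographically smallest index
   tuple. ⟨e^{−βΔG_l}⟩₀ = 1/(N·P₀) holds algebraically and is used as an
   independent identity check in the tests, never as the implementation.

Constants: k_B = 0.0083144621 kJ/(mol·K); default T = 310 K (the
physiological condition of the reference experiments). Lengths are nm
internally; PDB Å are converted on I/O.

## Synthetic generator

The generator emulates what essential-dynamics analyses of stable folds
show: a handful of large-amplitude non-Gaussian essential modes (uniform
boxes, Gaussian mixtures) over many small independent Gaussian
near-constraints, embedded into 3N Cartesian coordinates by a seeded random
orthonormal basis (QR of a standard-normal matrix, R-diagonal sign fixed —
uniform over the orthogonal group) around a helix-like mean curve with
0.38 nm Cα spacing. Optional per-frame rigid-body noise (rotation angle and
translation sampled uniformly within bounds) exercises the superposition
step. Basis and sample seeds are independent so landscapes can be resampled
in a fixed embedding. Spec invariants force every essential-mode variance
above every constraint variance so the planted ordering is the eigenvalue
ordering.

What it does **not** emulate: kinetic correlation between frames (samples
are i.i.d., so convergence with frame count is faster than for real MD),
coupling between essential modes (planted independently by default;
real essential fluctuations are coupled), anharmonic coupling between
essential and constraint subspaces, and solvent/side-chain degrees of
freedom. Passing tests therefore validate the *estimators* — that the
pipeline recovers planted spectra, dimensionalities and free-energy terms —
not the physical assumptions of the decomposition itself.

For bounded (box) essential modes the infinite-sampling thermodynamics are
available in closed form: with independent modes, cell probabilities are
products of per-dimension bin masses (CDF differences), giving exact N, P₀,
δ and hence ΔG_S and ΔG_L under a stated grid policy. Unbounded modes
require an explicit grid range (`GridPolicy.ranges`), otherwise the oracle
refuses rather than guess a support.

## Problem sizes and numerical notes

The validation suite runs the pipeline-vs-oracle comparison at 10⁵ i.i.d.
frames with d = 2 and 10 bins/dim (≥10³ expected counts per cell, making
the dominant error the ~3% binomial noise on the modal cell probability,
i.e. ≲0.05 kJ/mol on ΔG_L), spectrum/dimensionality recovery at 5·10⁴
frames with 6 planted non-Gaussian + 50 Gaussian modes on 25 atoms, and
rigid-noise invariance at 5·10⁴ frames with identical mode samples so the
comparison isolates the superposition step. These sizes were chosen as the
smallest at which the i.i.d. sampling noise is comfortably below the
quantities being checked.

Degenerate inputs are rejected explicitly: zero-range grid dimensions,
single-frame covariances, collinear superposition references, occupancy
fractions at 0 or 1, landscapes emptied by `min_count`. The occupancy free
energy is computed as −k_B T (ln f − ln(1−f)) so that swapping f ↔ 1−f
negates the result exactly in floating point.

## Structural descriptors

RMSF is √⟨‖x_i − ⟨x_i⟩‖²⟩ per Cα after superposition (isotropic jitter of
width σ per coordinate gives σ√3); residues above the profile mean are
flagged. A residual-drift heuristic warns (never errors) if the centroid
moves > 1e−3 nm between trajectory halves. Backbone hydrogen bonds use the
conventional geometric criterion — N···O ≤ 0.35 nm and N–H···O angle ≥ 150°
— with both cutoffs exposed, since published occupancies rarely state the
criterion; both directional pairs between two residues are evaluated
separately and jointly. Cα-only trajectories cannot evaluate H-bonds and
are rejected with a clear error. Cross-variant residue numbering is aligned
through an explicit per-variant `residue_offset` in the study config.
DSSP-style secondary-structure assignment is out of scope (an external
published tool); the study accepts only pre-computed summaries.

## Known limitations

- ΔA₀ and ΔG_Dim are never estimated separately, only in the combinations
  described above; absolute ΔG predictions are out of reach by design.
- The accessible volume depends on the populated-cell count N, which at
  fixed sampling grows with trajectory length; comparisons are meaningful
  between equally sampled conformers (the study design) rather than as
  absolute entropies. No block/convergence analysis of V(t) is provided.
- Compressed binary MD formats (XTC/DCD) are not part of the tested
  contract; multi-model PDB and the plain matrix format are.
- `evolution_comparison` assumes both variants were analysed at the same
  temperature and with the same transition convention; it checks the
  former and cannot check the latter.
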