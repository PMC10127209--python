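# Methods

This note records the models, numerical choices, and deliberate
limitations of the package. Everything stated here is computed by the
test suite or the demo pipeline; nothing is quoted from elsewhere.

## Boost-potential reweighting

A boosted simulation samples the modified density
∝ exp(−(V + ΔV)/kT) with a non-negative per-frame boost ΔV. The package
recovers canonical statistics with per-frame weights w_i and the
weighted histogram p_m = Σ_i w_i δ_{m,i} / Σ_i w_i over M bins of a 1D
or 2D collective-variable (CV) space, then F_m = −kT ln p_m shifted to a
zero minimum.

* **Weights.** `maclaurin_weights` evaluates the truncated series
  Σ_{j≤K} (ΔV/kT)^j / j! by Horner recursion; `exact_weights` is the
  exponential oracle. Default order K = 10: at the boost magnitudes the
  generator produces (ΔV/kT ≲ 3.5) the order-10 landscape agrees with
  the exact-exponential landscape to < 10⁻³ kcal/mol per bin, while
  orders 0 and 2 are measurably worse (the suite asserts the monotone
  improvement 0 → 2 → 10). The order is a parameter everywhere.
* **Temperature.** kT = 0.0019872041 × T kcal/mol; default T = 300 K
  (kT ≈ 0.596 kcal/mol), configurable.
* **Binning.** Default 50 bins per axis over the observed CV range
  padded by 2 %; explicit edges may be passed instead. Frames outside
  the range are clipped and counted.
* **Masking.** Bins with fewer than `min_count` = 10 raw frames carry no
  finite free energy: −kT ln of a tiny noisy probability would otherwise
  dominate the surface. Masked bins are NaN and excluded from the
  minimum shift.
* **Minima.** Strict local minima against all finite grid neighbours
  (Moore neighbourhood), sorted by depth. Marginalising a 2D landscape
  onto one axis integrates *probability* over the other axis and
  re-derives F — free energies are never averaged. A landscape whose
  finite bins are all equal reports zero strict minima and a flat flag.
* **Degenerate inputs.** All-zero weight vectors, empty histograms, and
  landscapes without any sufficiently occupied bin raise
  `DegenerateInputError` rather than returning NaN surfaces.

## Synthetic boosted ensembles

The generator samples CV space directly: the reweighting mathematics
consumes only (CV, ΔV) pairs, so Cartesian dynamics would add cost
without adding validation power. Sampling is an exact categorical draw
over a fine regular grid of the boosted density (2001 points in 1D,
301² in 2D) with uniform jitter inside each cell, so there is no
equilibration, autocorrelation, or integrator error; the discretisation
bias is O(h²) and far below the test tolerances.

* **Boost form.** Harmonic lower-bound boost per component:
  ΔV = k0/(2(E − V_min)) (E − V)² for V < E, else 0, with 0 < k0 ≤ 1 and
  E defaulting to the grid maximum of V. Two independent components
  (total-potential and dihedral) may be active simultaneously; the full
  per-frame boost is their sum, and both are recorded. Boost-parameter
  defaults (k0 = 0.2 total, 0.1 dihedral) are illustrative, not fitted
  to any particular simulation, and are exposed in the config.
* **Gaussian bath energy.** In a real solvated system the boost acts on
  the total potential energy, whose fluctuations are near-Gaussian
  because thousands of degrees of freedom contribute; a low-dimensional
  CV potential alone cannot reproduce that (its Boltzmann energy
  distribution is gamma-like, and skewness is scale-invariant, so no
  choice of k0 changes it). The optional `GaussianEnvironment` term adds
  an independent Gaussian bath energy (default sd 3 kcal/mol, quadrature
  grid ±8 sd) to the potential seen by the boost. With it the generated
  boost distribution is near-Gaussian (|skewness| ≈ 0.4 measured), while
  the CV marginal and the per-frame reweighting remain exact. The bath
  is off by default because the analytic worked examples (e.g. threshold
  E = 2 kcal/mol on the harmonic well) are defined on the bare CV
  potential.
* **Test surfaces.** Flat (uniformity/zero-boost identity), harmonic
  well V = 2(x−3)² on [0, 6] (landscape recovery), symmetric double well
  x⁴ − 2x² (symmetry), and a two-basin 2D surface
  a(x²−1)² + cx + by² whose tilt c is solved by root-finding so that the
  quadrature free-energy difference between the x<0 and x>0 basins
  equals a requested value (1.0 kcal/mol in the tests) exactly. Ground
  truth is always the quadrature of the analytic density, computed
  independently of the sampling path.

## Toy trajectories and the CV engine

`gen_toy_trajectory` emits pseudo-atom trajectories from per-state
template coordinates (two rigid groups; the default layout places the
kinase lobe-separation distance at 28.5 Å closed / 29.8 Å open and the
compact/extended distance at 20 / 25 Å) plus optional isotropic Gaussian
noise, in PDB + DCD or a full-precision CSV table. The generator records
the noiseless per-frame geometry as ground truth.

The CV engine loads files through MDAnalysis into an in-memory handle
and computes distances (minimum-image for orthorhombic boxes), angles
(arccos of the normalised dot product, clamped to [−1, 1]; a zero-length
vertex arm flags the frame NaN), contact occupancies (default heavy-atom
cutoff 4.0 Å; H-bond proxy: donor–acceptor ≤ 3.5 Å, since published
H-bond observations rarely state geometric criteria), and RMSD after
Kabsch superposition (scipy `Rotation.align_vectors`; ≥ 3 fit atoms
required). Selections resolve by residue number and atom name exactly as
carried in the PDB — full-length numbering, no renumbering — and a
selection that matches zero or several atoms is a hard error. DCD stores
float32, so cross-format equality tests compare after rounding to
10⁻⁴ Å; the CSV path is full precision.

Both presets for the C-lobe anchor of the lobe-separation distance
(residue 2060 as Ala or Gly naming) resolve identically because
selection is by residue number and atom name.

## States and clustering

State definitions are threshold rules with an optional dead band
labelled `unassigned`; occupancies (weighted or not) always sum to 1
over emitted labels. Default thresholds are documented stand-ins chosen
between the basin positions the landscapes themselves produce: 29.0 Å
for open/closed (between 28.5 and 29.8), 24.0 Å for compact/extended
(between 20–23 and 25), and 12 Å on the K1906 Nζ – D2017 Cγ distance as
a DYG-in proxy. All are config, not claims about any particular study's
criteria.

QT clustering precomputes the pairwise distance matrix (Euclidean on
feature vectors, or pairwise Kabsch-fitted RMSD on coordinates) and
greedily extracts largest neighbourhoods. Determinism: ties break to the
lowest frame index; emitted clusters are re-ranked by size (stable).
The O(N²) matrix limits direct use to a few thousand frames; the
workflow subsamples (default 400 frames, seeded) before clustering. The
implementation is tested for exact partition equality against a
brute-force enumeration oracle that recomputes every candidate
neighbourhood from scratch.

## HDX quantification

* Theoretical maximum uptake: length − 1 − internal prolines (the
  N-terminal amide back-exchanges too fast; proline has no amide
  hydrogen). An 11-residue proline-free peptide → 10 Da.
* Percent-of-maximum uses *uncorrected* uptake — that is the convention
  under which 5.0 Da of a 10 Da maximum is 50 % — and the
  back-exchange-corrected value (÷(1−f), default f = 0.25) is a separate
  column.
* Replicate summaries: mean ± SEM with the n−1 sample sd; one replicate
  reports SEM as missing, never 0. Percent > 110 is flagged, not
  clipped.
* Exponential fits U(t) = A(1 − e^{−kt}) (scipy `curve_fit`, bounds
  0 ≤ A ≤ theoretical max, k > 0) are presentational; all downstream
  statistics use raw means. Non-convergence flags the peptide and keeps
  the raw data. A single-exponential-to-plateau is a deliberate
  simplification of multi-amide kinetics; the synthetic recovery tests
  use single-amide ground truth where it is exact, and the noise-level
  test (sd 0.1 Da, 3 replicates) asserts 10 % parameter recovery.
* Differentials: Δ = mean_state − mean_reference, SEM in quadrature,
  significant when |Δ| ≥ max(0.5 Da, 2·SEM_Δ) — a package convention,
  configurable, since published datasets rarely state one. Protection
  therefore appears as Δ < 0 against the apo reference.
* Structure mapping writes overlap-averaged per-residue values into the
  B-factor column of a copy of the topology; uncovered residues get the
  sentinel −99.99 (fits the PDB column width).

## Synthetic HDX data

Replicate uptake at exposure t is
(1 − f) Σ_j A_j (1 − e^{−k_j t}) + N(0, σ) with per-amide rates k_j and
plateaus A_j, global back-exchange f, and replicate noise σ (default
0.1 Da, three replicates, exposures 0/0.5/1/2 min). The generator
validates plateau sums against the theoretical maximum and stores its
ground truth as JSON. What it does *not* emulate: isotope-envelope
shapes, EX1 bimodality, peptide-level back-exchange variation,
carry-over, or retention-time drift — so passing tests demonstrate
correctness of the quantification arithmetic and statistics, not
robustness to raw-spectra pathologies.

## Workflow

Both pipelines stage outputs in a temporary directory and move them into
place only on success, so failed runs leave nothing behind; manifests
record parameters, the seed, and SHA-256 hashes of every output, and a
rerun with the same seed is byte-identical. All randomness flows from
the single config seed. Problem sizes in the shipped demo (20 000 frames,
400-frame cluster subsample, three peptides × three states) keep a full
end-to-end run in the low seconds while leaving every statistical
assertion comfortably resolved; the recovery tests use 50 000–100 000
frames where their tolerances require it.

## Known limitations

* Landscapes are limited to 1D/2D; no cumulant-expansion reweighting
  variants or anharmonicity diagnostics beyond the skewness check.
* The QT metric on coordinates superposes all atoms (no separate
  fit/measure split inside the clustering metric).
* No Markov-state modelling, kinetics, or transition-path analysis.
* The HDX layer starts from centroid-level data; spectral processing,
  peptide identification and mobility handling are out of scope.
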