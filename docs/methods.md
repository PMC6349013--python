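# Methods

## Model and procedure

The pipeline post-processes snapshot streams of a ligand diffusing around a
protein. It assumes (i) a rigid reference structure onto which every frame
has been (or can be) superposed, (ii) per-snapshot binding energies scored by
an external function and consumed as given numbers, and (iii) that the
surface position of a bound ligand is usefully summarized by the *direction*
from a pocket-anchored origin to its center of mass.

**Coordinate frame.** The frame origin is an atom in the target pocket (for a
phosphodiesterase catalytic domain, the pocket Zn²⁺); the X axis points to a
first anchor Cα and the Y axis is the second anchor direction orthogonalized
against X (Gram–Schmidt), with Z = X×Y. Real anchor lines are never exactly
orthogonal; keeping X exact and orthogonalizing Y preserves the stated X
definition and right-handedness. Projection onto the globe is radial
(central): latitude/longitude depend only on the direction origin→point, so
the irregular molecular surface never needs triangulation. Longitude lies in
[−180°, +180°), west negative; poles carry longitude 0; equator and prime
meridian take the non-negative labels N/E.

**Grid and estimators.** The unrolled plate-carrée map is divided into 7200
half-open 3°×3° cells (latitude +90° folds into the top row). Cell energy is
the exponential (Boltzmann) average −RT ln⟨e^(−E/RT)⟩ computed by
log-sum-exp; it is bracketed by the cell minimum and the arithmetic mean and
is monotone in every input. Cell counts are conserved: they sum to the number
of bound snapshots ingested. Cell-level uncertainty is a seeded nonparametric
bootstrap SD of the same estimator (B = 200 by default); the bootstrap is the
natural choice when the estimator is a nonlinear functional of the sample.
Unvisited cells carry no energy (maps display them at the 0 kcal·mol⁻¹
unbound reference) and contribute no spline nodes and no well statistics.
No cos(latitude) area weighting is applied to cells — binning is in equal
angular cells, so high-latitude cells cover less area; comparisons on the
synthetic benchmark therefore place wells at matched latitudes.

**Kd calibration.** ΔG = RT ln(Kd/c°) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹,
c° = 1 M and T = 298.15 K by default (RT = 0.5925 kcal·mol⁻¹): 1000 μM ↔
−4.1 and 1000 nM ↔ −8.2 kcal·mol⁻¹ at one decimal, the two well thresholds.
The calibration temperature is configurable independently of any simulation
temperature because the thresholds above are room-temperature values.

**Wells.** Wells are connected components (8-connectivity, wrapping across
the ±180° longitude seam, no polar wrap) of cells with ΔG < −4.1; a
component is a deep well when its minimum is < −8.2, else shallow. Well
statistics use the raw per-cell exponential averages; thin-plate smoothing
is reserved for map rendering and barrier profiles, so segmentation never
depends on the smoothing parameter. "Well" here means thresholded basin — no
separate local-minimum test beyond the component minimum, and no watershed
splitting of merged basins.

**Thin-plate surfaces.** Fitted on the map plane to occupied cell centers:
r² log r kernel plus affine part, smoothing λ added to the kernel diagonal of
the augmented system (λ = 0 interpolates; affine trends are reproduced
exactly at any λ). The fit is not longitude-periodic; for display and
barrier sampling this is acceptable because nodes cover the map densely
wherever the statistics are meaningful.

**Bound states.** Bound ⇔ COM strictly within 5 Å (≈ ligand radius) of *any*
protein heavy atom — no surface-residue pre-filter, since an interior atom
within 5 Å implies surface contact in practice and the criterion stays
parameter-free. Effective ⇔ bound and ligand-RMSD < 15 Å (≈ pocket
diameter) against the native pose, heavy atoms in fixed order, no re-fitting
of the ligand and no symmetry reduction. A trajectory is successful when
every RMSD in its final 20% of frames (tail_fraction, our stability
definition) stays below the pocket scale. Both cutoffs are strict `<`.

**Pathways.** For a successful trajectory, bound positions are run-length
encoded over grid cells; dwells of ≥ 10 frames (dwell_min) become key points
at the dwell's spherical mean position, stamped with first-entry time. Runs
never merge across unbound gaps, and simplification is idempotent (key
points carry their dwell counts). Barriers are sampled along great-circle
segments (50 points by default) on the smoothed surface as
max(profile) − max(endpoints), floored at zero.

## Synthetic generator

The generator emulates the study conditions end to end: a quasi-uniform
Fibonacci-lattice pseudo-atom sphere (default 800 atoms, 30 Å radius,
off-origin center) with a ZN origin atom and two Cα anchors 70° apart
realizing a known frame; 4 ligand copies (the emulated systems carry four
inhibitor molecules); a surface potential that is a sum of Gaussian wells in
great-circle angle, U ≤ 0 with a 0 baseline; RT = 0.5925 kcal·mol⁻¹; additive
Gaussian noise σ_E = 0.3 kcal·mol⁻¹ on reported energies; bound frames 1.5 Å
above the surface, unbound excursions 6.5–20 Å above it (beyond the 5 Å
cutoff by construction).

The walker is Metropolis on the sphere with tangent-plane Gaussian proposals
of 1.5° (≈ half a cell; 30–60% acceptance over the test potentials) mapped
back to the sphere. Unbinding attempts are accepted with e^{U/RT} and uniform
rebinding proposals with 1 (U ≤ 0): the detailed-balance pairing for a flat
unbound reservoir, so excursions leave the bound-state density Boltzmann.
For multi-well potentials a symmetric *well-swap* move (the rotation carrying
well center k onto center k+1, proposed forward/backward with probability ½
and Metropolis-accepted, 10% of steps) is mixed in. The move preserves the
stationary density exactly; its purpose is mixing: a purely diffusive walker
crosses a ≥ 4 kcal·mol⁻¹ barrier at a rate ~e^(−ΔG‡/RT) ≈ once per 10⁶
steps, far too rarely to measure occupancy ratios, whereas the swap move
exchanges basins at ~Z_shallow/Z_deep per proposal (hundreds of exchanges
per 10⁶ steps for the benchmark pair).

All randomness flows from the single mandatory seed through
`numpy.random.SeedSequence` children spawned in fixed order (fixture lattice;
walker; energy noise; atom template/rotations), making CSV output
byte-identical across runs of the same seed.

What the generator does *not* emulate: force-field energetics, solvent,
protein flexibility, ligand conformational change, or scorer systematic
error (noise is i.i.d. Gaussian). Passing tests therefore demonstrate the
correctness of the projection, binning, estimation, segmentation and pathway
machinery under known ground truth — not the physical fidelity of any MD or
scoring protocol.

## Benchmark problem sizes

The standard two-well benchmark places a −8.5 and a −5.0 kcal·mol⁻¹ well
(widths 8°) at equal latitude, 80° apart — far enough that their tails stay
in the barrier band between them. Validation runs 4 copies × 250 000 steps
(10⁶ samples), which recovers well minima within one cell, depths within the
noise scale, and the cap-integrated Boltzmann occupancy ratio
(∫e^(−U/RT)dA over 25° caps, dense lat–lon quadrature) to a few percent.
Exponential averaging of noisy energies carries a known bias −σ_E²/(2RT)
(≈ −0.08 kcal·mol⁻¹ at the defaults), well inside the recovery tolerance.
Unit tests use shorter runs (6 000–30 000 steps) where only coarser
properties are asserted; the flat-landscape uniformity check thins samples
past the walker's decorrelation time before applying multinomial bounds.

## Numerical choices and degenerate inputs

- Exponential averages via `scipy.special.logsumexp` (overflow-safe); the
  test oracle is a 50-digit `decimal` evaluation.
- Kabsch superposition via SVD-based least squares; ±180° longitude values
  normalize to −180; the poles' longitude is 0 by convention.
- Percentages print at two decimals, round-half-away-from-zero; energies at
  4 decimals; snapshot CSV floats at fixed precision (1e-9 round-trip).
- Degenerate inputs raise typed errors: collinear/zero frame anchors,
  projection of the origin, ambiguous or empty atom selectors, mismatched
  correspondences, empty energy lists, < 3 or collinear spline nodes,
  too-short RMSD series, pathway extraction on unsuccessful trajectories,
  and stage invocation before its dependencies (the error names the missing
  stage).
- Empty pocket masks are invalid; cap radii must lie in (0°, 90°]. The
  default mask is a 15°-radius cap centred on the landscape's global
  minimum — a substitute for a pocket boundary that would otherwise have to
  be drawn by hand; override it with an explicit cap or cell set when the
  pocket is known.

## Known limitations

- Same-topology Kabsch superposition only; cross-isoform (sequence-
  independent) structural alignment is out of scope, so multi-isoform
  comparisons require externally superposed inputs.
- The thin-plate surface is not periodic in longitude and extrapolates
  freely across unvisited regions; barrier values across sparsely sampled
  territory inherit that uncertainty.
- Equal-angle cells distort areas toward the poles; anchor the frame so the
  pocket sits near the equator when absolute areas matter.
- No kinetics: no rates, residence times, committors or Markov-state models
  are estimated.
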