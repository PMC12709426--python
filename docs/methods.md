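# Methods

This note documents the models, conventions, numerical choices and
limitations behind each pipeline stage, and what the synthetic test
systems do and do not establish about real trajectories.

## Coordinates, units, conventions

All internal lengths are nm; energies kJ/mol; angles degrees at the API
surface. Areas that are conventionally quoted in Å² (area per lipid,
packing-defect areas and constants) are converted only at reporting
(1 nm² = 100 Å²). Boxes are orthorhombic; triclinic inputs are rejected —
every system the pipeline targets (planar and quasi-1D buckled bilayers)
lives in an orthorhombic box. Coordinates are wrapped into `[0, L)` per
axis on load (a choice, not a convention inherited from any file format),
and all lateral distance computations use the minimum image in xy.
GRO files are parsed by fixed column positions, so merged fields survive;
PDB Å are converted to nm on read. XTC/TRR streaming goes through
MDAnalysis; bead metadata comes from the GRO/PDB topology.

Peptide molecules are unwrapped bond-by-bond (minimum image on consecutive
bead differences) before COM or axis computations: a straight 21-bead
backbone spans ~7 nm, which can exceed half the box, where min-imaging
against a single reference bead would fold the chain.

## Leaflet assignment

A lipid is `upper` if the mean z of its head (phosphate) beads exceeds the
mean z of its tail beads, else `lower`. The per-lipid head-minus-tail rule
is deliberately local so it remains correct on buckled membranes, where a
global z-cut misclassifies lipids near the buckle extremes. Lipids are the
molecules owning a phosphate bead; a phosphate-bearing molecule without
tail beads is a structural error rather than a silent guess.

## Insertion depth

Depth = (mean z of the peptide leaflet's phosphates whose xy
minimum-image distance to the peptide COM is ≤ r) − (peptide COM z),
sign-flipped on the lower leaflet so positive always means deeper (toward
the core). Defaults: r = 1.0 nm. The local reference is the arithmetic
mean of the in-cylinder phosphates, not a fitted plane. Frames with an
empty cylinder are flagged and excluded from averages, never silently
dropped into them. With several replicate trajectories, the reported
value is the mean of replicate means and the sd their sample standard
deviation; a single trajectory reports the over-frames sd.

## Tilt and state classification

The peptide axis is the principal component of the backbone bead cloud,
oriented from the first to the last bead so 0° and 180° are distinct; on
collinear synthetic peptides it agrees with the end-to-end vector within
2° under bead jitter (tested). State windows — transmembrane when
|CV1| ≤ 0.5 nm and the tilt is within 45° of either normal, adsorbed when
|CV1| ≥ 1.2 nm, inserted otherwise — are explicit configuration derived
from the synthetic landscape geometry, not inferred from any reference
data, and they are echoed into every report. They partition the (CV1, CV2)
plane (property-tested).

## Surface fitting and curvature

The leaflet height field is expanded in the real tensor Fourier basis
`{1, cos(2πmx/Lx), sin(2πmx/Lx)} ⊗ {…y…}` up to mode cutoffs (Mx, My),
giving (2Mx+1)(2My+1) coefficients fitted by linear least squares
(SVD-backed; a QR solve of the normal equations must agree within 1e-10,
which is tested). Underdetermined or rank-deficient designs raise errors
(with a condition-number diagnostic) instead of returning garbage.
Defaults Mx = My = 3: low cutoffs deliberately under-resolve thermal
roughness so bead jitter is absorbed into the residual instead of showing
up as spurious curvature; the truncation is configurable and the synthetic
suite measures its effect.

Each leaflet is fitted separately from its own phosphate beads, and a
peptide is evaluated on its own leaflet's surface; this matches the
per-leaflet peptide bookkeeping and makes the upper/lower comparison a
true convergence check. Fits are per-frame and independent; no temporal
smoothing.

Sign convention: h is measured along +z, and the Monge-gauge formulas are
applied as-is for the upper leaflet; for the lower leaflet H (and hence
k1, k2) is negated. With this convention the two peptides of a buckled
system sample directly comparable curvature values, and a single-mode
buckle `h = A sin(kx)` has `H = −A k²/2` at its crest for the upper
leaflet. Gaussian curvature is orientation-independent and is not
negated; for any x-only height field K ≡ 0 (developable surface), which
the suite asserts at 1000 random points. `H² ≥ K` holds analytically; the
tiny negative discriminants produced by floating point are clamped at 0.

The accessible curvature distribution integrates H over a uniform xy grid
with each point weighted by its area element `√(1+|∇h|²)` — a surface
measure, chosen because a particle diffusing on the membrane samples the
surface, not its projection. The grid must resolve the highest fitted
mode (nx ≥ 4Mx); in practice a much denser grid (2048 x-points for
single-mode buckles) is used so the histogram is converged at the 0.005
nm⁻¹ bin width, which costs nothing at these problem sizes.

## Curvature-preference reweighting

Sampled curvature histograms (one H per frame, evaluated at the peptide
COM) are divided bin-by-bin by the accessible distribution and
renormalized. Bins with accessible weight < 1e-4 are masked (division
blow-up guard) and the discarded sampled probability is reported. The
headline identity, tested end-to-end: positions drawn with density
∝ dA·exp(a·H) reweight to a distribution whose log is linear in H with
slope a. Mean sensed curvature is the weighted mean over unmasked bins;
leaflet agreement is the total-variation distance with convergence
declared below 0.1 (configurable). Histogram default: 0.005 nm⁻¹ bins on
[−0.15, 0.15] nm⁻¹, wide enough for buckles up to |H| ≈ 0.15 nm⁻¹.

## Free-energy post-processing

Marginalization uses the trapezoid rule on the CV2 grid in log space
(log-sum-exp), so landscapes offset by +10⁶ kJ/mol give bit-identical
shifted profiles. The constant C defaults to the CV2 integration range;
since ΔΔG is invariant to C (and to global shifts) the choice is cosmetic
and tested as such. CV2 is integrated in its native grid unit (degrees);
any unit change only moves the C-absorbed additive constant, which the
minimum shift removes. Unvisited bins at the edges of a CV2 column are
excluded with a warning; unvisited interior bins are an error because the
column integral would be meaningless.

Temperature is mandatory context (default 310 K, the standard thermostat
setting for this simulation family) and is echoed into every report;
R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹.

States are strict local minima of the 1D profile refined by a 3-point
parabola; the transmembrane window is |CV1| ≤ 0.5 nm, adsorbed
|CV1| ≥ 1.2 nm (both configurable, same defaults as the classifier). A
profile with no minimum in a required window raises a state-detection
error — a monotonic profile has no transmembrane state, and the pipeline
says so rather than reporting a boundary value. The barrier is the
highest point between the adsorbed and transmembrane minima, relative to
the adsorbed one.

The synthetic landscape generator specifies the 1D marginal first — a
plateau at the programmed barrier carved by compact cosine-squared wells
(adsorbed at ±1.8 nm, transmembrane at 0, width 0.6 nm) — and adds a
CV1-independent harmonic tilt term. Disjoint well supports make the
programmed state energies exact, and the harmonic term marginalizes to an
exact additive constant, so recovered ΔΔG equals the programmed value to
quadrature accuracy; the suite exercises gaps from 0 to ~53 kJ/mol, the
magnitude range relevant for helices from strongly adsorbed to nearly
iso-stable transmembrane.

Boltzmann inversion (`G = −RT ln(ρ/ρ_max)`) flags zero-count bins as
unvisited (NaN) rather than −∞ and serves as the unbiased cross-check on
marginalized profiles.

## Packing defects

The interfacial grid scan: the leaflet is rasterized at 0.1 nm; a cell is
probed from the solvent side; any covering bead (disk of radius 0.26 nm,
the Martini bead radius, single default for all beads, configurable per
table) at or above the local phosphate mean z minus 0.1 nm covers the
cell; otherwise the cell is a defect cell if the topmost remaining
covering bead is an acyl-chain bead, or if no bead covers it at all
(void). Defect cells are merged 4-connected (8 optional) with periodic
wrap in both lateral directions; areas are cell counts × cell area in Å².
The defect-detection parameters are conventional, not reconstructive of
any particular published analysis, and reported constants are flagged as
parameter-dependent.

The defect-area constant π is fitted on the tail A ≥ a_min (default
15 Å²) by maximum likelihood: π = mean(A − a_min), CI = π/√n — unbiased
and binning-free; a log-linear histogram fit is kept as a cross-check and
must agree within its own error. By memorylessness the MLE is
a_min-invariant on truly exponential data (tested at 15/20/25 Å²). The
1σ CI covers the truth ≈68% of the time, verified by simulation (1000
repetitions at n = 400 draws; at this n the asymptotic coverage is
already exact to ~1%). All-equal areas are a degenerate fit: warned, and
π = 0 returned with a flag.

## Synthetic systems: what they are and are not

The generators emulate the geometry of coarse-grained bilayer systems,
not their physics. Lipids are vertical bead columns on a jittered
lattice (so tail order is exactly 1 and defects are purely geometric);
thermal roughness is independent Gaussian jitter (any stationary
small-amplitude noise suffices to exercise the fitting stack); the buckle
is a single sine mode along x, so its Gaussian curvature is exactly zero
and its mean curvature is known in closed form; peptides are 21 collinear
beads at 0.35 nm spacing — helical geometry is irrelevant to COM/tilt
observables; curvature-biased positions use rejection sampling (simple
and exact, no inverse-CDF approximation). Defaults: 92 lipids per leaflet
and 65 Å² for planar systems, A = 1 nm and λ = 20 nm for the buckle —
the buckle numbers are chosen for numerical convenience (λ = box length,
gentle slope), not fidelity to any particular compressed box.

Passing tests therefore establish that the *analysis* layer is correct:
geometry is measured exactly on jitter-free fixtures, estimators converge
at their theoretical rates under programmed noise, and biases programmed
into the sampling are recovered. They do not establish force-field
realism, sampling convergence of μs-scale trajectories, or the values of
membrane observables for real lipid types; those require real
trajectories, for which `pipeline.run_reference_check` computes area per
lipid and defect constants and compares them against published reference
values when such trajectories are supplied, degrading gracefully
("reference data unavailable") when they are not.

## Problem sizes and determinism

Default suite sizes: 92–400 lipids per leaflet, tens of frames per
trajectory, 10⁵ biased position samples for reweighting checks, 10⁴
exponential draws for the defect fit, 1000 repetitions for coverage and
type-I-error calibration. The whole test suite runs in well under a
minute; the acceptance script in a few seconds. All stochastic stages
draw from `numpy.random.default_rng` streams derived from a single seed
via `SeedSequence`, so every table is bit-reproducible; generator outputs
carry their parameters (and per-frame ground truth where applicable) so
downstream estimates can be predicted in closed form.

## Known limitations

* Orthorhombic boxes and planar/quasi-1D buckled topologies only; no
  vesicles or closed surfaces (the Monge gauge assumes a single-valued
  height field).
* Surfaces with overhangs (A ≥ λ/4 buckles) are rejected, not modelled.
* One bead radius for all bead types in defect detection by default.
* The 2D free-energy landscape is an input; no enhanced-sampling engine
  or bias-history reweighting is implemented.
* Density profiles use a single default bead mass (72 amu); per-type
  masses would matter only for absolute densities, not for the shapes and
  symmetries the pipeline asserts.
* The depth–curvature slope tests assume independent per-point errors;
  replicate structure beyond the per-membrane series is not modelled.
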