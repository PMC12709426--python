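# memsense

Analysis pipeline for peptide–membrane interactions in coarse-grained
bilayer simulations: how deep an amphipathic helix sits in a bilayer, how
it reorients between surface-adsorbed and transmembrane states, and which
membrane curvature it prefers once the bilayer is buckled.

The package is aimed at simulators working with Martini-style bead models
of lipid bilayers (planar or laterally compressed "buckled" boxes) and
short helical peptides. It covers the full post-simulation layer:

* **Surface reconstruction (Monge gauge).** Each leaflet is a single-valued
  height field `h(x, y)` fitted to phosphate bead positions by linear least
  squares in a box-periodic 2D Fourier basis. Mean, Gaussian and principal
  curvatures follow analytically:

  `H = [(1 + h_y²) h_xx − 2 h_x h_y h_xy + (1 + h_x²) h_yy] / [2 (1 + h_x² + h_y²)^{3/2}]`,
  `K = (h_xx h_yy − h_xy²) / (1 + h_x² + h_y²)²`.

* **Peptide observables.** Insertion depth (peptide COM vs the mean z of
  that leaflet's phosphates inside a 1.0 nm lateral cylinder, positive =
  deeper), tilt angle vs the membrane normal, the COM-distance collective
  variable, leaflet assignment that survives buckled geometries, and
  adsorbed / inserted / transmembrane state classification.

* **Free-energy post-processing.** A 2D landscape ΔG(CV1, CV2) — CV1 the
  peptide–membrane COM z-distance, CV2 the tilt — is marginalized by
  Boltzmann averaging, `G(CV1) = −RT ln(∫ e^{−βΔG(CV1,CV2)} dCV2 / C)`,
  symmetrized across leaflets (with per-bin errors from the half
  difference), shifted to min 0, and reduced to
  ΔΔG = G(transmembrane minimum) − G(adsorbed minimum). Boltzmann
  inversion of unbiased densities provides the cross-check.

* **Membrane characterization.** Area per lipid, S_CC tail order
  parameters, partial density profiles, peptide-centred thickness/order
  maps, and lipid packing defects (interfacial grid scan; defect sizes
  follow an exponential law `P(A) ∝ exp(−A/π)` whose constant π is fitted
  on the tail by maximum likelihood).

* **Curvature-preference statistics.** Sampled curvature histograms at the
  peptide position are divided by the accessible (area-weighted) curvature
  distribution of the surface; the reweighted distribution's mean is the
  "mean sensed curvature", leaflet agreement (total-variation distance) is
  the convergence diagnostic, and depth–curvature Pearson correlations plus
  two-sample slope t-tests quantify trends across membranes.

Every stage is exercised end-to-end on synthetic bead systems with known
ground truth (`memsense.synthetic`): jittered phosphate lattices, a
single-mode sinusoidal buckle with closed-form curvature, peptides placed
at programmed depth/tilt, curvature-biased position samples, double-well
free-energy surfaces with exact programmed ΔΔG, and exponential defect
areas. No external trajectory data are required.

## Worked example

Recover a programmed 20 kJ/mol adsorbed→transmembrane gap from a synthetic
2D landscape:

```python
from memsense.pmf import marginalize_cv2, symmetrize, shift_min_zero, delta_delta_g
from memsense.synthetic import gen_fes2d

fes = gen_fes2d(ddg=20.0, barrier=60.0)           # programmed landscape
pmf = shift_min_zero(symmetrize(marginalize_cv2(fes)))
print(f"ddG = {delta_delta_g(pmf):.2f} kJ/mol, barrier = {pmf.barrier:.2f} kJ/mol")
```

prints

```
ddG = 20.00 kJ/mol, barrier = 60.00 kJ/mol
```

i.e. the marginalize → symmetrize → shift → state-detection chain returns
the programmed gap exactly (quadrature accuracy). The same pattern holds
for the curvature stack: a peptide pinned at the crest of the
`h(x) = 1.0·sin(2πx/20)` buckle samples `H = −0.04935 nm⁻¹`
(= −A k²/2), and position samples biased by `exp(a·H)` with `a = 10 nm`
reweight to a distribution whose log-slope recovers `a` within a few
percent at n = 10⁵.

The numbered drivers under `analysis/` run the three full analyses on the
synthetic study systems and write their tables to `results/`:

```bash
python analysis/01_generate_systems.py     # systems + geometry checks
python analysis/02_insertion_depth.py      # depth vs hydrophobicity + slope tests
python analysis/03_pmf_reorientation.py    # 2D landscapes -> ddG table
python analysis/04_curvature_sensing.py    # reweighted curvature preference
```

A thin CLI (`memsense simulate|depth|curvature|pmf|sense|props|peptides|report`)
exposes the same stages on GRO/XTC inputs.

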