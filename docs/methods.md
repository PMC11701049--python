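# Methods

`octi` simulates temporal-interference (TI) electrical stimulation of the
retina in an anatomically structured human eye volume conductor, and
quantifies where the interference envelope concentrates on the retinal
surface and how electrode placement and channel current ratios steer it.

## Physical model

TI stimulation drives pairs of electrodes ("channels") with kHz sinusoidal
currents at slightly different frequencies.  At stimulation frequencies the
tissue behaves resistively (quasi-static approximation), so each channel's
field is the solution of the steady conduction problem

    div( sigma(x) grad phi ) = 0,        E = -grad phi,

with a fixed total current injected through the channel's stimulating
contact and extracted at its return contact, and zero normal current on the
outer boundary of the orbit (insulated surround).  Conductivities are
low-frequency values applied frequency-independently; capacitive and
dispersive effects are out of scope.

Where two channel fields `E1`, `E2` superpose, the beat envelope of the
component along a unit direction `n` has amplitude

    e(n) = | |(E1 + E2) . n| - |(E1 - E2) . n| |.

The printed difference form can be negative for some `n`; the physical
amplitude is its absolute value, and since e(n) = e(-n) the hemisphere
suffices for maximization.  The maximal modulated envelope amplitude (MMEA)
at a point is `max_n e(n)`:

* **Two channels** — evaluated in closed form (after flipping one field's
  sign if the fields subtend an obtuse angle, and ordering |E1| >= |E2|:
  the maximum is `2 |E2|` when `|E2| <= |E1| cos a`, else
  `2 |E2 x (E1 - E2)| / |E1 - E2|`).  A deterministic Fibonacci-lattice
  direction search (default 10^4, 10^5 in tests, with local polish around
  the best lattice directions) serves as an independent brute-force oracle;
  the two agree to better than 1e-3 relative on 10^4 random pairs.
* **Four channels (3D montage)** — the standard upper-bound approximation
  `MMEA ~= 2 min_i |E_i|` over the channel field magnitudes, used as
  printed in the source model.  For two channels this bound provably
  dominates the exact value (property-tested).

Linearity makes channel fields a superposition basis: a channel solved at
1 mA is rescaled to any current, so a whole (alphaX, alphaY) current-ratio
grid costs four solves.

## Anatomy and parameters

All lengths in mm, angles in degrees.  Coordinates: origin at the eye
center, +z posterior (anterior corneal pole at -z), +x nasal, +y superior.
Electrode polar angles are measured from the anterior pole.

The globe is a nest of concentric shells whose thicknesses follow the
tissue table: vitreous chamber diameter 22 (radius 11.0), then retina 0.33,
choroid 0.45, sclera 0.63, giving an outer scleral radius of 12.41 and a
retinal mid-surface radius of 11.165 (so 2.6 deg of eccentricity is
~0.51 mm of retinal arc).  The cornea is a 0.5-thick cap of half-angle
27 deg; the anterior chamber ("atria", sigma = 1.5 S/m) fills the 2.8-deep
space to the lens front; the lens is an ellipsoid of axial thickness 4.0.
Retina and choroid extend to 95 deg of eccentricity.

The optic nerve leaves the globe 22.5 deg nasal of the posterior pole: a
truncated cone from optic-disc radius 0.9 at the inner retinal surface to
the retrobulbar cylinder radius 1.775 at the scleral junction, then a
cylinder wrapped by coaxial CSF (0.58) and sheath (0.73) annuli.  The
nerve is the only anisotropic tissue: conductivity 0.5 S/m along the fiber
axis and 0.08 S/m across it, expressed as R diag(0.08, 0.08, 0.5) R^T with
R rotating +z onto the tilted axis.  A posterior muscle shell (1.42) and
orbital fat (radial extent 14.5, insulated outer boundary) surround the
globe.  Conductivities (S/m): cornea 0.422, atria/vitreous 1.5, lens 0.322,
retina/sclera 0.5028, choroid 0.2779, muscle 0.267, fat 0.028, CSF 2,
sheath 0.006.

Electrodes are 500 um Pt discs on the outer scleral surface.  At the mesh
scales used here the disc is at or below one element, so contacts are
modeled as compact nodal current-injection patches (nodes hugging the
scleral surface within the disc footprint or one local cell, Gaussian
lateral weights).  This keeps the stiffness matrix montage-independent —
one factorization serves every electrode position — at the cost of not
resolving the sub-electrode near field; all reported metrics live at least
one electrode diameter away.  Montages: 2D = nasal + temporal
stimulating/return pairs in the horizontal plane (channels 1, 2); 3D adds
superior + inferior vertical pairs (channels 3, 4).  The current-ratio
indexes alphaX = I1/(I1+I2) and alphaY = I3/(I3+I4) split a fixed 2 mA
per plane; alphaX = alphaY = 0.5 is 1 mA per channel.  Reported maps are
min-max normalized, so the absolute drive cancels.

## Discretization and solver

The mesh is a graded rectilinear grid whose boxes are cut into six
tetrahedra sharing the main diagonal (conforming by construction); each
tetrahedron takes the tissue of its centroid under the analytic geometry,
and the build is fully deterministic (hash-tested).  First-order elements;
per-element conductivity tensors; the singular Neumann system is gauged by
pinning the node farthest from the origin and reporting zero-mean
potentials.  Systems up to 60k nodes are solved by sparse direct LU (exact,
with ~0.1 s back-substitutions per additional electrode configuration);
larger ones by ILU-preconditioned BiCGstab to a relative residual of 1e-9,
orders below metric precision.

Element-wise gradients are discontinuous, so retinal sampling recovers a
nodal field by volume-weighted patch averaging restricted to the retinal
surface tissues (retina + nerve head; this avoids smearing across the
retina/vitreous and retina/choroid conductivity jumps) and evaluates it by
exact P1 interpolation.

Against the analytic Legendre-series solution for two point sources on a
homogeneous insulated sphere, the solver agrees to ~1% in the interior at
0.8-0.9 mm resolution; cut-plane current flux is conserved to <1% and
discrete reciprocity holds to <1%.

**Mesh presets.**  Resolution follows the feature being measured:

| preset | resolution | used for |
|---|---|---|
| `macular` | 0.18 mm over the posterior pole (to ~13 deg) | theta2=170 widths (~0.5 mm arc) |
| `posterior` | 0.3 mm cap to ~25 deg | steering-grid statistics |
| `globe` | uniform 1.0 mm over the whole globe | center-vs-edge sweep comparisons |
| `coarse` | 0.45 mm pole cap | balancing search, general desk scale |
| `test` | 0.6 mm | unit tests |

The uniform `globe` preset exists because pole-refined meshes resolve the
retinal center better than the periphery and would bias a center-vs-edge
comparison.  The 80% width of the theta2=170 envelope peak is a few tenths
of a millimetre of arc: meshes coarser than ~0.25 mm cannot represent it,
which is why the `macular` preset exists (widths were checked for
refinement consistency across 0.45/0.25/0.18 mm).

## Retinal metrics

Retinal coordinates are (eccentricity from the posterior pole, meridian
from the nasal semi-axis toward superior).  MMEA is sampled on a regular
(eccentricity x meridian) grid on the retinal mid-surface and min-max
normalized over that chart.  The theta2=170 configurations are analyzed on
a macular chart (20 deg extent, 0.2 deg step), matching how that montage
confines its field; all others on the full 80 deg chart.

* **Profiles and focality.**  Curves are taken along horizontal, vertical
  and diagonal great-circle directions.  Focality statistics use curves
  through the convergent peak in an azimuthal-equidistant (en-face) chart:
  the peak abscissa is then the central-peak offset relative to the retinal
  center (positive = temporal / superior), and FWHM / 80% width are the
  contiguous super-level intervals around the peak, endpoints located by
  linear interpolation, thresholds measured between the curve's own floor
  and peak so that widths are invariant to normalization constants.
  Boundary-reaching intervals are flagged censored; equal maxima resolve
  toward the center (tie-flagged); center-line curves are also produced for
  map display.
* **Iso-intensity contours.**  The 0.8 super-level region of the normalized
  map (meridian-periodic connected component containing the global peak) is
  "closed" iff it avoids the chart's eccentricity boundary; its overlap
  with the optic-nerve cross-section disc (angular radius
  asin(1.775/11.165) ~= 9.1 deg at 22.5 deg nasal) is none/partial/full.
  Steering-grid summaries (mean +/- SD widths, offset ranges) cover only
  non-excluded cases, excluding unclosed contours and any nerve overlap.
* **Regions.**  Fovea / parafovea / perifovea at 2.6 / 6.2 / 13.7 deg of
  eccentricity (0.5 / 1.25 / 2.75 mm of arc), nerve disc overriding;
  all configurable.

## Experiments

* **Return-electrode sweep** (theta1 fixed at 30 deg): equal-current maps
  for theta2 in {45..170}; the onset of central convergence is the largest
  theta2 at which the retinal-center MMEA still does not exceed every edge
  value (edge points at the extent boundary on the eight semi-axes).
* **Vertical balancing**: for a 3D montage with given theta2H, pick theta2V
  minimizing |80% width horizontal - vertical| at equal currents on a 1 deg
  grid (deterministic tie-break toward smaller theta2V, optional 0.5 deg
  refinement).
* **Steering grids**: (alphaX, alphaY) in {0.1..0.9}^2 by superposition
  (four solves per montage), with the exclusion bookkeeping above.

## What the model does and does not capture

Reproduced from the published study at desk scale: the 80% widths and FWHM
of the theta2=170 convergent area (2.3/2.7 deg and ~7.7 deg vs printed
2.6/3.0 and ~8), the balanced vertical angle at theta2H=105 (106 vs 107),
the mean steering-grid width at theta2=145 (9.5 +/- 1.5 vs 10.7 +/- 1.4),
and the qualitative nerve-mediated effects (nasal/temporal peak shifts,
horizontal-vertical anisotropy, nerve-overlap exclusion patterns).

Known deviations: the center-over-edge convergence onset falls at
theta2 = 90 here vs 105 published (the crossing is marginal — center/edge
= 1.09 at 105 — and sensitive to the retinal extent used for edge points,
which the source never prints); and the maximum temporal steering offset
at theta2=170 is ~7.4 deg vs 4.5 published — in this model the envelope
peak at extreme alphaX approaches the weak channel's return electrode more
closely, a behavior set by near-contact fields and orbital tissue geometry
that printed parameters do not constrain.

Simplifications to keep in mind: stair-step tissue boundaries from
centroid labeling (no boundary-fitted interfaces); electrodes as nodal
injection patches rather than meshed Pt volumes; schematic anterior
segment and orbital fat/muscle shapes; no time-domain waveforms, neuronal
response models, or surrounding head anatomy.  Passing tests demonstrate
faithfulness to this volume-conductor idealization, not to real ocular
anatomy or to measured in-vivo fields.
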