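# Methods

This note documents the models, conventions, defaults and numerical choices
behind each analysis stage, what the synthetic-ensemble generator does and
does not emulate, and the design decisions taken where the method left room.

## Coordinate conventions

All coordinates are in Angstrom, the membrane normal is the z axis, and the
bilayer midplane (z = 0 for analysis purposes) is recomputed per frame as
the mean z of all phosphorus atoms.  Boxes are orthorhombic; triclinic
boxes are rejected with an explicit error rather than silently mistreated.
Atom indices are 0-based internally; residues are identified by
(residue name, residue id).  The shipped selection config uses CHARMM36
DPPC atom names (P; glycerol refs C2/C31/C21; ester carbonyl oxygens O22 =
sn-2, O32 = sn-1; phosphate non-ester oxygens O13/O14; palmitoyl C-H pairs)
and is overridable via YAML/JSON for other force fields.

## Area per lipid

Each lipid's in-plane position is the centroid of its three glycerol-region
reference atoms projected to xy.  Per-lipid area is the cell of a Voronoi
tessellation of these centroids under periodic boundary conditions,
implemented by replicating the (wrapped) centroids into the eight
neighboring images, tessellating once, and reading the central points'
cells; cell polygons are closed by construction and their areas (shoelace
formula) sum to Lx*Ly exactly to floating point.  The leaflet mean is
therefore identically box-area / n_lipids — the per-lipid *distribution* is
what the tessellation adds.  Whether the underlying "polygon from three
atoms" construction is read as raw triangles or Voronoi cells does not
change the leaflet mean; the Voronoi reading is used and recorded in the
run manifest.  Fewer than three lipids per leaflet or a collinear centroid
set is an error.

## Density profiles and bilayer thickness

Mass density along z is a per-frame mass-weighted histogram of the selected
atoms (z re-centered to the frame midplane), averaged over frames and
normalized by bin volume.  Default bin width 0.2 A.  Thickness is the
distance between the density maxima on the two sides of z = 0, each refined
by 3-point parabolic interpolation so the estimate is not quantized to the
bin grid; a flat profile or a side without mass raises "no peak".  The
summary window for time series defaults to the final third of frames, the
converged tail of a production run.

## Deuterium order parameters

S_CD = -1/2 <3 cos^2(theta) - 1> with theta the instantaneous C-H angle to
the fixed z normal (no local-normal estimation), averaged over frames,
lipids and the equivalent hydrogens of each carbon.  The ensemble brackets
are part of the definition; the instantaneous kernel is exposed separately
for testing.  Values are bounded to [-1, +1/2]; the isotropic limit is 0.
Standard errors come from contiguous frame-block means (default 5 blocks),
the usual defense against time-correlated frames.  Output reports the
signed value plus an |S_CD| column, since experimental comparisons
conventionally use magnitudes.  All hydrogens listed for a carbon are
averaged together (the possible inequivalence of the two sn-2 C2 protons is
not resolved separately).

## Depth, tilt, and free-energy maps

Each probe contributes one sample per frame: z = mass-weighted center of
mass minus the frame midplane; tilt = angle between the ring-A -> ring-B
axis vector and +z, in [0, 180] deg.  Lower-leaflet samples can be folded
into the upper-leaflet frame ((z, tilt) -> (-z, 180 - tilt)), which is
exact under bilayer mirror symmetry and doubles effective sampling; the
fold is a separate helper (default on in the CLI) so the map function
itself remains mirror-equivariant.  Histogram defaults: 2.5 deg x 0.5 A
bins, tilt range [0, 180] deg, z range fitted to the data.  Free energy is
F = -kB T ln(p / p_max) with kB = 0.0019872041 kcal/(mol K); temperature is
a required parameter (the emulated systems were run at 310 and 325 K).
Empty bins are flagged unsampled (NaN), never given a finite energy.
Marginals sum the probability over the other axis first and invert second;
no sin(theta) Jacobian is applied by default (the raw density is inverted),
and enabling it is an explicit, labelled option.

## Hydrogen-bond typing

A bond is declared when donor-acceptor heavy-atom distance <= d_max
(default 3.5 A) and D-H...A angle >= angle_min (default 150 deg), with
minimum-image distances.  Only the probe donates (the lipid has no
donors): donor groups are the 3,5-dihydroxy end (To) and the 4'-OH (B);
acceptors are phosphate oxygens (H) and ester carbonyl oxygens (Ta,
carrying the sn-1/sn-2 chain label).  The defaults are the common
geometric criteria for MD hydrogen-bond analysis and both are CLI-exposed
for sensitivity checks.  Each (probe, frame) is classified into a
composite code concatenating donor tokens with the acceptor tokens they
touch, To-part before B-part and Ta before H (e.g. ToTaH = the 3,5-OH end
bonded to both an ester and a phosphate oxygen); no events is NA.
Probabilities are per probe-frame (the convention is recorded in the
manifest); mean bonds per probe, ester/phosphate event fractions, and the
sn-2:sn-1 ester ratio (undefined, not infinite, when no sn-1 events exist)
summarize the table.

## ADIFAB quantification

R = (I550 - I550_blank)/(I457 - I457_blank); R0 is the same ratio for the
zero-FFA control; [FFA] = Kd*Q*(R - R0)/(Rmax - R) with kit constants
Kd = 32, Q = 5, Rmax_calibration = 0.762.  The calibration rescale
(R0_measured / R0_calibration) * Rmax_calibration is implemented as
producing the *working Rmax* for the binding equation — the reading of the
rescale that keeps the equation consistent when the measured zero-FFA ratio
differs from the kit's calibration; the convention applied is recorded in
the manifest.  Kd's units are not standardized here, so FFA values are
labelled "Kd units" and the CLI accepts a unit string rather than inventing
one.  R >= Rmax is a saturation error; R < R0 yields a negative value
returned as-is with a below-baseline flag.  [FFA]_net = [FFA]_PLA -
[FFA]_background is a plain difference, flagged when negative.

## DSC transition extraction

A linear baseline is fit to the outer 15% of the temperature range on each
side (quadratic optional) and subtracted.  The main transition is the
global maximum of the excess signal, required to exceed 5 flank standard
deviations (otherwise the result is "no transition", not an exception); Tm
is parabolic-refined and the half-height width is the full width where the
excess crosses half the peak height, linearly interpolated between grid
points.  The largest secondary maximum below Tm with prominence >= 5% of
the main peak is reported as the pre-transition.  For a noiseless Gaussian
the extracted width equals 2*sqrt(2 ln 2)*sigma within a grid step, and Tm
is invariant to baseline slope.

## The synthetic-ensemble generator

The generator is a statistical emulator, not a physical simulator.  Per
frame it places lipids on a jittered square lattice per leaflet (box edge
chosen so area/lipid is exact by construction), phosphorus at
z = +/- thickness/2 plus Gaussian noise, glycerol refs straddling the
lattice site, and C-H bond vectors drawn from a two-component mixture of
fixed-angle cones (theta = 0 and theta = 90 deg) whose weight
w = (1 - 2*S)/3 makes the expected instantaneous order parameter exactly
the target — an exact-expectation construction valid on the whole physical
range [-1, +1/2].  Probes are rigid dummies (two ring-centroid markers 8 A
apart plus one O-H hydroxyl per end) placed on a sparse per-leaflet lattice
(so probes cannot come within bonding range of each other) with Gaussian
depth and truncated-Gaussian tilt, alternating leaflets with mirrored
(z, tilt).  Hydrogen-bond codes are drawn per probe-frame from configured
frequencies and realized geometrically: each bonded donor end claims its
own nearest free lipid (matching the observation that a probe bridges two
neighboring lipids), that lipid's acceptors are first parked beyond
cutoff + 0.5 A, and the drawn acceptors are repositioned at 2.8 A along the
O-H direction (a second acceptor of the same donor 12 deg off-linear so
the atoms do not coincide while staying inside the angle criterion).
Non-bonding lipids keep their acceptors in a shell 4 A above the phosphate
plane, out of range of the probe depth band.

Defaults are the emulated study's conditions: 80 lipids per leaflet, 18
probes, 51.7 A^2 per lipid and 44.9 A thickness (the transition-regime
values at 310 K), probe density z = 12 +/- 1.5 A and tilt = 75 +/- 10 deg,
and code frequencies calibrated once so the planted ensemble reproduces the
headline bonding statistics (1.6 bonds per probe-frame, 46.6% ester vs
53.4% phosphate events, sn-2:sn-1 = 1.2 via an independent per-event sn-2
probability of 1.2/2.2).  The z-depth noise default of 0.5 A and the
glycerol/acceptor offsets are chosen as representative of headgroup-region
positional spread; they are one-time choices, not fitted quantities.

What the emulator deliberately lacks: real chain conformations and their
z-dependence, water, lipid diffusion and frame-to-frame correlation,
membrane undulations, and any coupling between area, thickness and order.
Passing recovery tests therefore demonstrates the *analysis* is correct and
unbiased at realistic noise levels — not that the emulator's geometry is a
substitute for a physical trajectory.

## Problem sizes and determinism

Recovery tests run at sizes where the expected statistical error is several
times smaller than the asserted tolerance: 10,000 C-H vectors per carbon
for S_CD (+/- 0.02), 160 lipids x 100 frames for structure recovery (2% on
area, 0.2 A on thickness), 810,000 samples for the free-energy map (the
probe-count x frame-count scale of the emulated analysis), and 10,000+
probe-frames for code frequencies (+/- 0.02).  The per-bin comparison of
re-exponentiated probabilities against the planted density uses the
multinomial counting error and is asserted family-wise (>= 99% of
well-sampled bins within 3 sigma, all within 6 sigma), since the expected
maximum over ~500 bins of a correctly specified model already exceeds 3
sigma.  All stochastic stages draw from numpy Generators seeded from a
single user seed; identical seeds give byte-identical outputs, including
the written PDB/DCD fixtures and all CSVs.

## Known limitations

- The trajectory reader handles PDB and DCD only (no PSF/TPR topologies);
  masses come from the PDB element column.
- Leaflet assignment is by sign of P z against the mean-P midplane and will
  misassign lipids in strongly undulating membranes.
- Free-energy uncertainty is counting-error only; no autocorrelation-aware
  error bars on F.
- DSC deconvolution is limited to the pre/main two-peak scheme; overlapping
  multi-component transitions are out of scope.
- Enzyme-kinetics modelling and downstream inferential statistics on FFA
  results are out of scope; the FFA stage emits tidy CSV for any stats
  package.
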