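# memprobe

Analysis toolkit for locating a small amphipathic probe molecule — the
motivating case is the polyphenol resveratrol — inside a phospholipid
bilayer, and for quantifying its membrane effects from both simulation-style
coordinate data and bench assays.

Molecular-dynamics studies of probe/membrane systems reduce to a handful of
standard observables, and `memprobe` implements each of them as a tested
library function with a thin CLI on top:

- **Area per lipid** by tessellation: each lipid is reduced to the centroid
  of three glycerol-region reference atoms (C2, C31, C21) projected into the
  membrane plane, and its area is its cell in a periodic Voronoi
  tessellation, so per-leaflet areas sum exactly to the box cross-section.
- **Bilayer thickness** as the peak-to-peak distance of the phosphorus mass
  density along the membrane normal, with parabolic peak refinement.
- **Deuterium order parameters** per acyl carbon,
  `S_CD = -1/2 <3 cos^2(theta) - 1>`, where theta is the instantaneous angle
  between a C-H bond and the bilayer normal.
- **Free-energy maps of probe location and orientation**: every probe
  contributes one (tilt, z) sample per frame; the pooled 2D histogram is
  Boltzmann-inverted, `F = -kB T ln(p / p_max)`, with 1D marginals obtained
  by integrating the probability over the other axis.
- **Hydrogen-bond typing**: geometric detection (donor-acceptor distance
  <= 3.5 A, D-H...A angle >= 150 deg by default) and classification of
  every probe-frame into composite codes (`ToH`, `ToTa`, `ToTaH`, `BH`, ...,
  `NA`) distinguishing the probe's two hydroxylated ends (To = 3,5-OH,
  B = 4'-OH) and the lipid acceptor groups (H = phosphate O, Ta = ester
  carbonyl O, with sn-1/sn-2 chain attribution).
- **ADIFAB free-fatty-acid quantification**:
  `[FFA] = Kd * Q * (R - R0) / (Rmax - R)` with blank-corrected 550/457 nm
  intensity ratios and kit constants (Kd = 32, Q = 5, Rmax = 0.762).
- **DSC transition extraction**: main transition temperature Tm and the
  width of the transition peak at half height after linear baseline
  subtraction, plus optional pre-transition detection.

Because reference trajectories for such systems are rarely deposited, the
package ships a first-class **synthetic-ensemble generator** that plants
every quantity above as known ground truth (lattice bilayer with target
area/thickness, C-H vectors with exact target S_CD expectation, Gaussian
probe depth/tilt density, exact H-bond code frequencies) so every analysis
stage has a parameter-recovery test.

## Worked example

Generate a 50-frame synthetic bilayer (160 DPPC-like lipids, 18 probes,
planted area 51.7 A^2/lipid and 44.9 A phosphate-peak thickness) and run the
structural, hydrogen-bond and free-energy stages:

```
memprobe simulate --seed 42 --frames 50 --out demo/sim
memprobe structure --top demo/sim/system.pdb --traj demo/sim/trajectory.dcd --out demo/structure
memprobe hbonds    --top demo/sim/system.pdb --traj demo/sim/trajectory.dcd --out demo/hb
memprobe femap     --top demo/sim/system.pdb --traj demo/sim/trajectory.dcd --temp 310 --window 1.0 --out demo/fe
```

which prints (one JSON summary per stage):

```
{"area_per_lipid_mean": 51.69999404681148, "area_per_lipid_sd": 3.2e-14,
 "thickness_mean": 44.951959603105415, "thickness_sd": 0.37, ...}
{"mean_hbonds_per_probe": 1.5811111111111111, "frac_ester": 0.46380885453267745,
 "frac_phosphate": 0.5361911454673226, "sn2_to_sn1_ratio": 1.1498371335504887, ...}
{"min_angle_deg": 73.75, "min_z_A": 11.25, "n_samples": 900}
```

Reading the numbers: the Voronoi mean area returns the planted 51.7 A^2
(the tessellation conserves box area, so the leaflet mean is exact by
construction) and the phosphate-peak thickness recovers 44.9 +/- 0.4 A under
0.5 A positional noise.  Each probe forms ~1.6 hydrogen bonds per frame,
~46% of them with ester carbonyl oxygens, with the sn-2 ester slightly
favored over sn-1.  The free-energy map's minimum sits in the bin covering
a depth of ~12 A from the bilayer center and a tilt of ~75 deg from the
membrane normal — the planted insertion mode.  Every stage also writes
per-frame/per-bin CSV files and a `manifest.json` recording inputs
(checksummed), parameters, package version and timestamp.

The `ffa` and `dsc` subcommands work from plain CSV inputs (fluorescence
readings; temperature/heat-flow thermograms) and need no trajectory.

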