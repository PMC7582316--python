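# powerstroke

Desk-scale analysis of the myosin-II ADP-release conformation and the
second step of the power stroke.

Myosin motors convert ATP hydrolysis into force through a cycle of
conformational states. The release of the hydrolysis product ADP — the
step that sets how long the motor stays bound to its actin track — is
coupled to a second, smaller swing of the mechanical converter domain.
This package implements the computational side of characterizing that
transition for people working with motor-domain structures and binding
data:

* **state metrics** — the observables used to place a structure on the
  pre-power-stroke → ADP-release → rigor axis: actin-binding-cleft widths
  measured between the Cα atoms of the marker pairs Ser272–Ser465 (inner
  cleft) and Ser416–Lys589 (outer cleft), converter rotation from a
  core/domain Kabsch decomposition, P-loop displacement, and nearest-
  landmark state classification;
* **interaction networks** — hydrogen-bond and salt-bridge detection with
  trajectory occupancies, including the switch-1 Arg238–Glu459 bridge,
  the Arg131–Glu187 nucleotide groove, and the Arg232 communication hub
  that links switch-1, the P-loop and the SH2-helix;
* **biased coarse-grained dynamics** — a Cα elastic-network Langevin
  engine with targeted MD (harmonic bias on the best-fit RMSD gap,
  `V = (k/2N)·[RMSD(t) − RMSD*(t)]²`) and constant-velocity steered MD
  (`V = k/2·(v·t − s)²` on the ligand centre of mass), used to
  reconstruct cleft closure, the second converter rotation, and ADP
  unbinding along multiple release vectors with force profiles in pN;
* **energy profiles** — a pairwise protein–ligand interaction-energy
  surrogate (Lennard-Jones + distance-dependent-dielectric Coulomb +
  buried-contact term) scored along the reconstructed pathway, with
  automatic detection of low-energy conformations;
* **binding fits** — Hill-equation dissociation constants from
  thermophoresis-style dose–response tables,
  `S(c) = baseline + amplitude·cⁿ/(K_Dⁿ + cⁿ)`, with multi-start least
  squares and case-resampling bootstrap intervals.

A synthetic-data module generates everything needed to exercise the full
pipeline without downloads: toy motor-domain structures with exactly
controllable cleft widths and converter angles, interpolated
trajectories, and Hill-model titrations.

## Worked example

Generate the standard fixtures and measure a release-like toy structure
against a rigor-like reference:

```sh
$ powerstroke simulate-fixtures --out fx --seed 1
$ powerstroke metrics --pdb fx/toy_release_adp.pdb --reference fx/toy_rigor_apo.pdb
metric  value
inner_cleft     11.7
outer_cleft     11.3
converter_rotation_vs_pps       55.002
ploop_shift     0.0
global_rmsd_vs_reference        1.917
state   ADP-release
distance_to[pre-power-stroke]   5.956
distance_to[ADP-release]        0.0
distance_to[rigor-like] 1.568
```

The cleft is ~1 Å wider than the fully closed rigor pose (10.7/10.2 Å)
and the converter sits 55° from the up position — the fingerprint of the
ADP-release conformation, and indeed the nearest landmark.

Salt bridges show the encoded nucleotide groove and communication hub:

```sh
$ powerstroke bridges --pdb fx/toy_release_adp.pdb
basic   acidic  distance_A
A131    A187    3.0
A232    A180    3.0
A238    A459    3.0
A232    A674    3.301
...
```

Fit dissociation constants for the four assay conditions (synthetic
curves generated with the reported affinities as ground truth, 2% noise):

```sh
$ powerstroke fit-kd --csv fx/binding_curves.csv --fix-n 1
condition  kd_uM    hill_n  amplitude  baseline  rss
+Mg        36.787   1.0     1.0054     -0.0021   0.00216
-Mg        134.929  1.0     0.9929     -0.0041   0.00495
+bleb+Mg   19.023   1.0     1.0042     -0.0167   0.010187
+bleb-Mg   43.761   1.0     0.9859     0.0158    0.006741
```

Each fitted K_D lands close to its generating value (37.5, 145.8, 21.2,
40.6 µM); the −Mg/+Mg ratio reproduces the ~4-fold magnesium effect on
ADP affinity.

The full reconstruction — cleft-closure TMD, converter-rotation TMD with
the cleft restrained, unbiased relaxation, four-vector SMD release, the
pathway energy profile with its minima, and state metrics on the start,
intermediate and end frames — runs from one command and writes a
checksummed manifest:

```sh
powerstroke run-all --out run --seed 1
```

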