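# Methods

This note documents the models behind `powerstroke`, the parameters that
matter, and the design decisions taken where the problem was genuinely
open. It states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## State metrics

The actin-binding cleft is measured as two Cα–Cα distances on author
(deposited) residue numbering of the *Dictyostelium* myosin-II motor
domain: inner cleft Ser272–Ser465, outer cleft Ser416–Lys589. Landmark
values for classification are the printed metrics of the three reference
conformations — pre-power stroke 12.6/13.4 Å, ADP-release 11.7/11.3 Å,
rigor-like 10.7/10.2 Å — with converter rotations of 0°, 55° and 60°
from the up position. Classification normalizes each metric (1 Å for
distances, 10° for angles, putting the ~1 Å cleft steps and ~5° rotation
steps on comparable footing) and picks the nearest landmark in Euclidean
distance; exact ties resolve to the earlier state in the fixed order
pre-power-stroke < ADP-release < rigor-like.

Converter rotation uses the standard core/domain decomposition: Kabsch
superposition on the N-terminal core (Cα of residues 2–80 by default),
then the axis-angle magnitude of the least-squares rotation carrying the
reference converter (690–750) onto the target converter. No community
standard fixes the core selection, so both selections are arguments; the
quoted tolerances (0.05 Å for direct distances, 0.1 Å for RMSD, 3° for
rotations) absorb printed-value rounding and pairing ambiguity. Residue
pairing between structures is the intersection of author residue numbers
with the atom present in both, because deposited structures differ in
resolved termini. Superposition itself is delegated to
`scipy.spatial.transform.Rotation.align_vectors`; degenerate (collinear)
selections are rejected because the rotation is not identifiable.

P-loop displacement is the mean Cα shift of residues 179–186 after core
superposition. The P-loop motif is the Walker A sequence GESGAGKT
(179–186); Glu187 closes the loop and forms the nucleotide groove with
Arg131.

## Interaction criteria

Crystal structures carry no hydrogens, so the default hydrogen-bond
criterion is purely geometric: two N/O/S heavy atoms of different
residues within 3.5 Å. When explicit hydrogens are present, a D–H···A
angle ≥ 120° is additionally required. Salt bridges pair Arg/Lys/His
charged-group nitrogens with Asp/Glu carboxylate oxygens within 4.0 Å
(minimum distance per residue pair); histidine counts as basic only with
both imidazole nitrogens resolved, since protonation is unknowable from
coordinates. These are common literature conventions; every cutoff is an
argument, and counts that depend on the unknown criteria behind reported
interaction totals are reported, not asserted.

Occupancy over a trajectory is 100 × (simultaneous bonds summed over
frames)/n_frames per residue; values above 100% are meaningful (a
residue holding two bonds in every frame scores 200%), which is how
multi-dentate anchors such as the P-loop lysine appear.

## Coarse-grained engine

The protein is a Cα elastic network: one bead per residue (110 amu),
stiff virtual bonds between chain neighbours (50 kcal mol⁻¹ Å⁻²), and
harmonic contacts (default 1 kcal mol⁻¹ Å⁻²) between all bead pairs with
sequence separation ≥ 3 within 10 Å, at their build-time distances. ADP
is four beads — adenine, ribose, α- and β-phosphate — chained together
and coupled to protein beads within 5 Å by native-contact springs
(2 kcal mol⁻¹ Å⁻² unless overridden) that can be flagged breakable: a
breakable spring detaches permanently once stretched 1.5 Å past its rest
length (per-contact overrides let a fixture encode which anchors resist
longest; rupture force for a harmonic-to-plateau contact is k × the
break extension). Compact folded regions (the converter and the core it
docks against) can be declared rigid: springs internal to the union of
those ranges are stiffened ×25, which keeps the small toy converter from
diffusing orientationally at 310 K while leaving its coupling to the
rest of the network soft. Mg²⁺ is not modelled as a bead: the release
conformation has lost its magnesium coordination.

Integration is BAOAB Langevin in internal units kcal mol⁻¹ / Å / amu /
ps (acceleration conversion 418.4, k_B = 0.0019872041 kcal mol⁻¹ K⁻¹).
At zero friction and temperature the scheme reduces to velocity Verlet;
with the default 2 fs step the stiffest default spring (chain bonds,
period ≈ 0.46 ps) is resolved ~230-fold, and the unthermostatted energy
drift over 10⁴ steps is below 10⁻⁴ relative at 1 fs (the tolerance used
by the conservation test). All runs are pure functions of their seeds
and reproduce bitwise. Forces are reported in pN via
1 kcal mol⁻¹ Å⁻¹ = 69.48 pN.

### Targeted MD

The biasing potential is a harmonic penalty on the gap between the
current best-fit RMSD of the biased atoms to a target and a scheduled
reference: V = (k/2N)·[RMSD(t) − RMSD*(t)]², with the superposition
recomputed at every evaluation and RMSD*(t) decreasing linearly over the
stage. The gradient is evaluated at the per-step optimal superposition;
because the fit parameters are stationary at the optimum, this equals
the full best-fit gradient (validated against central finite differences
to 10⁻⁵ relative). The per-atom bias stiffness scales as k/N², so tight
schedule tracking on the elastic network requires k well above the
network stiffness times N²; the pipeline default is 2000 kcal mol⁻¹ Å⁻²
(the all-atom protocol's 200 scaled by a ×10 coarse-grain calibration,
exposed in the configuration). N is always computed from the configured
selection and reported in the manifest, never assumed.

### Steered MD

The ligand centre of mass, projected on a unit reaction coordinate ξ, is
tethered to a reference moving at constant velocity:
V = k/2·(v·t − s)², with k = 4 kcal mol⁻¹ Å⁻² and v = 0.005 Å ps⁻¹ as
the method defaults. The recorded pulling force is the spring force; the
force on each pulled bead is mass-weighted. The pipeline pulls at
0.5 Å ps⁻¹ so that a 40 ps desk-scale run covers a ~20 Å unbinding path;
this changes absolute force scales (loading rate) but not the relative
comparisons the pipeline makes. During pulling all protein beads are
positionally restrained (5 kcal mol⁻¹ Å⁻²), the coarse analogue of the
backbone restraint sets the all-atom protocol uses against drift.

## Pipeline

The reconstruction runs: thermal relaxation of the ligand-bound
open-cleft start → stage-1 TMD closing the cleft (bias on the cleft
marker blocks) toward a strong-ADP-like intermediate → stage-2 TMD
rotating the converter 55° toward the down position while the cleft is
positionally restrained, with the P-loop region biased to shift toward
the front entrance of the active site and the nucleotide following its
pocket unbiased → unbiased relaxation → four-vector SMD release in
duplicate. An elastic network is single-basin by construction, so
equilibration *around* the post-stroke state is modelled by re-anchoring
the network at the stage-2 endpoint for the relaxation and release
stages — the coarse-grained analogue of relaxing in the new basin; the
alternative (relaxing in the start-pose network) simply replays the
transition backwards. Default stage lengths (2000–6000 steps of 2 fs)
complete the whole pipeline in well under ten minutes on one CPU; every
stage seed, parameter and artifact checksum lands in the manifest, and
rerunning a configuration reproduces identical checksums.

The release directions are a 25° cone of four unit vectors around the
outward axis from the protein centre of mass through the ligand. The toy
complex encodes the strong β-phosphate–Thr186 and adenine-groove–Arg131
anchors by giving those native contacts higher stiffness (6 kcal mol⁻¹
Å⁻²) and a doubled rupture extension (3 Å); the release experiment
reports, per profile, the rupture order and the contacts that never
break within the pull.

## Energy profile surrogate

End-point implicit-solvent scoring (the MM/GBSA class of methods) is not
a desk-scale computation, and this package deliberately does not claim
its absolute energies. The per-frame score is an explicitly labelled
surrogate with the same role — rank conformations along a pathway and
locate low-energy states: a 12-6 Lennard-Jones term (ε = 0.2 kcal mol⁻¹,
r_min = 3 Å between beads), Coulomb screened by the distance-dependent
dielectric ε(r) = 4r (i.e. 332.0636·q_iq_j/(4r²) kcal mol⁻¹) over coarse
unit charges (Arg/Lys +1, Asp/Glu −1, the two phosphate beads −1), and a
favourable smooth buried-contact term (−0.1 kcal mol⁻¹ per contact,
switched off between 4 and 8 Å). Pairs beyond 30 Å contribute exactly
zero, so a dissociated ligand scores zero. Outputs are kJ mol⁻¹
(1 kcal = 4.184 kJ). Profiles are smoothed with a centered moving
average (11 frames by default; the pipeline uses 75 because its frames
are 20 fs apart) and minima are local minima of the smoothed series with
prominence ≥ 2 kJ mol⁻¹ via `scipy.signal.find_peaks`. The surrogate is
validated by closed forms and brute-force double-loop oracles, and by
the constructed two-minimum pathway fixture; barrier heights are
reported, not compared to all-atom magnitudes.

## Binding fits

The Hill model S(c) = baseline + amplitude·cⁿ/(K_Dⁿ + cⁿ) is fit by
bounded nonlinear least squares with a 12-point log-spaced K_D start
grid spanning the measured concentrations; K_D is optimized on a log
scale, which conditions the problem and makes the fit exactly
scale-equivariant. The Hill coefficient is free but bounded to [0.5, 3]
by default; `fix_n`, `fix_amplitude` and `fix_baseline` pin parameters.
Free ligand is approximated by total ligand (no depletion correction):
the labelled protein sits at 10 nM, orders of magnitude below the lowest
ADP concentration in the series. Uncertainty is a case-resampling
bootstrap percentile interval; the reported intervals are percentile
bootstrap, not fit standard errors.

The K_D-recovery protocol (also used by `scripts/acceptance.py`)
generates 16-point 1:1 dilutions from 10 mM with additive Gaussian noise
of 2% of the normalized signal range — the dilution design of the
thermophoresis assay; the noise level and replicate count are not
reported for the original data, so 2% is this repository's choice of a
clean optical assay. Because the generated signal is normalized fraction
bound and the assay is single-site, recovery fits the Hill equation
proper with n = 1 and amplitude/baseline pinned at 1/0. With amplitude
and baseline left free the estimator's spread roughly doubles; the
protocol choice reflects what "fitting normalized data with the Hill
equation" means, not a statement that free-parameter fits are wrong.

## What the synthetic fixtures do and do not show

The toy motor is a metric test jig, not a fold: four spatial groups
(N-terminal-like core, U50-like, L50-like, converter-like) carrying the
real residue numbering, marker pairs placed at exactly the requested
cleft widths, a converter helix rotated rigidly by the requested angle,
side-chain tips positioned to realize the named salt bridges, and a
four-bead ADP in the P-loop/purine-loop slot. Passing metric tests on
the jig demonstrates the correctness of the geometry code (distances,
rotations, detection criteria) to machine precision; it says nothing
about force-field realism, and the coarse-grained pathway demonstrates
the biasing machinery and the qualitative two-minimum,
consistent-release-force structure of the reconstruction — not all-atom
peak forces (~2000 pN), occupancy percentages, or ~30 kJ mol⁻¹ barrier
heights, which are out of reach at this resolution by design. Checks
against the deposited crystal structures (cleft widths, the 0.54 Å rigor
superposition, the ~55° converter rotation, the Arg232 hub) live in the
acceptance tests and require the one-time download script, since
structure files are not shipped with the repository.

## Numerical choices and degenerate inputs

* PDB I/O goes through gemmi; first model only, HETATM retained, blank
  and 'A' alternate locations kept (deterministic single-conformer
  geometry), waters excluded from interaction analysis unless selected
  by name. Coordinates round-trip to the format's 3-decimal precision.
* Selections matching zero atoms raise instead of returning empty — a
  silent empty selection hides residue-range typos.
* Superpositions with fewer than 3 paired atoms or collinear geometry
  are rejected; TMD requires ≥ 3 biased atoms for the same reason.
* The TMD gradient is zero exactly at RMSD = 0 (the gap term vanishes
  faster than the 1/RMSD factor diverges; guarded numerically).
* Dynamics abort with a stage-tagged diagnostic when the potential
  exceeds 10⁸ kcal mol⁻¹ or turns non-finite.
* Bond rupture is deliberately non-conservative (the spring's stored
  energy is dropped at detachment); energy-conservation checks therefore
  run on models with permanent contacts.
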