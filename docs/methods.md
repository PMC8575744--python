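# Methods

This note records the models, estimators, conventions and numerical
choices behind `xanmem`, and what the synthetic-bilayer validation does
and does not demonstrate.

## Units, geometry, formats

All internal coordinates are Ångström and all times picoseconds; GRO
files (nanometres) are converted on read and write.  Boxes are
orthorhombic only — triclinic input is rejected with a clear error rather
than silently mishandled.  Minimum-image arithmetic is used for every
distance; molecules are assumed whole (never split across the periodic
boundary), which the synthetic generator guarantees by construction.
Frame times default to `index × 1 ps` when the format carries none,
matching the 1 ps recording interval of the reference systems.  Dihedrals
follow the IUPAC convention (cis = 0°, trans = 180°, range (−180°, 180°]),
cross-checked in the tests against MDAnalysis.

Atom selection is role-based: analyses ask for chemical roles (`Op` =
non-esterified phosphate oxygens O13/O14, `Oc` = carbonyl O22/O32, `Og` =
glycerol O21/O31, choline N/CH₃, xanthophyll OH oxygens per ring, polyene
methyls per chain half, ...), and an `AtomClassMap` binds roles to
(residue, atom-name) patterns.  A shipped default covers POPC with
Sundaralingam head-group numbering, LUT/ZEA carotenoid names and 3-site
water, plus the generator's pseudo-atom names; custom YAML maps override
it.  A stage that needs an empty role refuses to run instead of returning
vacuous numbers.

## Torsion dynamics

Ring torsions are reduced to two-state traces.  State windows default to
centre ± 40° for the ε ring (130°, −50°) and centre ± 25° for the β ring
(+30°, −30°) — widths chosen to cover the observed oscillation bands
(roughly 100–150° around the 130° minimum) while keeping windows disjoint
on the circle; both are configurable because the operational definition of
a "transition" versus a fluctuation is a judgement call.  Frames outside
every window are `unassigned` and transparent: they do not break a dwell.
`min_dwell` (default 0 ps, i.e. even sub-200 ps excursions count) filters
excursions shorter than the given persistence.  All angular arithmetic is
circular (differences reduced into (−180°, 180°]); population histograms
are densities (Σ density × bin = 1, default bin 5°) so different
trajectory lengths compare directly.

## Orientation

Per frame and leaflet, the interface is referenced by the mean z of the P
atoms and of the glycerol oxygens; leaflets are assigned by the sign of
z minus the instantaneous bilayer centre (midpoint of the leaflet P
means).  The interfacial slab of a leaflet is the band between its
glycerol-O and P reference planes padded by `tol` = 2 Å.  A molecule is
**V** when its two ring centres of mass (mass-weighted; the geometric
variant differs negligibly for the symmetric ring clusters used here) lie
in opposite slabs, **H** when both lie in the same slab, **transit**
otherwise.  Frame flicker is suppressed by a running-majority filter
(default window 1 ns), and a reorientation event is a maximal transit run
bounded by two different stable labels; its reported time is the start of
the new stable label.  Detection accuracy is therefore bounded by
smoothing + frame stride, which is the tolerance used in all timing tests.

The polyene-plane label of a horizontal molecule is `beta_up` when the
β-half methyls sit above the ε-half methyls for an upper-leaflet molecule
(mirror logic in the lower leaflet), i.e. the β-ring OH faces the water
phase.  The long-axis rotation angle θ uses the MET–C13 bond sampled every
100 ps: for vertical molecules the angle of its x–y projection against the
x axis; for horizontal molecules the angle from the z axis within the
vertical plane perpendicular to the long axis (the plane the bond sweeps
as the molecule rolls).  Unwrapping takes nearest-image angular steps, so
sampling must be fast enough that true steps stay below 180°.

Hydrophobic width is operationalised as the distance between the leaflet
mean carbonyl-oxygen (Oc) z planes; the role is a parameter, so acyl-C2
planes can be substituted.  Molecular length is the C3–C3′ distance.
Aggregation monitoring reports episodes in which the minimum heavy-atom
distance between two xanthophylls stays below a cutoff (default 4 Å) for
a minimum number of consecutive frames; transient single-frame contacts
are thereby ignored.

## Polar contacts

H-bonds use a geometric criterion: donor–acceptor oxygen distance
≤ 3.25 Å and donor–H···acceptor angle (at the hydrogen) ≥ 135°.  The
literature on carotenoid–lipid H-bonding names the interactions without
printing cutoffs, so these defaults follow common practice for water and
lipid oxygens; they are explicit parameters and every summary records the
criteria used.  OH ↔ water is evaluated in both donor directions; PC
oxygens only accept.  Water bridges are counted at pair level: a bridge
exists between an OH group and a PC oxygen when at least one water is
H-bonded to both in the same frame, and two bridging waters still count
once — this avoids double counting and makes the bridge set a function of
the H-bond sets.  Charge pairs use a plain distance cutoff (4 Å) from the
OH oxygen to the nearest choline N or methyl carbon.  Neighbour searches
run on periodic KD-trees; the test suite proves exact equivalence with
naive 27-image double loops on hundreds of random frames.

Contact tables report time-and-ensemble means per OH group and per ps,
grouped by ring and, when orientation labels are supplied, by H/V with
transit frames excluded; the "All" row is the exact sum of the PC-oxygen
classes before rounding.

## Lifetime decay and multi-exponential fitting

The returns-allowed statistic: C(τ) = ⟨Σ_pairs 1[on at t₀]·1[on at
t₀+τ]⟩ over evenly spaced origins (default stride 1 ns, lag 5 ns,
spacing 1 ps).  Because returns are allowed there is no absorbing break
and C(τ) decays to the stationary re-encounter level rather than zero.
For a two-state telegraph bond the exact form is C(τ)/C(0) = p +
(1−p)e^{−(k_on+k_off)τ}, which the tests verify by simulation.

Fits minimise unweighted squared error on the linear scale for the model
C₀ Σ (Aᵢ/100) e^{−τ/Tᵢ} with Aᵢ ≥ 0 and Tᵢ > 0.  Parameterisation:
absolute amplitudes Bᵢ (reported as percentages of their sum, which makes
ΣAᵢ = 100 an identity, with C₀ = ΣBᵢ) via a squared variable, and log Tᵢ
bounded in [1 ms⁻¹-scale floor, 20 × lag].  Each restart seeds the
amplitudes by non-negative least squares at log-spaced trial time
constants (a separable/VarPro-style initialisation) and refines with
`scipy.optimize.least_squares`; 16 jittered restarts by default, best SSE
wins.  Standard errors come from the Gauss–Newton covariance at the
optimum.  If two fitted time constants lie within 5% of each other the
fit is flagged `degenerate` rather than silently reported.  There is no
additive constant: a plateau is absorbed by a large T₄, consistent with
the pure four-exponential form of the reference decomposition.  Residual
diagnostics report max |r|/C(0) and a Wald–Wolfowitz runs-test z score,
which flags structured misfit (e.g. fitting too few components).

Noiseless round trips of all five reference parameter rows recover every
Aᵢ and Tᵢ to machine precision (the acceptance threshold is 1% relative);
the slowest row (T₄ ≈ 9.5 ns) needs the lag extended to 30 ns to be
resolved, which the acceptance script does.

## Radial distribution functions

g(r) uses minimum-image distances, uniform bins (default 0.1 Å, cutoff
10 Å), and ideal-gas normalisation from the instantaneous full box volume
and target count (N−1 for self-RDFs).  In a bilayer slab the full-volume
density makes g(r) comparative — peak positions and relative heights are
meaningful, absolute coordination numbers are not.  A slab-corrected
normalisation is a known limitation, not implemented.  Water RDFs use the
water oxygen by default.

## The synthetic bilayer generator

The generator is the package's ground truth, not an MD substitute.  It
emulates the reference composition — 188 POPC, 6 xanthophylls, ~8,500
waters in an 80 Å box — as a statistical structure: lipids are
leaflet-anchored pseudo-molecules whose atoms jitter (σ_z = 0.5 Å,
σ_xy = 1 Å) about reference planes (P at ±20 Å, glycerol-O at ±15 Å,
carbonyl at ±15.15 Å, so the hydrophobic-width estimator returns 30.3 Å
by construction); xanthophylls are rigid rods with C3–C3′ = 28.3 Å.  The
ring "hexagons" lie perpendicular to the long axis with centres at the
rod ends, so each ring COM coincides with the end of the C3–C3′ segment —
this keeps vertical ring COMs inside the interfacial slabs (at ±14.15 Å)
and the measured length exactly equal to the preset under rigid motion.

Prescribed dynamics: ring torsions follow two-state Markov chains with
Gaussian angular noise (defaults: ε frozen in the 130° state — the
high-barrier isomerisation essentially never happens in the bilayer — and
β hopping at k = 0.001/0.002 ps⁻¹, stationary occupancies 2:1); torsion
atoms are placed each frame by a z-matrix (natural-extension) construction
whose sign is calibrated against the analysis dihedral at build time.
Orientation schedules place molecules H or V, with flips interpolated over
a transit window (default 20 ns) ending at the scheduled flip time —
matching the detector's "event time = start of the stable new label"
convention.  Rolls about the long axis encode the polyene-plane label for
horizontal molecules and Brownian rotation (default D = 0.06 deg²/ps) for
vertical ones.

Bonding is realised by telegraph processes per OH group and partner
class, with defaults chosen to sit in the reported ranges for vertical
molecules (two water slots at p = 0.65 each plus the bridge water ≈ 1.6
water H-bonds/OH·ps; direct phosphate H-bond p = 0.12; water bridge
p = 0.33; charge pair p = 0.70).  "On" states are realised as exact
geometry: water-donor slots at 2.8 Å with a hydrogen aimed at the OH
oxygen, a collinear phosphate oxygen for the direct H-bond, a
water + phosphate pair in series for the bridge, a choline nitrogen at
3.5 Å for the charge pair; "off" partners retreat to 6 Å or their natural
positions.  These geometries satisfy any reasonable criterion and fail
clearly outside it.  Incidental contacts with the jittered background
lipids can add small realistic extras (e.g. occasional carbonyl bridges);
truth-recovery tests therefore compare against the designed partner class.
Everything is deterministic per seed, bitwise.

What passing these tests shows: the estimators recover known torsion
kinetics, flip times, plane labels, contact statistics, decay spectra and
rotational diffusion from coordinates alone.  What they do not show:
correctness on real force-field conformers (flexible lipids, split
molecules, protonation variants), realistic densities, or lipid flip-flop
— real data should still be sanity-checked against the classmap warnings
and the reported criteria.

## Problem sizes

Test and acceptance runs use the full 188-lipid/6-xanthophyll leaflet
layout with reduced water counts (60–200) and spans from 2 ns at 2 ps
spacing up to 1.1 µs at 0.5 ns spacing; statistical stress tests of the
decay machinery bypass geometry entirely via the telegraph fast path
(up to 10⁴ pairs × 3×10⁴ frames).  These sizes give the Monte-Carlo
bands quoted in the tests (3σ unless stated) while a full desk run of the
suite plus acceptance script completes in a few minutes.

## Known limitations

- Orthorhombic boxes only; no unwrapping of molecules split across
  boundaries (a warning-level concern for real data).
- RDF normalisation is not slab-corrected.
- The H-bond criterion is geometric only; energetic definitions are out
  of scope.
- Reorientation timing resolution is limited by smoothing + stride by
  design; sub-window events are invisible.
- The four-exponential model is descriptive: component count is a user
  choice, guarded by the degeneracy flag and residual runs test rather
  than by model selection.
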