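# xanmem

Trajectory analysis of xanthophylls — the polar carotenoids lutein and
zeaxanthin — in phosphatidylcholine (POPC) bilayers.

Xanthophylls carry a hydroxylated ionone ring at each end of a conjugated
polyene chain.  In a membrane they sit either *vertically* (transmembrane,
one ring anchored at each interface) or *horizontally* (both rings in one
leaflet's interfacial region), and their behaviour is governed by a small
set of measurable statistics: the two-state "hopping rotation" of the ring
torsions (ε ring: 130° ↔ −50°, β ring: +30° ↔ −30°), reorientation between
the horizontal and vertical positions, rotation about the long molecular
axis, the polar contacts of the OH groups (H-bonds, water bridges, choline
charge pairs), and the lifetimes of those contacts.  `xanmem` implements
all of these as a tested, reusable library for MD practitioners working on
carotenoid–membrane systems, plus a ground-truth synthetic-bilayer
generator so that every estimator can be validated without running MD.

## What it computes

| module         | statistic |
| -------------- | --------- |
| `core`         | GRO/PDB multi-frame I/O, minimum-image geometry, IUPAC dihedrals, mass-weighted COM |
| `torsions`     | ring-torsion series, circular population densities, two-state assignment, dwell times, hopping rates |
| `orientation`  | leaflet interface references (P / glycerol-O planes), H/V/transit classification, reorientation events, β-up/β-down polyene-plane labels, long-axis rotation angle θ, C3–C3′ length, hydrophobic width, aggregation monitoring |
| `contacts`     | per-ps H-bond / water-bridge / charge-pair detection, pair×frame event matrices, per-OH contact tables, firm-bonding duration rasters |
| `lifetime`     | returns-allowed decay curves `C(τ)` with multi-origin averaging; constrained fits `C(τ) = C₀ Σᵢ (Aᵢ/100) e^{−τ/Tᵢ}` with Aᵢ ≥ 0, ΣAᵢ = 100, multi-start + NNLS seeding, standard errors and residual diagnostics |
| `rdf`          | minimum-image radial distribution functions |
| `synthetic`    | deterministic slab generator: 188 POPC / 6 xanthophyll / ~8,500 water composition, prescribed torsion kinetics, scheduled flips, telegraph bonding, rotational diffusion |
| `pipeline`/CLI | config-driven end-to-end runs writing CSV/JSON reports |

The central lifetime statistic: at an origin time the bonds present are
recorded, and `C(τ)` counts how many of them are present again at lag τ —
re-formed bonds count (*returns allowed*).  Averaged over origins this
yields smooth decay curves that are well described by a sum of four
exponentials whose percentage contributions Aᵢ and time constants Tᵢ
(≈2 ps, ≈50–70 ps, ≈330–490 ps, ≈2–9 ns for hydroxyl–water H-bonds)
characterise the hydration dynamics of the ring OH groups.

## Worked example

```bash
python examples/04_lifetime_decay.py
```

prints

```
telegraph bonds: C(tau)/C(0) vs closed form, max deviation 0.014

zeaxanthin beta-ring OH...water decay, four-exponential fit:
                A_i (%)   T_i (ps)
 component 1      22.46        2.2
 component 2      30.52       72.1
 component 3      31.51      488.7
 component 4      15.51     2981.3
sum A_i = 100.00 %, max |residual|/C(0) = 2.8e-16
```

The first line validates the decay statistic itself: on simulated
two-state (telegraph) bonds the normalised curve matches the closed form
`p + (1−p)e^{−(k_on+k_off)τ}` to within Monte-Carlo error.  The table is a
round trip: a noiseless curve is generated from the reference zeaxanthin
parameter set and the constrained fit returns every contribution and time
constant — machine-precision residuals confirm the decomposition is exact.
The other examples cover torsion hopping (`01`), orientation flips and the
structural scalars — apparent length 2.83 nm vs hydrophobic width 3.03 nm
(`02`), polar-contact counting against telegraph truth (`03`), and RDFs
(`04`, `05`).

A thin CLI wraps the pipeline for shell use:

```bash
xanmem synth --duration 2000 -o slab.gro
xanmem all -t slab.gro -o report/
```

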