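"""Reference parameter sets for xanthophyll/POPC bilayer analyses.

``DECAY_PRESETS`` holds literature four-exponential decompositions of the
hydroxyl-water H-bond decay (returns-allowed statistic) for zeaxanthin and
lutein rings in a POPC bilayer: percentage contributions ``fractions``
(A_i) and time constants ``taus`` (T_i, ps), component order ascending in
T.  They serve as generator inputs for round-trip validation of the decay
fitting machinery and as realistic defaults.

Geometry presets mirror the same system: leaflet P planes at +-20 A,
glycerol-O at +-15 A, carbonyl planes at +-15.15 A (hydrophobic width
30.3 A), and an apparent C3-C3' xanthophyll length of 28.3 A.
"""

from __future__ import annotations

DECAY_PRESETS: dict[str, dict] = {
    # vertical zeaxanthin beta-ring
    "ZEA": {
        "fractions": (22.46, 30.52, 31.51, 15.51),
        "taus": (2.17, 72.1, 488.7, 2981.3),
    },
    # horizontal lutein, epsilon and beta rings
    "LUT_H_eps": {
        "fractions": (23.07, 27.11, 34.41, 15.41),
        "taus": (1.35, 64.2, 396.7, 2692.7),
    },
    "LUT_H_beta": {
        "fractions": (20.06, 29.86, 35.42, 14.65),
        "taus": (1.69, 68.0, 476.1, 9481.5),
    },
    # vertical lutein, epsilon and beta rings
    "LUT_V_eps": {
        "fractions": (23.18, 29.96, 31.81, 15.05),
        "taus": (1.42, 50.0, 332.5, 1808.7),
    },
    "LUT_V_beta": {
        "fractions": (23.98, 31.25, 34.44, 10.33),
        "taus": (1.84, 58.2, 380.9, 3170.3),
    },
}

#: Leaflet reference planes (A) and molecular geometry defaults.
GEOMETRY = {
    "p_plane": 20.0,
    "og_plane": 15.0,
    "oc_plane": 15.15,     # gives hydrophobic width 30.3 A between leaflets
    "rod_length": 28.3,    # apparent C3-C3' distance, A
    "box": (80.0, 80.0, 80.0),
}

#: Bilayer composition of the reference systems.
COMPOSITION = {"n_popc": 188, "n_xan": 6, "n_water": 8500}
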