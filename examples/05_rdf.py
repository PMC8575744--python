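"""Radial distribution functions around the xanthophyll.

Computes minimum-image RDFs on a synthetic bilayer: hydroxyl oxygen vs
water oxygen (H-bonding shows as a sharp first peak near 2.8 A) and the
polyene-chain carbons vs lipid acyl carbons (featureless, comparative).
"""

import numpy as np

from xanmem import compute_rdf, default_classmap, default_truth, generate

truth = default_truth(duration=400.0, seed=9, n_water=120, n_popc=60)
traj, _ = generate(truth, duration=400.0, spacing=2.0)
cm = default_classmap(traj)

oh_water = compute_rdf(traj, cm.require("xan_OH_O"), cm.require("water_O"),
                       r_max=10.0, bin_width=0.1)
peak_bin = np.argmax(oh_water.g)
print(f"OH...water RDF: first peak at r = "
      f"{oh_water.bin_centers[peak_bin]:.2f} A, g = {oh_water.g[peak_bin]:.0f}")

cc = compute_rdf(traj, cm.require("polyene_C"), cm.require("acyl_C"),
                 r_max=10.0, bin_width=0.2)
print(f"polyene-acyl C-C RDF: mean g over 4-10 A = "
      f"{cc.g[cc.bin_centers > 4].mean():.2f}")
print()
print("The sharp hydroxyl-water peak at the H-bond distance (2.8 A) is the")
print("RDF signature of hydration of the ring OH groups; the flat C-C")
print("profile reflects the unstructured synthetic acyl background.")
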