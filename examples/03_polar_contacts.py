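"""Counting the polar interactions that anchor xanthophyll OH groups.

Detects hydroxyl H-bonds (to water and to PC phosphate/carbonyl oxygens),
water bridges and choline charge pairs every frame, and compares the
time-and-ensemble means per OH group against the generator's telegraph
truth.
"""

from xanmem import default_classmap, default_truth, generate
from xanmem.contacts import build_event_matrix, duration_panels, summarize_contacts

truth = default_truth(duration=2000.0, seed=3, n_water=80, n_popc=60)
traj, truth = generate(truth, duration=2000.0, spacing=2.0)
cm = default_classmap(traj)
expected = truth.expected_means()

hb = build_event_matrix(traj, "hbond", cm)
wb = build_event_matrix(traj, "water_bridge", cm)
cp = build_event_matrix(traj, "charge_pair", cm)

s = summarize_contacts(hb)
n_oh = 2 * truth.n_xan
for cls, key in (("water", "water"), ("Op", "Op")):
    got = s[s.partner == cls].mean_per_ps.mean()
    print(f"H-bonds with {cls:6s}: {got:.2f} /OH/ps  (truth {expected[key]:.2f})")
wb_op = [i for i, b in enumerate(wb.pairs) if b.partner_class == "Op"]
print(f"water bridges (Op) : "
      f"{wb.matrix[wb_op].sum() / wb.matrix.shape[1] / n_oh:.2f} /OH/ps  "
      f"(truth {expected['bridge']:.2f})")
print(f"charge pairs       : "
      f"{cp.matrix.sum() / cp.matrix.shape[1] / n_oh:.2f} /OH/ps  "
      f"(truth {expected['choline']:.2f})")

panels = duration_panels(hb)
longest = max((max((e[2] for e in p["episodes"]), default=0)
               for p in panels.values()))
print(f"\nlongest continuous firm-bonding episode: {longest} frames")
print("Water H-bonds dominate (about 1.6 per OH per ps); direct lipid")
print("contacts are sparser but re-form many times, which is what the")
print("duration panels (dot rasters) record per partner molecule.")
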