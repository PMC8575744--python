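"""Orientation classification and reorientation timing.

Builds a 20 ns synthetic bilayer in which two horizontally placed
xanthophylls rotate to the transmembrane (vertical) orientation, the
transit completing at 9 ns, and shows that the classifier recovers the
scheduled flip time.  Also reports the polyene-plane (beta-up/beta-down)
labels of the molecules that stay horizontal, and the structural scalars.
"""

from xanmem import default_classmap, default_truth, generate
from xanmem.orientation import (
    hydrophobic_width, molecular_length, orientation_series, plane_orientation,
)

duration, spacing = 20_000.0, 20.0
truth = default_truth(duration, seed=21, n_water=60, n_popc=60,
                      transit_duration=4000.0)
traj, truth = generate(truth, duration, spacing)
cm = default_classmap(traj)

oss = orientation_series(traj, cm, smoothing=500.0)
for i, (mol, s) in enumerate(oss.items()):
    frac_v = (s.labels == "V").mean()
    desc = f"molecule {mol[1]}: {frac_v:5.1%} vertical"
    for t0, t1, direction in s.events:
        desc += f"; {direction} completed at {t1 / 1000:.1f} ns"
    if truth.xan[i].initial == "H" and truth.xan[i].flip_time is None:
        desc += f"; polyene plane: {plane_orientation(traj, cm, s)}"
    print(desc)

length = molecular_length(traj, cm)["mean_A"].mean()
_, width, _ = hydrophobic_width(traj, cm)
print()
print(f"apparent C3-C3' length = {length / 10:.2f} nm; "
      f"hydrophobic width (carbonyl planes) = {width / 10:.2f} nm")
print("Scheduled flips completed at 9.0 ns; the detected end times above")
print("agree within the smoothing window. The near-match of length and")
print("width is why vertical xanthophylls anchor one OH at each interface.")
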