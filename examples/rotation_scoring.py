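"""Count full rotations from a simulated heading trace and screen outliers.

A mouse with unilaterally increased dopamine release rotates
preferentially in one direction under amphetamine; the net rotation
count (CW - CCW) per session is the behavioral readout. The example
also screens a group of net counts for a single outlier with the
two-sided Grubbs test.
"""

from neurorestore import behavior, synth

trace, truth = synth.gen_rotation(
    synth.RotationSimConfig(
        cw_turns=9, ccw_turns=2, duration_s=120.0, jitter_sd=10.0, seed=5
    )
)
counts = behavior.count_rotations(trace)
print(f"simulated: {truth.cw} CW, {truth.ccw} CCW (net {truth.net})")
print(f"counted:   {counts.cw} CW, {counts.ccw} CCW (net {counts.net})")

# one animal in this synthetic control group is strongly CW-biased
net_per_mouse = [2, -1, 0, 3, -2, 1, 38]
res = behavior.grubbs_test(net_per_mouse, alpha=0.05)
print(
    f"Grubbs screen: G = {res.statistic:.3f} vs critical {res.critical:.3f} "
    f"(n = {res.n}, alpha = {res.alpha})"
)
if res.is_outlier:
    print(f"outlier: value {net_per_mouse[res.outlier_index]} -> removed from analysis")
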