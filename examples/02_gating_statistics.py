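"""Compare gating statistics across channel variants.

Builds a small two-variant suite (an open-biased wild-type-like condition
and a closing protonated-like condition), pools the equilibrated tail of
each trajectory and prints the per-variant summary: order-parameter
correlations, wet-cavity occupancy and distribution modes.
"""

import kvpore as kp

config = kp.AnalysisConfig()
suite = kp.make_variant_suite(
    variants=["WT-unprotonated", "Ep327-Hp418"],
    n_trajectories=3,
    base_spec=kp.ToyChannelSpec(n_frames=800),
    master_seed=7,
)

pooled = {}
for label, runs in suite.items():
    series = [kp.extract_series(frames, config, label) for frames, _ in runs]
    pooled[label] = kp.pool_window(series, config.window_fraction)

report = kp.variant_report(pooled, config)
print(report.to_string(index=False))

# The protonated-like variant closes: its wet occupancy drops, its dihedral
# distribution gains the straight-helix mode near 245 deg, and the latent
# open/closed mixing produces strong |r| between distance and dihedral.
# The wild-type-like variant stays open, so its correlations are weak.
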