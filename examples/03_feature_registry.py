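"""Compute the per-repetition feature registry for one repetition.

The registry holds 223 named scalar features per sensor (892 per
repetition over the four sensors): descriptive statistics of thirteen
scalar signals, triad features (correlations, energy, signal magnitude
area), spectral descriptors, and movement-smoothness measures (log
dimensionless jerk, sample entropy, spectral arc length).
"""

from aclgait import features, preprocess, synth

spec = synth.CohortSpec(seed=1)
rep = synth.generate_repetition(spec, "acl_00", 0)
aligned = preprocess.align_repetition(rep)

registry = features.default_registry()
vector = features.extract_features(aligned, registry)

print(f"registry size: {len(registry)} features "
      f"({len(registry) // 4} per sensor)")
print(f"flagged (undefined) values: {len(vector.flagged)}")

show = [
    "left_shank__gyro_x__rms",         # mediolateral angular-rate magnitude
    "left_shank__jerk_z__sd",          # vertical jerk variability
    "left_shank__accel_mag__iqr",      # acceleration-magnitude spread
    "left_shank__gyro_x__dominant_frequency",
    "left_shank__accel_z__sampen",     # regularity of the vertical accel
    "left_shank__accel_z__sparc",      # smoothness (more negative = rougher)
]
print("\nselected features for the affected (left) shank:")
for name in show:
    print(f"  {name:42s} {vector.values[name]: .4f}")
# jerk- and smoothness-related features on the affected limb are the
# ones that carry the injected post-ACL roughness contrast
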