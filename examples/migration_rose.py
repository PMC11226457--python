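"""Angular statistics of a synthetic collective-migration velocity field.

Vectors slower than 10 um/h are filtered out, the rest binned into 12 x 30
degree bins; each bin's frequency times its mean speed is the relative
angular speed.  A Gaussian fit to the frequency histogram gives the major
angular component (0 degrees = the outward wound normal).
"""

import numpy as np

from ajmech import migration, synth

fields, truth = synth.gen_velocity_fields(mean_angle_deg=0.0,
                                          angular_concentration=4.0,
                                          seed=5)
dist = migration.angular_distribution(fields)
fit = migration.gaussian_major_angle(dist)

print(f"{'bin':>14}  {'freq':>6}  {'rel speed (um/h)':>16}")
for lo, hi, fr, rs in zip(dist.bin_edges_deg[:-1], dist.bin_edges_deg[1:],
                          dist.frequency,
                          dist.relative_angular_speed_um_h):
    print(f"[{lo:6.0f},{hi:5.0f})  {fr:6.3f}  {rs:16.2f}")

print(f"\nretained vectors : {dist.n_retained}")
print(f"major angle      : {fit.mean_deg:.1f} deg (sd {fit.sd_deg:.1f} deg)")
print()
print("Cohesively migrating tissue concentrates frequency and relative")
print("angular speed in the bin straddling 0 degrees; uncoordinated")
print("motion spreads both across bins and widens the fitted Gaussian.")
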