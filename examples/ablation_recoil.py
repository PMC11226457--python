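"""Initial recoil rate of an ablated junction from synthetic edge tracks.

Frames every 2 s from 6 s before to 30 s after the cut; the initial recoil
rate is the secant of the inter-edge distance over the first 2 s and is a
proxy for the tension the junction carried.
"""

import numpy as np

from ajmech import recoil, synth

rates = []
for s in range(20):
    track, _ = synth.gen_recoil_track(ballistic_rate=1.77, noise_um=0.05,
                                      seed=s)
    rates.append(recoil.initial_recoil(track))

print(f"true ballistic rate : 1.77 um/s")
print(f"mean initial recoil : {np.mean(rates):.3f} um/s "
      f"(sd {np.std(rates, ddof=1):.3f}, n = {len(rates)})")

table, anova, pairwise = recoil.compare_recoil({
    "wt": rates,
    "kd": [recoil.initial_recoil(
        synth.gen_recoil_track(1.34, noise_um=0.05, seed=100 + s)[0])
        for s in range(20)],
})
print(f"wt vs kd Sidak-adjusted p = {pairwise[('wt', 'kd')]:.2g}")
print()
print("A higher initial recoil means higher junctional tension; the")
print("group comparison mirrors how conditions are contrasted (one-way")
print("ANOVA with Sidak-corrected pairwise tests).")
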