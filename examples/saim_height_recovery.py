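"""Recover a protein's axial position from a synthetic SAIM angle stack.

A 64x64 field of fluorophores at 55.93 nm (the wild-type vinculin
N-terminus position) above the oxide surface is imaged over the 14-angle
sweep with 2% noise, fit per pixel, and summarized by the ROI median
(z-center).
"""

import numpy as np

from ajmech import saim, synth

sweep = saim.AngleSweep()            # 0-52 degrees in 4-degree steps
layers = saim.LayerStack()           # 488 nm over 500 nm thermal oxide

stack, truth = synth.gen_saim_stack(55.93, sweep=sweep, stack=layers,
                                    noise_frac=0.02, seed=1)
height_map, fits = saim.fit_stack(stack, sweep, layers)
roi = saim.roi_zcenter(height_map, np.ones(height_map.shape, bool))

print(f"ground truth height : 55.93 nm")
print(f"recovered z_center  : {roi.z_center_nm:.2f} nm "
      f"over {roi.n_pixels} pixels")
print(f"pixel height spread : {np.std(roi.pixel_heights_nm):.2f} nm (sd)")
print()
print("The z-center is the median fitted height over the ROI; at 2% image")
print("noise it recovers the true axial position to well under 2 nm, the")
print("scale on which the junctional proteins' terminus positions differ.")
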