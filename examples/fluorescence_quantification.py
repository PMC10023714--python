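"""Quantifying axonal innervation of brain targets from fluorescence images.

Builds synthetic brain-slice images with known ROI intensities, measures
normalized fluorescence (F/Fo = ROI mean / background mean), applies the
1.5 dense-innervation threshold, and localizes an innervated band with a
cross-section profile (30 um wide mask, 0.75 um stations, 6 um bins).
"""

import numpy as np
from shapely.geometry import box

import retinamosaic as rm

# -- F/Fo of two target regions over the same background ------------------
background_region = box(700.0, 50.0, 880.0, 230.0)
dense_target = box(100.0, 100.0, 260.0, 260.0)    # e.g. a contralateral IGL
sparse_target = box(400.0, 100.0, 560.0, 260.0)   # e.g. an OPN shell

image = rm.gen_fluor_image((300, 900), 1.0,
                           [dense_target, sparse_target],
                           [47.0, 28.4], background=20.0,
                           noise_sd=2.0, seed=0)

for name, region in [("dense target", dense_target), ("sparse target", sparse_target)]:
    m = rm.f_over_fo(image, region, background_region)
    call = "innervated" if rm.innervation_call(m) else "not innervated"
    print(f"{name}: F/Fo = {m.f_over_fo:.2f} -> {call} (threshold 1.5)")

# -- cross-section profile through a bright band ---------------------------
slice_img = np.full((300, 900), 20.0)
slice_img[:, 420:540] = 60.0  # innervated band at 420-540 um
profile = rm.cross_section_profile(slice_img, 1.0, mask_origin=(100.0, 150.0),
                                   mask_axis=(1.0, 0.0), length_um=650.0)
peak = profile.bin_centers_um[np.argmax(profile.values)]
print(f"profile peak at {peak:.0f} um from the mask origin "
      f"(band starts {420 - 100} um in)")

# The dense target clears the 1.5 threshold, the sparse one does not, and
# the profile localizes the innervated band to its true position.
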