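"""Gaussian-filter elastic registration along z.

Distorts every slice of a phantom stack with an independent smooth random
warp (high-frequency along z, like sectioning artifacts) and runs one
filtering sweep.  Because the filter acts on deformation fields along the
stack axis, it attenuates the slice-to-slice artifactual component while
leaving the smooth natural deformation of the phantom untouched — SSIM
against the undistorted truth rises, without over-aligning the stack.
"""

import numpy as np

from emalign import (apply_elastic_distortion, generate_phantom,
                     register_stack_elastic, slice_volume)
from emalign.evaluation import ssim

clean = slice_volume(generate_phantom((16, 192, 192), seed=5), 1)
distorted, gt = apply_elastic_distortion(clean, alpha=1.0, seed=6)

result = register_stack_elastic(distorted)

pre = np.array([ssim(distorted[i], clean[i]) for i in range(clean.n)])
post = np.array([ssim(result.stack[i], clean[i]) for i in range(clean.n)])
print("slice   SSIM before   SSIM after")
for i in range(clean.n):
    print(f"{i:5d}   {pre[i]:11.3f}   {post[i]:10.3f}")
print(f"\nmean SSIM vs truth: {pre.mean():.3f} -> {post.mean():.3f} "
      f"(gain {post.mean() - pre.mean():+.3f} from one sweep)")
mags = np.sqrt((result.fields ** 2).sum(axis=1))
print(f"median applied correction {np.median(mags):.2f} px "
      f"(injected distortions peak at 8 px)")
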