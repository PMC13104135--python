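"""Ground-truth-free registration quality report.

Scores a well-aligned phantom pair and a deliberately misaligned version
of the same pair with the multi-scale difference-filtering metric:
adjacent-slice difference -> Laplacian -> entropy, bilateral-split SNR,
and GLCM contrast on a difference-of-Gaussians pyramid.  On synthetic
stacks the entropy axis separates the two reliably (misalignment spreads
the Laplacian histogram); see the methods note for the observed behavior
of the SNR and contrast axes on phantoms.
"""

import numpy as np

from emalign import (SliceStack, add_gaussian_noise, apply_elastic_distortion,
                     apply_rigid_jitter, evaluate_stack, generate_phantom,
                     slice_volume)

clean = slice_volume(generate_phantom((16, 192, 192), seed=300), 1)
pair = SliceStack(clean.data[7:9].copy())
misaligned, _ = apply_rigid_jitter(pair, t_max=40, theta_max=15, seed=400)
misaligned, _ = apply_elastic_distortion(misaligned, alpha=1.0, seed=500)

registered = add_gaussian_noise(pair, 0.02, seed=600)
misaligned = add_gaussian_noise(misaligned, 0.02, seed=600)

rep_reg = evaluate_stack(registered).per_pair.iloc[0]
rep_mis = evaluate_stack(misaligned).per_pair.iloc[0]

print(f"{'metric':12s} {'registered':>12s} {'misaligned':>12s}")
for key in ["entropy", "snr", "con_0", "con_1", "con_2", "con_3"]:
    print(f"{key:12s} {rep_reg[key]:12.3f} {rep_mis[key]:12.3f}")
print("\nentropy (bits of the quantized Laplacian difference) is lower for "
      "the registered pair:\nits residuals concentrate near zero, while "
      "misalignment spreads them across the range.")
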