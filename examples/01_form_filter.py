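"""Build the three-region form filter and show its scale tolerance.

A plain Laplacian-of-Gaussian peaks only for blobs near its own scale;
the three-region kernel answers with the same peak for every blob radius
in its design interval [R1, R2].
"""

import numpy as np
from scipy import ndimage

from microcalc import FilterConfig, GrayImage, build_kernel, convolve
from microcalc.form_filter import log_value

cfg = FilterConfig(r1=2, r2=6)
kernel = build_kernel(cfg)
print(f"kernel geometry: R1={cfg.r1}, R2={cfg.r2}, sigma={cfg.sigma:.3f}, "
      f"halfwidth={cfg.kernel_halfwidth}")
print(f"alpha (tail renormalization) = {kernel.alpha:.4f}")
print(f"sum of weights = {kernel.weights.sum():+.2e} "
      f"(null-sum condition, positive sum {kernel.positive_sum:.4f})")

hw = cfg.kernel_halfwidth
idx = np.arange(-hw, hw + 1, dtype=float)
dx, dy = np.meshgrid(idx, idx)
plain = log_value(dx, dy, cfg.sigma)

print("\nbright disk of radius r on a dark background -> peak response:")
print(f"{'radius':>8} {'form filter':>12} {'plain LoG':>12}")
for radius in (2, 3, 4, 5):
    size = 64
    gy, gx = np.mgrid[:size, :size]
    img = np.where(np.hypot(gy - size // 2, gx - size // 2) <= radius, 100.0, 0.0)
    form_peak = convolve(GrayImage(img), kernel).max()
    log_peak = ndimage.correlate(img, plain, mode="reflect").max()
    print(f"{radius:>8} {form_peak:>12.2f} {log_peak:>12.2f}")

print("\nThe form-filter column is constant: any microcalcification with "
      "radius in [R1, R2]\nproduces the same detection signal, while the "
      "plain LoG loses half its response\nby radius 4-5.")
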