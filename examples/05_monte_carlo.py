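"""Monte-Carlo check of spectral reconstruction stability under noise.

Repeats the noise -> reconstruction cycle at several SNR levels and scores
the mean normalized spectrum against the ground truth. (The study design
uses 500 replicates; this demo uses 20 to run in seconds.)
"""

import numpy as np

import cortecs as c

scheme = c.build_protocol(seed=0)
gt = c.mixture_2d_default()  # 12x12 default grid
res = c.run_monte_carlo(
    gt, scheme, snr_levels=[25.0, 100.0, np.inf],
    radial_dir=np.array([1.0, 0.0, 0.0]),
    n_reps=20, seed=0, alpha=0.03,
)

print("SNR      MSE        SSIM    JSD")
for snr in res.snr_levels:
    s = res.scores[snr]
    print(f"{snr:>6}  {s['mse']:.3e}  {s['ssim']:.3f}  {s['jsd']:.3f}")
print("JSD (Jensen-Shannon divergence, base 2, 0 = identical) should fall "
      "as SNR rises: reconstruction accuracy improves with less noise. The "
      "residual JSD at infinite SNR is the smoothing bias of the fixed "
      "damping weight used here.")
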