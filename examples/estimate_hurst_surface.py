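"""Estimate the Hurst exponent of a synthetic rough surface.

Generates a 256 x 256 fractional Brownian surface with a known roughness
exponent, runs the full WTMM pipeline (gradient-wavelet transform, maxima
chains, space-scale skeleton, partition functions, tau(q) fit), and prints
the recovered exponent next to the ground truth.
"""

from mammofractal import estimate_hurst, generate_fbm_surface

TRUE_H = 0.65

image = generate_fbm_surface(side=256, hurst=TRUE_H, seed=7)
est = estimate_hurst(image)

print(f"ground-truth H      : {TRUE_H:.3f}")
print(f"estimated H         : {est.hurst:.3f} +- {est.stderr:.3f}")
print(f"monofractal         : {est.monofractal}")
print(f"tau(q) curvature    : {est.provenance['curvature']:+.4f}")
print(f"scaling range (px)  : {est.provenance['scaling_range'][0]:.1f}"
      f" - {est.provenance['scaling_range'][1]:.1f}")
print()
print("A single 256-px patch recovers H to within ~0.05 (one window-level")
print("standard deviation); the near-zero tau(q) curvature is what certifies")
print("the surface as monofractal, so a single H summarizes its roughness.")
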