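# mammofractal

Sliding-window multifractal analysis of mammographic tissue: per-region
Hurst exponents via the 2D wavelet transform modulus maxima (WTMM) method,
tissue-class maps, and bilateral breast-asymmetry statistics.

## The problem

Mammographic texture carries a physical signature of tissue organization.
Modeling local intensity fluctuations as a rough surface,
`E[(f(r+e) − f(r))²] ~ |e|^(2H)`, the Hurst exponent `H` separates three
regimes: anti-correlated fluctuations (`H ≤ 0.45`, fatty tissue,
blue), long-range correlated fluctuations (`H ≥ 0.55`, dense tissue, red),
and uncorrelated fluctuations (`0.45 < H < 0.55`, yellow) — the last being
the signature of *tissue disruption*, a loss of microenvironment
homeostasis associated with tumor development. Scanning a mammogram with
overlapping 360-px windows (32-px steps, central 256-px core analyzed)
yields a class map per breast, summarized as percentages %B, %Y, %R and
the score %Y/%B. Comparing the two breasts of one patient gives a single
asymmetry number,

    YB Factor = (%Y/%B)_tumor / (%Y/%B)_opposite ,

which is ≈ 1 for symmetric breasts and > 1 when the tumor side carries
excess disrupted tissue relative to fatty tissue.

The per-window `H` comes from the 2D WTMM formalism: a Gaussian-smoothed,
scale-adapted gradient field `T_ψ = a∇T_θ`; modulus-maxima chains at each
scale `a`; maxima lines linked across scales into the space-scale skeleton
`L(a)`; partition functions `Z(q, a)` over the lines with
`Z(q, a) ~ a^τ(q)`; and a monofractality screen on the curvature of
`τ(q)` — for a monofractal surface `τ(q) = qH − 2` and the single slope
`H` characterizes the window. Windows without acceptable scaling are
rejected (gray).

Because clinical mammograms cannot ship with a software package, a
first-class synthetic module generates fractional Brownian surfaces with
known `H`, composite breast phantoms, and whole patient cohorts (104
patients: 43 ILC, 38 IDC, 23 benign, with a configurable tumor-side
disruption shift), so that every stage is validated against ground truth.

## A worked example

```python
from mammofractal import estimate_hurst, generate_fbm_surface

image = generate_fbm_surface(side=256, hurst=0.65, seed=7)
est = estimate_hurst(image)
print(f"estimated H: {est.hurst:.3f}  (monofractal: {est.monofractal})")
```

prints

```
estimated H: 0.611  (monofractal: True)
```

— the ground truth is 0.65 and a single 256² patch recovers it to within
about one window-level standard deviation (≈ 0.05); averaged over many
patches the estimator is unbiased to < 0.03. The `examples/` directory
holds short narrative scripts, one per capability:

* `examples/estimate_hurst_surface.py` — surface → WTMM → `H` with
  diagnostics;
* `examples/tissue_map_phantom.py` — two-texture phantom → sliding-window
  class map → %B/%Y/%R;
* `examples/cohort_statistics.py` — synthetic 104-patient cohort →
  YB Factors → rank-sum contrasts (prints the full contrast table).

A thin CLI covers the same ground from the shell:

```bash
mammofractal analyze-mammogram --image scan.png --out results/
mammofractal analyze-patient --tumor L.png --opposite R.png --out results/
mammofractal analyze-cohort --seed 1 --out cohort.csv
mammofractal compare-groups --metrics-csv cohort.csv --out contrasts.csv
```

All outputs (CSV/JSON/PNG) embed the configuration hash and reproduce
byte-identically under the same inputs and seed.

## Layout

```
src/mammofractal/
  image.py      grayscale containers, masks
  synthetic.py  fBm surfaces, phantoms, cohorts (ground truth)
  wtmm.py       the WTMM engine: transform → chains → skeleton → τ(q) → H
  windows.py    sliding-window protocol and tissue classification
  metrics.py    %B/%Y/%R, %Y/%B, YB Factor
  stats.py      rank-sum contrasts, Shapiro–Wilk, box plots
  io.py         lossless image I/O, segmentation fallback, run config
  cli.py        command-line interface
docs/methods.md   model, numerical choices, accuracy, limitations
examples/         runnable narrative scripts
```
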