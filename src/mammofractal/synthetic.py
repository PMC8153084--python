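"""Synthetic stimuli with known roughness: fBm surfaces, breast phantoms, cohorts.

Every downstream stage of the pipeline (Hurst estimation, window
classification, asymmetry metrics, cohort statistics) is validated against
surfaces generated here, whose Hurst exponent is known by construction.

Fractional Brownian surfaces are synthesized by Fourier spectral filtering:
Hermitian-symmetric white noise is shaped so the spectral density follows
``|k|^-(2H+2)``, which yields an isotropic Gaussian random field with
stationary increments of roughness ``H``. Synthesis happens on a grid several
times the requested side, followed by a center crop, so that neither the
periodicity of the discrete Fourier transform nor its infrared (box-size)
cutoff leaks into the analyzed portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import BreastRegionMask, GrayImage
from .windows import CLASS_DENSE, CLASS_DISRUPTED, CLASS_FATTY, CLASS_REJECTED, classify_hurst

#: ground-truth code for positions outside any textured region
CLASS_OUTSIDE = -1

#: Tissue-class groups of the study population and their sizes.
TABLE1_GROUP_SIZES: dict[str, int] = {
    "ILC": 43,
    "IDC1": 1,
    "IDC2": 27,
    "IDC3": 10,
    "fib_a": 12,
    "fib_m": 11,
}

CANCER_GROUPS = frozenset({"ILC", "IDC1", "IDC2", "IDC3"})
BENIGN_GROUPS = frozenset({"fib_a", "fib_m"})

#: Representative Hurst exponents used to texture phantom tissue classes.
CLASS_TARGET_H = {CLASS_FATTY: 0.30, CLASS_DISRUPTED: 0.50, CLASS_DENSE: 0.65}


def _fbm_field(
    side: int, hurst: float, rng: np.random.Generator, margin: int = 8
) -> np.ndarray:
    """Raw float fBm surface of unit variance, synthesized at ``margin`` times
    the requested side and center-cropped.

    The oversized grid pushes the infrared (box-size) cutoff of the discrete
    spectrum well below the analysis scales: with a tight margin the missing
    low-frequency power visibly flattens the modulus growth of smooth
    (high-H) surfaces across the usable scale range."""
    n = margin * side
    kx = np.fft.fftfreq(n)[None, :]
    ky = np.fft.fftfreq(n)[:, None]
    k = np.sqrt(kx * kx + ky * ky)
    k[0, 0] = np.inf  # zero the DC mode
    # amplitude spectrum ~ |k|^-(H+1)  =>  power spectrum ~ |k|^-(2H+2)
    amp = k ** (-(hurst + 1.0))
    noise = np.fft.fft2(rng.standard_normal((n, n)))
    surf = np.real(np.fft.ifft2(noise * amp))
    lo = (n - side) // 2
    surf = surf[lo : lo + side, lo : lo + side]
    surf = surf - surf.mean()
    sd = surf.std()
    if sd > 0:
        surf = surf / sd
    return surf


def generate_fbm_surface(
    side: int,
    hurst: float,
    seed: int,
    *,
    bit_depth: int | str = 8,
    pixel_size_um: float = 50.0,
) -> GrayImage:
    """Generate an isotropic fractional Brownian surface with known ``hurst``.

    Parameters
    ----------
    side
        Image side in pixels (>= 32; powers of two are fastest).
    hurst
        Target Hurst exponent, strictly inside (0, 1).
    seed
        Seed for the white-noise draw; identical seeds give identical images.
    bit_depth
        8 (default, matching digital mammograms), 12, or ``"float"``.

    Returns
    -------
    GrayImage
        The surface rescaled to the requested bit depth (full-range affine
        map for integer depths; unit-variance float otherwise).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if side < 32:
        raise ValueError("side must be >= 32")
    rng = np.random.default_rng(seed)
    surf = _fbm_field(side, hurst, rng)
    if bit_depth != "float":
        full = 2 ** int(bit_depth) - 1
        lo, hi = surf.min(), surf.max()
        surf = np.round((surf - lo) / (hi - lo) * full)
    return GrayImage(surf, pixel_size_um=pixel_size_um, bit_depth=bit_depth)


# ---------------------------------------------------------------------------
# Phantoms


@dataclass
class PhantomRegion:
    """One textured region of a phantom: a geometry plus target roughness.

    ``geometry`` is one of
      ``{"kind": "full"}``
      ``{"kind": "rect", "rows": (r0, r1), "cols": (c0, c1)}``  (pixel bounds)
      ``{"kind": "disc", "center": (r, c), "radius": px}``
      ``{"kind": "ellipse", "center": (r, c), "radii": (rr, rc)}``
    optionally carrying ``"exclude": [geometry, ...]`` to carve holes (e.g.
    a background region minus an embedded lesion disc).
    """

    geometry: dict
    target_h: float
    amplitude: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_h < 1.0:
            raise ValueError("target_h must lie in (0, 1)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def pixel_mask(self, side: int) -> np.ndarray:
        mask = self._shape_mask(self.geometry, side)
        for sub in self.geometry.get("exclude", []):
            mask &= ~self._shape_mask(sub, side)
        return mask

    @staticmethod
    def _shape_mask(geometry: dict, side: int) -> np.ndarray:
        kind = geometry["kind"]
        rr, cc = np.mgrid[0:side, 0:side]
        if kind == "full":
            return np.ones((side, side), dtype=bool)
        if kind == "rect":
            r0, r1 = geometry["rows"]
            c0, c1 = geometry["cols"]
            return (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        if kind == "disc":
            r, c = geometry["center"]
            rad = geometry["radius"]
            return (rr - r) ** 2 + (cc - c) ** 2 <= rad * rad
        if kind == "ellipse":
            r, c = geometry["center"]
            ar, ac = geometry["radii"]
            return ((rr - r) / ar) ** 2 + ((cc - c) / ac) ** 2 <= 1.0
        raise ValueError(f"unknown region kind {kind!r}")


@dataclass
class PhantomSpec:
    """Specification of a composite breast phantom."""

    image_side: int = 448
    mask_shape: str = "full_frame"  # or "half_ellipse_MLO"
    regions: list[PhantomRegion] = field(default_factory=list)
    background_level: float = 120.0
    bit_depth: int = 8
    taper_px: int = 16

    def __post_init__(self) -> None:
        if self.mask_shape not in ("full_frame", "half_ellipse_MLO"):
            raise ValueError("mask_shape must be 'full_frame' or 'half_ellipse_MLO'")
        if self.bit_depth not in (8, 12):
            raise ValueError("phantom bit_depth must be 8 or 12")

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        """Build a spec from its JSON form; regions are dicts with keys
        geometry / target_h / amplitude."""
        import json

        data = json.loads(text)
        data["regions"] = [PhantomRegion(**r) for r in data.get("regions", [])]
        return cls(**data)


@dataclass
class Phantom:
    """A rendered phantom: image, breast mask, and per-pixel ground truth.

    ``truth`` holds class codes (CLASS_FATTY/_DISRUPTED/_DENSE) inside
    textured regions and CLASS_OUTSIDE elsewhere.
    """

    image: GrayImage
    mask: BreastRegionMask
    truth: np.ndarray

    def window_truth(self, geometry) -> np.ndarray:
        """Ground-truth class per sliding-window position.

        Each grid cell is labelled by the class of the region containing the
        window center; CLASS_OUTSIDE where the center falls in no region.
        """
        h, w = self.truth.shape
        n_r = (h - geometry.window_side) // geometry.stride + 1
        n_c = (w - geometry.window_side) // geometry.stride + 1
        out = np.full((max(n_r, 0), max(n_c, 0)), CLASS_OUTSIDE, dtype=np.int8)
        half = geometry.window_side // 2
        for i in range(n_r):
            for j in range(n_c):
                out[i, j] = self.truth[i * geometry.stride + half, j * geometry.stride + half]
        return out


def classify_target_h(h: float) -> int:
    """Ground-truth class of a region's target H (same thresholds as the
    window pipeline's classifier)."""
    return classify_hurst(h)


def _breast_mask(spec: PhantomSpec) -> np.ndarray:
    side = spec.image_side
    if spec.mask_shape == "full_frame":
        return np.ones((side, side), dtype=bool)
    # MLO-like half ellipse pressed against the left (chest-wall) edge
    rr, cc = np.mgrid[0:side, 0:side]
    return ((rr - side / 2) / (0.47 * side)) ** 2 + (cc / (0.88 * side)) ** 2 <= 1.0


def generate_phantom_mammogram(spec: PhantomSpec, seed: int) -> Phantom:
    """Render a phantom: each region filled with fBm of its target H.

    Region textures are blended in with a cosine taper (``spec.taper_px``
    wide) so that region borders do not introduce step singularities that
    would dominate the wavelet transform. Regions are interpreted within the
    breast mask (clipped to it); overlapping regions with different target H
    are rejected.
    """
    side = spec.image_side
    breast = _breast_mask(spec)
    canvas = np.zeros((side, side), dtype=np.float64)
    canvas[breast] = spec.background_level
    truth = np.full((side, side), CLASS_OUTSIDE, dtype=np.int8)

    claimed_h = np.full((side, side), np.nan)
    ss = np.random.SeedSequence([int(seed), side])
    children = ss.spawn(max(len(spec.regions), 1))
    for region, child in zip(spec.regions, children):
        rmask = region.pixel_mask(side) & breast
        if not rmask.any():
            raise ValueError("phantom region lies entirely outside the breast mask")
        overlap = rmask & ~np.isnan(claimed_h)
        if overlap.any() and not np.allclose(claimed_h[overlap], region.target_h):
            raise ValueError("overlapping phantom regions with different target H")
        claimed_h[rmask] = region.target_h

        rng = np.random.default_rng(child)
        texture = _fbm_field(side, region.target_h, rng) * region.amplitude
        # cosine taper of the blend weight over taper_px inside the region
        if spec.taper_px > 0:
            dist = ndimage.distance_transform_edt(rmask)
            w = 0.5 * (1.0 - np.cos(np.pi * np.minimum(dist, spec.taper_px) / spec.taper_px))
        else:
            w = rmask.astype(float)
        canvas += texture * w
        truth[rmask] = classify_target_h(region.target_h)

    full = 2 ** spec.bit_depth - 1
    canvas = np.clip(np.round(canvas), 0, full)
    canvas[~breast] = 0.0
    image = GrayImage(canvas, bit_depth=spec.bit_depth)
    return Phantom(image=image, mask=BreastRegionMask(breast), truth=truth)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Statistical design of a synthetic patient cohort.

    ``baseline_fractions`` are the expected (fatty, disrupted, dense) shares
    of analyzed windows in a healthy breast; ``cancer_effect`` is an additive
    shift of the disrupted share (with an equal reduction of the fatty share)
    applied to the tumor-side breast of cancer-group patients only. Benign
    groups receive no asymmetry by construction. The defaults are
    configuration values for the simulation, not claims about real tissue.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(TABLE1_GROUP_SIZES))
    baseline_fractions: tuple[float, float, float] = (0.55, 0.10, 0.35)
    cancer_effect: float = 0.15
    seed: int = 0
    #: windows analyzed per mammogram in the metrics-level simulation
    n_windows: int = 2500
    #: Dirichlet concentrations: patient-to-patient and breast-within-patient
    patient_concentration: float = 60.0
    breast_concentration: float = 150.0

    def __post_init__(self) -> None:
        fr = self.baseline_fractions
        if any(f < 0 for f in fr) or sum(fr) > 1.0 + 1e-9:
            raise ValueError("baseline fractions must be >= 0 and sum to <= 1")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        unknown = set(self.n_per_group) - (CANCER_GROUPS | BENIGN_GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        import json

        data = json.loads(text)
        if "baseline_fractions" in data:
            data["baseline_fractions"] = tuple(data["baseline_fractions"])
        return cls(**data)

    def patients(self):
        """Yield (patient_index, patient_id, group, is_cancer) in fixed order."""
        idx = 0
        for group in TABLE1_GROUP_SIZES:
            for _ in range(self.n_per_group.get(group, 0)):
                yield idx, f"P{idx:04d}", group, group in CANCER_GROUPS
                idx += 1


def _patient_rng(spec_seed: int, patient_index: int, side_code: int) -> np.random.Generator:
    # per-patient-and-side seed derived deterministically from the cohort seed
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), patient_index, side_code]))


def _patient_fractions(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    base = np.asarray(spec.baseline_fractions, dtype=float)
    return rng.dirichlet(spec.patient_concentration * base)


def _shift_cancer(p: np.ndarray, effect: float) -> np.ndarray:
    """Move ``effect`` of probability mass from fatty into disrupted."""
    q = p.copy()
    moved = min(effect, max(q[0] - 0.005, 0.0))
    q[0] -= moved
    q[1] += moved
    return q


@dataclass
class PatientPhantomPair:
    """Rendered phantom pair for one synthetic patient."""

    patient_id: str
    group: str
    tumor_side: str  # "L" or "R"
    tumor: Phantom
    opposite: Phantom


def _banded_phantom_spec(side: int, fractions: np.ndarray, amplitude: float) -> PhantomSpec:
    """Phantom whose breast is split into horizontal bands per class fraction."""
    fr = np.asarray(fractions, dtype=float)
    fr = fr / fr.sum()
    edges = np.round(np.cumsum(np.concatenate([[0.0], fr])) * side).astype(int)
    regions = []
    for cls, (r0, r1) in enumerate(zip(edges[:-1], edges[1:])):
        if r1 <= r0:
            continue
        regions.append(
            PhantomRegion(
                geometry={"kind": "rect", "rows": (int(r0), int(r1)), "cols": (0, side)},
                target_h=CLASS_TARGET_H[cls],
                amplitude=amplitude,
            )
        )
    return PhantomSpec(image_side=side, mask_shape="half_ellipse_MLO", regions=regions)


def generate_cohort(
    spec: CohortSpec, *, image_side: int = 448, amplitude: float = 30.0
) -> list[PatientPhantomPair]:
    """Render phantom image pairs for every patient in the cohort design.

    Each breast is a banded MLO phantom whose fatty/disrupted/dense band
    heights follow the patient's class fractions; the tumor-side breast of
    cancer patients has its disrupted share increased by ``cancer_effect``.
    Identical ``spec.seed`` yields an identical cohort.
    """
    out = []
    for idx, pid, group, is_cancer in spec.patients():
        rng = _patient_rng(spec.seed, idx, 0)
        p = _patient_fractions(spec, rng)
        p_tumor = _shift_cancer(p, spec.cancer_effect) if is_cancer else p
        tumor_side = "L" if rng.random() < 0.5 else "R"
        seed_t = int(_patient_rng(spec.seed, idx, 1).integers(2**31))
        seed_o = int(_patient_rng(spec.seed, idx, 2).integers(2**31))
        tumor = generate_phantom_mammogram(_banded_phantom_spec(image_side, p_tumor, amplitude), seed_t)
        opp = generate_phantom_mammogram(_banded_phantom_spec(image_side, p, amplitude), seed_o)
        out.append(PatientPhantomPair(pid, group, tumor_side, tumor, opp))
    return out


def simulate_cohort_metrics(spec: CohortSpec) -> "list":
    """Metrics-level cohort simulation (no images, no wavelet transform).

    Emulates the statistical structure of per-breast tissue-class counts
    directly: per-patient mean class fractions are drawn from a Dirichlet
    around the baseline, per-breast fractions from a Dirichlet around the
    patient mean, and window counts from a multinomial over ``n_windows``.
    Returns one :class:`~mammofractal.metrics.PatientRecord` per patient.

    This is the generator used for power and type-I studies of the cohort
    statistics, where rendering and wavelet-transforming thousands of
    phantom windows would add nothing but runtime.
    """
    from .metrics import PatientRecord, metrics_from_counts, yb_factor

    records = []
    for idx, pid, group, is_cancer in spec.patients():
        rng = _patient_rng(spec.seed, idx, 0)
        p = _patient_fractions(spec, rng)
        p_tumor_mean = _shift_cancer(p, spec.cancer_effect) if is_cancer else p
        p_t = rng.dirichlet(spec.breast_concentration * np.maximum(p_tumor_mean, 1e-6))
        p_o = rng.dirichlet(spec.breast_concentration * np.maximum(p, 1e-6))
        c_t = rng.multinomial(spec.n_windows, p_t)
        c_o = rng.multinomial(spec.n_windows, p_o)
        m_t = metrics_from_counts(int(c_t[0]), int(c_t[1]), int(c_t[2]))
        m_o = metrics_from_counts(int(c_o[0]), int(c_o[1]), int(c_o[2]))
        records.append(
            PatientRecord(
                patient_id=pid,
                group=group,
                tumor_side="L",
                tumor_metrics=m_t,
                opposite_metrics=m_o,
                yb_factor=yb_factor(m_t, m_o),
            )
        )
    return records
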