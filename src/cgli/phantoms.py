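"""Seeded synthetic phantoms for desk-scale validation.

Three families of test images, each returned with its exact generative
ground truth and a circular field-of-view mask:

``two_phase_disk``
    A piecewise-homogeneous disk on a flat background — the canonical
    two-phase case where global region statistics suffice.
``bias_field_blob``
    An elliptical blob under a smooth multiplicative bias field — the
    intensity-inhomogeneity case that breaks global two-mean assumptions.
``vessel_tree``
    A branching tree of ribbons with Gaussian cross-section intensity
    profiles, emulating the matched-filter model of retinal vessels, with
    optional bias field and additive noise, clipped to a circular FOV.

All randomness flows from ``PhantomSpec.seed``; identical specs produce
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "make_phantom"]

KINDS = ("two_phase_disk", "bias_field_blob", "vessel_tree")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image.

    fg / bg are the object and background base intensities in [0, 1]
    (vessels are generated *bright* on a dark background, matching the
    package's phi > 0 = object convention; invert real fundus images where
    vessels are dark).  ``bias_amplitude`` is the peak relative amplitude
    of a low-order harmonic multiplicative field; ``noise_std`` the
    standard deviation of additive Gaussian noise.  Vessel widths are
    full ribbon widths in pixels, interpreted as the FWHM of the Gaussian
    cross-section profile (``cross_section_sigma`` of None uses
    width/2.355), so the ground-truth ribbon edge sits at the half-peak
    level.  Thin branches are rendered at reduced contrast (half strength
    at the narrowest width), mimicking faint capillaries.
    """

    kind: str
    size: tuple[int, int] = (64, 64)
    fg: float = 0.9
    bg: float = 0.1
    bias_amplitude: float = 0.0
    noise_std: float = 0.0
    n_branches: int = 3
    width_range: tuple[float, float] = (2.0, 4.0)
    cross_section_sigma: float | None = None
    fov_fraction: float = 1.0
    seed: int = 0
    # filled by the generator: (length, width) per branch centerline
    branch_stats: list = field(default_factory=list, compare=False)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        h, w = self.size
        if h < 8 or w < 8:
            raise ValueError("phantom size must be at least 8x8")
        if self.fg == self.bg:
            raise ValueError("fg and bg intensities must differ")
        if self.width_range[0] < 1:
            raise ValueError("vessel widths must be >= 1 pixel")
        if self.width_range[1] > min(self.size) / 4:
            raise ValueError("vessel width exceeds image size")
        if not (0 < self.fov_fraction <= 1):
            raise ValueError("fov_fraction must lie in (0, 1]")
        if self.bias_amplitude < 0 or self.noise_std < 0:
            raise ValueError("bias_amplitude and noise_std must be >= 0")


def _grid(h, w):
    return np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                       indexing="ij")


def _fov_mask(h, w, fraction):
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = fraction * min(h, w) / 2.0
    yy, xx = _grid(h, w)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _bias_field(h, w, amplitude, rng):
    """Smooth multiplicative field 1 + A*cos(...)cos(...), range [1-A, 1+A]."""
    if amplitude == 0:
        return np.ones((h, w))
    yy, xx = _grid(h, w)
    py, px = rng.uniform(0, 2 * math.pi, size=2)
    b = np.cos(math.pi * yy / h + py) * np.cos(math.pi * xx / w + px)
    return 1.0 + amplitude * b


def _segment_distance(yy, xx, a, b):
    """Per-pixel Euclidean distance to the segment a-b (points as (y, x))."""
    ay, ax = a
    by, bx = b
    dy, dx = by - ay, bx - ax
    L2 = dy * dy + dx * dx
    if L2 < 1e-12:
        return np.hypot(yy - ay, xx - ax)
    t = np.clip(((yy - ay) * dy + (xx - ax) * dx) / L2, 0.0, 1.0)
    return np.hypot(yy - ay - t * dy, xx - ax - t * dx)


def _grow_branch(start, direction, width, step, max_steps, keep_radius,
                 center, rng):
    """Random-walk a centerline polyline until it leaves the growth disk."""
    pts = [np.asarray(start, dtype=float)]
    ang = float(direction)
    for _ in range(max_steps):
        ang += rng.uniform(-0.25, 0.25)
        nxt = pts[-1] + step * np.array([math.sin(ang), math.cos(ang)])
        if np.hypot(*(nxt - center)) > keep_radius:
            break
        pts.append(nxt)
    return {"points": pts, "width": float(width)}


def _make_tree(spec: PhantomSpec, rng) -> list[dict]:
    h, w = spec.size
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    r_fov = spec.fov_fraction * min(h, w) / 2.0
    # keep centerlines well inside the FOV so ribbons never get clipped
    keep = r_fov - spec.width_range[1] / 2.0 - 2.0
    step = max(3.0, min(h, w) / 12.0)
    lo, hi = spec.width_range

    ang0 = rng.uniform(0, 2 * math.pi)
    start = center + 0.95 * keep * np.array([math.sin(ang0), math.cos(ang0)])
    trunk = _grow_branch(start, ang0 + math.pi + rng.uniform(-0.3, 0.3),
                         hi, step, int(2.5 * keep / step), keep, center, rng)
    branches = [trunk]
    attempts = 0
    while len(branches) < spec.n_branches and attempts < 50 * spec.n_branches:
        attempts += 1
        parent = branches[rng.integers(len(branches))]
        pts = parent["points"]
        if len(pts) < 3:
            continue
        j = int(rng.integers(1, len(pts) - 1))
        local = pts[j + 1] - pts[j - 1]
        local_ang = math.atan2(local[0], local[1])
        side = rng.choice([-1.0, 1.0])
        child_ang = local_ang + side * rng.uniform(0.5, 1.1)
        child = _grow_branch(pts[j], child_ang, rng.uniform(lo, hi), step,
                             int(1.5 * keep / step), keep, center, rng)
        if len(child["points"]) >= 3:
            branches.append(child)
    return branches


def _rasterize_tree(spec: PhantomSpec, branches):
    h, w = spec.size
    yy, xx = _grid(h, w)
    truth = np.zeros((h, w), dtype=bool)
    profile = np.zeros((h, w))
    lo, hi = spec.width_range
    for br in branches:
        wid = br["width"]
        # width is the FWHM of the cross-section profile by default
        sigma = spec.cross_section_sigma or wid / 2.355
        # thin vessels are fainter, as in fundus imagery: contrast scales
        # from half strength (narrowest) to full strength (widest)
        amp = 1.0 if hi == lo else 0.5 + 0.5 * (wid - lo) / (hi - lo)
        pts = br["points"]
        for a, b in zip(pts[:-1], pts[1:]):
            d = _segment_distance(yy, xx, a, b)
            truth |= d <= wid / 2.0
            np.maximum(profile, amp * np.exp(-(d**2) / (2.0 * sigma**2)),
                       out=profile)
    return truth, profile


def make_phantom(spec: PhantomSpec):
    """Generate ``(img, truth, fov)`` for a phantom spec.

    ``truth`` is the exact generative object mask, ``fov`` a centered disk,
    and ``img = clip(base * bias + noise, 0, 1)``.  For ``vessel_tree`` the
    per-branch centerline ``(length, width)`` pairs are recorded in
    ``spec.branch_stats`` for analytic pixel-count checks, and the truth is
    clipped to the FOV.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    fov = _fov_mask(h, w, spec.fov_fraction)
    yy, xx = _grid(h, w)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    if spec.kind == "two_phase_disk":
        r = 0.3 * min(h, w)
        truth = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        base = np.where(truth, spec.fg, spec.bg)
    elif spec.kind == "bias_field_blob":
        ra, rb = 0.32 * min(h, w), 0.2 * min(h, w)
        theta = rng.uniform(0, math.pi)
        yr = (yy - cy) * math.cos(theta) - (xx - cx) * math.sin(theta)
        xr = (yy - cy) * math.sin(theta) + (xx - cx) * math.cos(theta)
        truth = (yr / rb) ** 2 + (xr / ra) ** 2 <= 1.0
        base = np.where(truth, spec.fg, spec.bg)
    else:  # vessel_tree
        branches = _make_tree(spec, rng)
        truth, profile = _rasterize_tree(spec, branches)
        truth &= fov
        base = spec.bg + (spec.fg - spec.bg) * profile
        spec.branch_stats.clear()
        for br in branches:
            pts = br["points"]
            length = float(sum(np.hypot(*(b - a))
                               for a, b in zip(pts[:-1], pts[1:])))
            spec.branch_stats.append((length, br["width"]))

    img = base * _bias_field(h, w, spec.bias_amplitude, rng)
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=(h, w))
    return np.clip(img, 0.0, 1.0), truth, fov
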