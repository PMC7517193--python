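"""Synthetic retinal-like phantoms and ground-truth deformations.

Real fundus photographs show a roughly circular field of view inscribed in
the frame, a dark periphery, a tree of curvilinear vessels, and a mottled
background (the choroid shows through the retina as low-frequency intensity
texture).  The phantoms imitate that coarse geometry — disc, random-walk
branches, band-limited background texture, Gaussian pixel noise — because
the demons machinery is intensity-generic; no attempt is made at
photometric realism (illumination gradients, optic disc, pathology).

The background texture matters for registration tests: an intensity-driven
solver receives no force from perfectly flat regions, so a texture-free
cartoon is qualitatively harder than real tissue, not easier.

Every phantom and synthetic warp is reproducible bit-exactly from its spec
and seed, which makes the module the package's download-free stand-in for
external fundus benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .demons import warp_image
from .errors import ConfigError, ShapeError
from .fields import DeformationField

__all__ = [
    "PhantomSpec",
    "SyntheticWarp",
    "make_phantom",
    "true_field",
    "apply_warp",
    "recovery_error",
    "make_phantom_pair",
]

WARP_KINDS = ("translation", "rotation_like", "gaussian_bump")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one vessel-tree phantom.

    ``noise_sigma`` is the standard deviation of additive Gaussian pixel
    noise on the [0, 1] scale; ``disc_radius_frac`` the field-of-view disc
    radius as a fraction of min(H, W)/2 (1.0 = inscribed, touching the frame
    edges, as in fundus photographs); ``texture_amp``/``texture_scale`` the
    standard deviation and correlation length (pixels) of the mottled
    background texture inside the disc.
    """

    size: tuple[int, int] = (128, 128)
    n_branches: int = 8
    vessel_width: tuple[float, float] = (1.5, 3.5)
    disc_radius_frac: float = 1.0
    texture_amp: float = 0.06
    texture_scale: float = 3.0
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ConfigError(f"phantom size must be at least 32x32, got {self.size}")
        if self.n_branches < 0:
            raise ConfigError("n_branches must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.texture_amp < 0:
            raise ConfigError("texture_amp must be >= 0")
        if self.texture_scale <= 0:
            raise ConfigError("texture_scale must be > 0")
        lo, hi = self.vessel_width
        if not (0 < lo <= hi):
            raise ConfigError(f"vessel_width must satisfy 0 < lo <= hi, got {self.vessel_width}")


@dataclass(frozen=True)
class SyntheticWarp:
    """Analytic ground-truth deformation.

    kinds
        ``translation``  — spatially constant shift of ``magnitude`` pixels
        along ``direction`` (unit-normalized (row, col)).
        ``rotation_like`` — the displacement field of a small rotation by
        ``magnitude`` degrees about ``center`` (fraction coordinates).
        ``gaussian_bump`` — a radial push of peak ``magnitude`` pixels with a
        Gaussian envelope of ``extent`` (fraction of min(H, W)).
    """

    kind: str = "translation"
    magnitude: float = 3.0
    direction: tuple[float, float] = (1.0, 0.0)
    center: tuple[float, float] = (0.5, 0.5)
    extent: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in WARP_KINDS:
            raise ConfigError(f"unknown warp kind {self.kind!r}; choose from {WARP_KINDS}")
        if self.magnitude < 0:
            raise ConfigError("magnitude must be >= 0")
        if self.extent <= 0:
            raise ConfigError("extent must be > 0")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate one vessel-tree phantom image, values in [0, 1].

    A dim field-of-view disc (intensity 0.35) on a dark surround (0.05)
    carries mottled background texture (Gaussian-filtered noise of the
    configured amplitude and correlation length) and bright (0.9)
    random-walk vessel branches started at the disc rim and steered inward
    with curvature noise; Gaussian pixel noise is added last and the result
    clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.disc_radius_frac * min(h, w) / 2.0
    img = np.full((h, w), 0.05)
    disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
    img[disc] = 0.35
    if spec.texture_amp > 0:
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), spec.texture_scale)
        std = tex.std()
        if std > 0:
            img[disc] += (tex / std * spec.texture_amp)[disc]

    for _ in range(spec.n_branches):
        # start on the disc rim, walk inward with meandering direction
        theta = rng.uniform(0, 2 * np.pi)
        r = np.array([cr + 0.95 * radius * np.sin(theta), cc + 0.95 * radius * np.cos(theta)])
        heading = np.arctan2(cr - r[0], cc - r[1]) + rng.normal(0, 0.3)
        width = rng.uniform(*spec.vessel_width)
        n_steps = int(1.2 * radius)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.18)
            r += np.array([np.sin(heading), np.cos(heading)])
            if not (0 <= r[0] < h and 0 <= r[1] < w):
                break
            rr, cc_ = int(round(r[0])), int(round(r[1]))
            half = int(np.ceil(width))
            r0, r1 = max(rr - half, 0), min(rr + half + 1, h)
            c0, c1 = max(cc_ - half, 0), min(cc_ + half + 1, w)
            sub_r, sub_c = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            d2 = (sub_r - r[0]) ** 2 + (sub_c - r[1]) ** 2
            img[r0:r1, c0:c1][d2 <= (width / 2.0) ** 2] = 0.9

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def true_field(warp: SyntheticWarp, shape: tuple[int, int]) -> DeformationField:
    """Evaluate the analytic displacement field of ``warp`` on a pixel grid."""
    h, w = shape
    rows, cols = np.meshgrid(
        np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij"
    )
    if warp.kind == "translation":
        d = np.asarray(warp.direction, dtype=np.float64)
        norm = np.hypot(*d)
        d = d / norm if norm > 0 else np.array([1.0, 0.0])
        u_row = np.full(shape, warp.magnitude * d[0])
        u_col = np.full(shape, warp.magnitude * d[1])
    elif warp.kind == "rotation_like":
        cr = warp.center[0] * (h - 1)
        cc = warp.center[1] * (w - 1)
        angle = np.deg2rad(warp.magnitude)
        dr, dc = rows - cr, cols - cc
        # displacement taking each pixel to its rotated source position
        u_row = dr * (np.cos(angle) - 1.0) - dc * np.sin(angle)
        u_col = dr * np.sin(angle) + dc * (np.cos(angle) - 1.0)
    else:  # gaussian_bump
        cr = warp.center[0] * (h - 1)
        cc = warp.center[1] * (w - 1)
        s = warp.extent * min(h, w)
        dr, dc = rows - cr, cols - cc
        envelope = np.exp(-(dr**2 + dc**2) / (2.0 * s**2))
        # radial push; unit direction away from the center, zero at the center
        dist = np.hypot(dr, dc)
        with np.errstate(invalid="ignore", divide="ignore"):
            er = np.where(dist > 0, dr / dist, 0.0)
            ec = np.where(dist > 0, dc / dist, 0.0)
        u_row = warp.magnitude * envelope * er
        u_col = warp.magnitude * envelope * ec
    return DeformationField(u_row, u_col)


def apply_warp(img: np.ndarray, warp: SyntheticWarp) -> tuple[np.ndarray, DeformationField]:
    """Warp ``img`` by the analytic field; returns (warped, true_field).

    The warp magnitude must stay below min(H, W)/4 so the deformed content
    remains inside the frame.
    """
    h, w = img.shape
    if warp.magnitude >= min(h, w) / 4.0:
        raise ConfigError(
            f"warp magnitude {warp.magnitude} too large for a {h}x{w} image "
            f"(must be < {min(h, w) / 4.0})"
        )
    field = true_field(warp, (h, w))
    return warp_image(img, field), field


def recovery_error(
    estimated: DeformationField,
    truth: DeformationField,
    mask: np.ndarray | None = None,
    border: int = 16,
) -> float:
    """Root-mean-square endpoint error (pixels) between two fields.

    With no explicit ``mask``, a border band of ``border`` pixels is excluded
    so boundary-condition artifacts of the solver do not dominate the score.
    """
    if estimated.shape != truth.shape:
        raise ShapeError(f"field shapes differ: {estimated.shape} vs {truth.shape}")
    h, w = estimated.shape
    if mask is None:
        mask = np.zeros((h, w), dtype=bool)
        if 2 * border >= h or 2 * border >= w:
            raise ValueError(f"border {border} leaves no interior in a {h}x{w} field")
        mask[border : h - border, border : w - border] = True
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != estimated.shape:
            raise ShapeError("mask shape must match the fields")
    if not mask.any():
        raise ValueError("empty recovery mask")
    dr = estimated.u_row - truth.u_row
    dc = estimated.u_col - truth.u_col
    return float(np.sqrt(((dr**2 + dc**2)[mask]).mean()))


def make_phantom_pair(
    spec: PhantomSpec, warp: SyntheticWarp
) -> tuple[np.ndarray, np.ndarray, DeformationField]:
    """Convenience: (fixed, moving, truth) registration test case.

    The warped phantom is returned as the FIXED image and the original as
    the MOVING image, so a solver that estimates u with
    ``moving(p + u(p)) ~ fixed(p)`` should recover ``truth`` itself (not its
    negation): fixed(p) = moving(p + truth(p)) by construction.
    """
    img = make_phantom(spec)
    warped, field = apply_warp(img, warp)
    return warped, img, field
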