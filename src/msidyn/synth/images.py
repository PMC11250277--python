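"""Synthetic multiplex-immunofluorescence tiles of ellipse-shaped cells.

Cells are filled ellipses rendered at a foreground intensity into the channels
of their phenotype, over a background with an optional linear ramp and additive
Gaussian noise. The returned ground truth (ellipse parameters and phenotype
labels) is the oracle for the segmentation workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageSpec", "ImageGroundTruth", "gen_cell_image", "rasterize_ellipse"]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed under the disjointness constraints."""


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic tile.

    ``overlap_pairs`` touching pairs are placed with center distance below the
    sum of their semi-minor axes; all other cells are pairwise disjoint.
    ``channel_spec`` maps phenotype name -> {channel name: intensity scale},
    where the rendered intensity is ``scale * fg_intensity``.
    """

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 0.5
    n_cells: int = 20
    overlap_pairs: int = 0
    axis_range_px: tuple[float, float] = (5.0, 9.0)
    fg_intensity: float = 200.0
    bg_intensity: float = 10.0
    gradient_amplitude: float = 20.0
    noise_sd: float = 5.0
    channel_spec: dict = field(
        default_factory=lambda: {"cell": {"dapi": 1.0}}
    )
    seed: int = 0
    max_retries: int = 10_000

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if 2 * self.overlap_pairs > self.n_cells:
            raise ValueError("overlap_pairs requires 2 cells each")
        lo, hi = self.axis_range_px
        if not (0 < lo <= hi):
            raise ValueError("axis_range_px must satisfy 0 < min <= max")


@dataclass
class ImageGroundTruth:
    """True ellipses ``(cx, cy, semi_major, semi_minor, angle_rad)`` (x=col,
    y=row), one phenotype label per cell, and the noise-free channel stack."""

    ellipses: list[tuple[float, float, float, float, float]]
    phenotypes: list[str]
    channel_stack: dict[str, np.ndarray]

    def foreground_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for e in self.ellipses:
            mask |= rasterize_ellipse(shape, *e)
        return mask


def rasterize_ellipse(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    a: float,
    b: float,
    angle: float,
) -> np.ndarray:
    """Boolean mask of the filled ellipse with semi-axes ``a >= b`` rotated by
    ``angle`` radians (x toward columns, y toward rows)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_ellipse(rng, spec: ImageSpec, near_circular: bool = False):
    lo, hi = spec.axis_range_px
    a = rng.uniform(lo, hi)
    if near_circular:
        b = a * rng.uniform(0.85, 1.0)
    else:
        b = rng.uniform(lo, a)
    angle = rng.uniform(0.0, np.pi)
    return a, max(b, lo * 0.5), angle


def _fits_inside(cx, cy, a, spec: ImageSpec) -> bool:
    return a <= cx <= spec.width_px - 1 - a and a <= cy <= spec.height_px - 1 - a


def gen_cell_image(spec: ImageSpec) -> tuple[dict[str, np.ndarray], ImageGroundTruth]:
    """Render a synthetic tile.

    Returns ``(channels, truth)`` where ``channels`` maps channel name to a
    float image of shape ``(height_px, width_px)``. Placement uses rejection
    sampling with a retry cap and fails loudly rather than dropping cells.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    phenotype_names = list(spec.channel_spec)
    channel_names: list[str] = []
    for chans in spec.channel_spec.values():
        for c in chans:
            if c not in channel_names:
                channel_names.append(c)

    ellipses: list[tuple[float, float, float, float, float]] = []
    majors: list[float] = []

    def try_place(near_circular=False, pair_with: int | None = None):
        for _ in range(spec.max_retries):
            a, b, angle = _sample_ellipse(rng, spec, near_circular)
            if pair_with is None:
                cx = rng.uniform(a, spec.width_px - 1 - a)
                cy = rng.uniform(a, spec.height_px - 1 - a)
            else:
                pcx, pcy, pa, pb, _ = ellipses[pair_with]
                # touching: centers closer than the sum of semi-minor axes,
                # but far enough that each keeps its own distance-transform peak
                d = 0.9 * (pb + b)
                theta = rng.uniform(0, 2 * np.pi)
                cx = pcx + d * np.cos(theta)
                cy = pcy + d * np.sin(theta)
            if not _fits_inside(cx, cy, a, spec):
                continue
            ok = True
            for j, (ex, ey, ea, eb, eang) in enumerate(ellipses):
                if pair_with is not None and j == pair_with:
                    continue
                dist = np.hypot(cx - ex, cy - ey)
                if dist < a + ea + 2.0:  # disjoint with a 2 px margin
                    ok = False
                    break
            if ok:
                ellipses.append((cx, cy, a, b, angle))
                majors.append(a)
                return
        raise PlacementError(
            f"could not place cell after {spec.max_retries} retries; "
            "frame too small for the requested layout"
        )

    for _ in range(spec.overlap_pairs):
        try_place(near_circular=True)
        try_place(near_circular=True, pair_with=len(ellipses) - 1)
    for _ in range(spec.n_cells - 2 * spec.overlap_pairs):
        try_place()

    phenotypes = [phenotype_names[rng.integers(len(phenotype_names))] for _ in ellipses]

    shape = (spec.height_px, spec.width_px)
    ramp = np.zeros(shape)
    if spec.gradient_amplitude:
        ramp = spec.gradient_amplitude * np.linspace(0, 1, spec.width_px)[None, :]
        ramp = np.broadcast_to(ramp, shape).copy()
    clean: dict[str, np.ndarray] = {
        c: spec.bg_intensity + ramp.copy() for c in channel_names
    }
    for (ell, pheno) in zip(ellipses, phenotypes):
        m = rasterize_ellipse(shape, *ell)
        for chan, scale in spec.channel_spec[pheno].items():
            img = clean[chan]
            img[m] = np.maximum(img[m], scale * spec.fg_intensity)

    truth = ImageGroundTruth(
        ellipses=ellipses,
        phenotypes=phenotypes,
        channel_stack={c: img.copy() for c, img in clean.items()},
    )

    channels: dict[str, np.ndarray] = {}
    lo = 0.0
    hi = spec.fg_intensity * max(
        (s for chans in spec.channel_spec.values() for s in chans.values()),
        default=1.0,
    ) + abs(spec.gradient_amplitude) + spec.bg_intensity
    for c in channel_names:
        img = clean[c]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
            img = np.clip(img, lo, hi)
        channels[c] = img
    return channels, truth
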