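"""Ellipsoidal cell segmentation for multiplex immunofluorescence tiles.

The workflow assumes cells are well approximated by filled ellipses and
proceeds in four stages:

1. ``binarize`` — Gaussian smoothing (5x5 kernel), adaptive local-mean
   thresholding, then light morphology (erosion, dilation, small-object
   removal) to produce the binary mask M.
2. ``detect_seeds`` — regional maxima of the Euclidean distance transform of
   M; maxima closer than a merge distance are collapsed, keeping the one with
   the larger distance value.
3. ``em_fit`` / ``select_components`` — a 2-D Gaussian mixture over foreground
   pixel coordinates, one component per seed, fitted by EM (initialized by
   nearest-seed assignment). Erroneous seeds are rejected by greedy backward
   elimination under the fitness degree

       score = (A_F - A_B - A_T - W_I) / E

   where E is the total pixel area covered by the component ellipses (with
   multiplicity), A_F / A_B its foreground / background parts, A_T the
   pairwise ellipse-overlap area and W_I an intensity-variance penalty. The
   score is at most 1 and reaches 1 exactly when the ellipses tile the
   foreground with no overlap and uniform intensity.
4. ``assign_pixels`` — Bayesian (maximum-posterior) assignment of each
   foreground pixel to a component, yielding one labeled region per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import chi2
from skimage import morphology

__all__ = [
    "BinarizeConfig",
    "EllipseComponent",
    "EmFit",
    "FitnessBreakdown",
    "CellRecord",
    "SegmentConfig",
    "binarize",
    "detect_seeds",
    "em_fit",
    "fitness_degree",
    "select_components",
    "assign_pixels",
    "segment",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class BinarizeConfig:
    """Adaptive-threshold and morphology parameters.

    ``offset_frac`` is the additive threshold offset as a fraction of the
    channel's dynamic range; ``window_px`` the local-mean window (odd).
    """

    window_px: int = 51
    offset_frac: float = 0.02
    gaussian_sigma: float = 1.0  # 5x5 support with truncate=2
    morph_radius: int = 1
    min_object_px: int = 30


@dataclass
class EllipseComponent:
    """A fitted 2-D Gaussian component drawn as its ``boundary_quantile``
    Mahalanobis contour (chi-square with 2 dof)."""

    mean: np.ndarray  # (row, col)
    covariance: np.ndarray  # 2x2 SPD
    weight: float
    boundary_quantile: float = 0.95

    @property
    def mahalanobis_radius2(self) -> float:
        return float(chi2.ppf(self.boundary_quantile, df=2))

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean: which (row, col) points fall inside the drawn ellipse."""
        d = coords - self.mean
        inv = np.linalg.inv(self.covariance)
        md2 = np.einsum("ni,ij,nj->n", d, inv, d)
        return md2 <= self.mahalanobis_radius2

    def ellipse_params(self):
        """(cx, cy, semi_major, semi_minor, angle_rad) in x=col, y=row."""
        vals, vecs = np.linalg.eigh(self.covariance)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        r = np.sqrt(self.mahalanobis_radius2)
        a, b = r * np.sqrt(vals[0]), r * np.sqrt(vals[1])
        # covariance axes are (row, col); report angle in x-y convention
        angle = float(np.arctan2(vecs[0, 0], vecs[1, 0]))
        return float(self.mean[1]), float(self.mean[0]), float(a), float(b), angle


@dataclass
class EmFit:
    components: list[EllipseComponent]
    loglik_trace: np.ndarray
    converged: bool


@dataclass
class FitnessBreakdown:
    A_F: float
    A_B: float
    A_T: float
    W_I: float
    E: float
    score: float


@dataclass
class CellRecord:
    cell_id: int
    center_rc: tuple[float, float]
    center_um: tuple[float, float]
    ellipse: tuple[float, float, float, float, float]
    area_px: int
    channel_means: dict[str, float]
    phenotype: str | None = None


@dataclass(frozen=True)
class SegmentConfig:
    nuclear_channel: str = "dapi"
    binarize: BinarizeConfig = field(default_factory=BinarizeConfig)
    merge_dist_px: float = 5.0
    boundary_quantile: float = 0.95
    max_iter: int = 100
    tol: float = 1e-4
    select_max_iter: int = 30  # EM budget for trial refits during selection


def binarize(channel: np.ndarray, config: BinarizeConfig | None = None) -> np.ndarray:
    """Adaptive local-mean binarization of one channel.

    A pixel is foreground when its Gaussian-smoothed value exceeds the mean of
    its local window plus an offset; the mask is then cleaned with one
    erosion, one dilation (disk) and removal of small connected components.
    """
    config = config or BinarizeConfig()
    img = np.asarray(channel, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("channel contains non-finite pixels")
    if config.window_px < 3 or config.window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    smoothed = ndimage.gaussian_filter(img, sigma=config.gaussian_sigma, truncate=2.0)
    local_mean = ndimage.uniform_filter(smoothed, size=config.window_px)
    dynamic = img.max() - img.min()
    offset = config.offset_frac * dynamic
    mask = smoothed > local_mean + offset
    selem = morphology.disk(config.morph_radius)
    mask = ndimage.binary_erosion(mask, structure=selem)
    mask = ndimage.binary_dilation(mask, structure=selem)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = np.nonzero(sizes < config.min_object_px)[0] + 1
        mask[np.isin(labels, small)] = False
    return mask


def detect_seeds(mask: np.ndarray, merge_dist_px: float = 5.0) -> list[tuple[int, int, float]]:
    """Regional maxima of the Euclidean distance transform of the mask.

    Each connected plateau of maxima contributes one candidate at its
    lexicographically smallest pixel. Candidates closer than ``merge_dist_px``
    are merged, keeping the larger distance value (ties resolved toward the
    smallest (row, col)). Returns ``[(row, col, distance), ...]``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    dt = ndimage.distance_transform_edt(mask)
    maxima = morphology.local_maxima(dt, allow_borders=True) & mask
    labels, n = ndimage.label(maxima)
    cands: list[tuple[int, int, float]] = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(labels == i)
        order = np.lexsort((cc, rr))
        r, c = int(rr[order[0]]), int(cc[order[0]])
        cands.append((r, c, float(dt[r, c])))
    # larger distance first; ties toward smallest (row, col)
    cands.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept: list[tuple[int, int, float]] = []
    for r, c, d in cands:
        if all(np.hypot(r - kr, c - kc) >= merge_dist_px for kr, kc, _ in kept):
            kept.append((r, c, d))
    return kept


def _log_gauss(coords: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = coords - mean
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    md2 = np.einsum("ni,ij,nj->n", d, inv, d)
    return -0.5 * (md2 + logdet + 2.0 * _LOG2PI)


def _regularize(cov: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    vals = np.linalg.eigvalsh(cov)
    if vals.min() < eps:
        cov = cov + (eps - min(vals.min(), 0.0) + eps) * np.eye(2)
    return cov


def em_fit(
    mask: np.ndarray,
    seeds: list[tuple[int, int, float]],
    max_iter: int = 100,
    tol: float = 1e-4,
    boundary_quantile: float = 0.95,
    min_pixels: int = 3,
) -> EmFit:
    """Fit a Gaussian mixture over foreground pixel coordinates by EM.

    One component per seed; initialization assigns each pixel to its nearest
    seed (1-NN, Euclidean) and takes group means/covariances/weights.
    Iterates until the observed-data log-likelihood gain drops below ``tol``
    or ``max_iter`` is reached. The trace is non-decreasing (EM monotonicity);
    near-singular covariances are ridge-regularized, and components whose
    initial group holds fewer than ``min_pixels`` pixels are dropped with a
    warning.
    """
    if not seeds:
        raise ValueError("em_fit requires at least one seed")
    coords = np.argwhere(np.asarray(mask, dtype=bool)).astype(float)
    n = len(coords)
    if n < min_pixels:
        raise ValueError("too few foreground pixels to fit")

    seed_pts = np.array([[r, c] for r, c, _ in seeds], dtype=float)
    d2 = ((coords[:, None, :] - seed_pts[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)

    means, covs, weights = [], [], []
    for k in range(len(seeds)):
        pts = coords[assign == k]
        if len(pts) < min_pixels:
            warnings.warn(f"seed {k} holds {len(pts)} pixels; component dropped")
            continue
        means.append(pts.mean(axis=0))
        covs.append(_regularize(np.cov(pts.T) if len(pts) > 1 else np.eye(2)))
        weights.append(len(pts) / n)
    if not means:
        raise ValueError("all components dropped during initialization")
    means = np.array(means)
    covs = np.array(covs)
    weights = np.array(weights)
    weights = weights / weights.sum()
    k = len(means)

    trace = []
    converged = False
    log_resp = np.empty((n, k))
    for _ in range(max_iter):
        for j in range(k):
            log_resp[:, j] = np.log(weights[j]) + _log_gauss(coords, means[j], covs[j])
        log_norm = np.logaddexp.reduce(log_resp, axis=1)
        ll = float(log_norm.sum())
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        resp = np.exp(log_resp - log_norm[:, None])
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ coords) / nk[:, None]
        for j in range(k):
            d = coords - means[j]
            covs[j] = _regularize((resp[:, j][:, None] * d).T @ d / nk[j])

    components = [
        EllipseComponent(
            mean=means[j].copy(),
            covariance=covs[j].copy(),
            weight=float(weights[j]),
            boundary_quantile=boundary_quantile,
        )
        for j in range(k)
    ]
    return EmFit(components=components, loglik_trace=np.array(trace), converged=converged)


def _coverage_counts(
    shape: tuple[int, int], components: list[EllipseComponent]
) -> np.ndarray:
    """Per-pixel count of component ellipses covering it."""
    cover = np.zeros(shape, dtype=np.int32)
    h, w = shape
    r2 = None
    for comp in components:
        # bounding box of the drawn ellipse keeps rasterization cheap
        r2 = comp.mahalanobis_radius2
        vals = np.linalg.eigvalsh(comp.covariance)
        rad = np.sqrt(r2 * vals.max())
        r0 = max(int(np.floor(comp.mean[0] - rad)), 0)
        r1 = min(int(np.ceil(comp.mean[0] + rad)) + 1, h)
        c0 = max(int(np.floor(comp.mean[1] - rad)), 0)
        c1 = min(int(np.ceil(comp.mean[1] + rad)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        inside = comp.contains(pts).reshape(rr.shape)
        cover[r0:r1, c0:c1] += inside
    return cover


def fitness_degree(
    mask: np.ndarray,
    components: list[EllipseComponent],
    intensity: np.ndarray | None = None,
) -> FitnessBreakdown:
    """Evaluate the ellipse-fit fitness degree (A_F - A_B - A_T - W_I)/E.

    Areas are pixel counts of the rasterized boundary-quantile contours,
    counted with multiplicity over components, so E = A_F + A_B always and a
    duplicated component is strictly penalized through A_T (the unordered
    pairwise overlap count, sum over pixels of C(n, 2) for coverage n). W_I is
    the area-weighted within-ellipse intensity variance normalized by the
    whole-foreground variance (0 when the foreground is uniform).
    """
    mask = np.asarray(mask, dtype=bool)
    if not components:
        raise ValueError("fitness_degree requires at least one component")
    cover = _coverage_counts(mask.shape, components)
    E = float(cover.sum())
    if E == 0:
        raise ValueError("estimated ellipses cover no pixels; score undefined")
    A_F = float(cover[mask].sum())
    A_B = float(cover[~mask].sum())
    A_T = float((cover.astype(np.int64) * (cover - 1) // 2).sum())

    # Intensity penalty: per-ellipse variance over the ellipse's foreground
    # pixels (touching-cell separation is about foreground content; covered
    # background is already charged to A_B), scaled by its excess over the
    # foreground-wide variance so that noise common to every pixel is free.
    W_I = 0.0
    if intensity is not None:
        img = np.asarray(intensity, dtype=float)
        fg = img[mask]
        var_ref = float(fg.var()) if fg.size else 0.0
        if var_ref > 0:
            for comp in components:
                inside = (_coverage_counts(mask.shape, [comp]) > 0) & mask
                vals = img[inside]
                if vals.size:
                    excess = max(0.0, float(vals.var()) - var_ref)
                    W_I += vals.size * excess / var_ref
    score = (A_F - A_B - A_T - W_I) / E
    return FitnessBreakdown(A_F=A_F, A_B=A_B, A_T=A_T, W_I=W_I, E=E, score=score)


def select_components(
    mask: np.ndarray,
    seeds: list[tuple[int, int, float]],
    intensity: np.ndarray | None = None,
    config: SegmentConfig | None = None,
) -> tuple[EmFit, FitnessBreakdown]:
    """Greedy backward seed rejection under the fitness degree.

    Fits the full seed set, then repeatedly tries removing each single seed,
    refitting and rescoring; the removal with the largest score improvement is
    accepted, until no removal improves or one seed remains. The returned
    score is never below the full-set score.
    """
    config = config or SegmentConfig()
    if not seeds:
        raise ValueError("select_components requires at least one seed")

    def fit_and_score(seed_subset, max_iter):
        fit = em_fit(
            mask,
            seed_subset,
            max_iter=max_iter,
            tol=config.tol,
            boundary_quantile=config.boundary_quantile,
        )
        return fit, fitness_degree(mask, fit.components, intensity)

    current_seeds = list(seeds)
    best_fit, best_fb = fit_and_score(current_seeds, config.max_iter)
    while len(current_seeds) > 1:
        trial_best = None
        for i in range(len(current_seeds)):
            subset = current_seeds[:i] + current_seeds[i + 1:]
            try:
                fit, fb = fit_and_score(subset, config.select_max_iter)
            except ValueError:
                continue
            if trial_best is None or fb.score > trial_best[2].score:
                trial_best = (i, fit, fb)
        if trial_best is None or trial_best[2].score <= best_fb.score:
            break
        i, best_fit, best_fb = trial_best
        current_seeds.pop(i)
    return best_fit, best_fb


def assign_pixels(mask: np.ndarray, components: list[EllipseComponent]) -> np.ndarray:
    """Maximum-posterior component label per foreground pixel.

    Background is 0; labels are 1..K; exact posterior ties break toward the
    lower component index (argmax convention).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    coords = np.argwhere(mask).astype(float)
    if len(coords) == 0 or not components:
        return labels
    log_post = np.empty((len(coords), len(components)))
    for j, comp in enumerate(components):
        log_post[:, j] = np.log(comp.weight + 1e-300) + _log_gauss(
            coords, comp.mean, comp.covariance
        )
    best = np.argmax(log_post, axis=1)
    labels[mask] = best + 1
    return labels


def segment(
    channels: dict[str, np.ndarray],
    config: SegmentConfig | None = None,
    um_per_px: float = 1.0,
) -> tuple[list[CellRecord], np.ndarray]:
    """Full workflow: binarize, seed, select components, assign pixels.

    Returns one record per retained component (center, ellipse parameters,
    pixel area and per-channel mean intensity over its labeled pixels) plus
    the label map. Deterministic: no random numbers are consumed.
    """
    config = config or SegmentConfig()
    if config.nuclear_channel not in channels:
        raise KeyError(f"nuclear channel {config.nuclear_channel!r} missing")
    nuclear = channels[config.nuclear_channel]
    mask = binarize(nuclear, config.binarize)
    seeds = detect_seeds(mask, config.merge_dist_px)
    if not seeds:
        return [], np.zeros(np.asarray(nuclear).shape, dtype=np.int32)
    fit, _ = select_components(mask, seeds, intensity=nuclear, config=config)
    labels = assign_pixels(mask, fit.components)

    records: list[CellRecord] = []
    for j, comp in enumerate(fit.components):
        region = labels == (j + 1)
        area = int(region.sum())
        if area == 0:
            continue
        means = {name: float(np.asarray(img, dtype=float)[region].mean())
                 for name, img in channels.items()}
        r, c = float(comp.mean[0]), float(comp.mean[1])
        records.append(
            CellRecord(
                cell_id=len(records) + 1,
                center_rc=(r, c),
                center_um=(c * um_per_px, r * um_per_px),
                ellipse=comp.ellipse_params(),
                area_px=area,
                channel_means=means,
            )
        )
    return records, labels
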