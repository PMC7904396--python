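"""Hierarchical normalized-cross-correlation (NCC) myocardial tracking.

Tracks every masked myocardial point from end-diastole (ED) through
end-systole (ES) by chaining frame-to-frame dense displacement fields.
Each field is estimated by a four-level coarse-to-fine template-matching
cascade: large templates localise large image features, and successively
smaller templates ("segments", "chunks", "windows") refine the estimate in
smaller search radii seeded by the parent level.  Matches use NCC with
quadratic 3x3 subpixel refinement; each level's field is Gaussian-smoothed
before seeding the next, which suppresses tag-periodicity ("picket-fence")
false peaks.

Coordinates are 0-based pixel-centred ``(x = column, y = row)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "TaggedSequence",
    "TrajectoryField",
    "DegenerateTextureError",
    "ncc_match",
    "hierarchical_match",
    "track_sequence",
    "DEFAULT_LEVELS",
]

#: (template_size_px, search_radius_px, grid_stride_px) per level, coarse to
#: fine.  The coarsest template spans >= 2 tag periods at 6 mm tags / 1.5 mm px.
DEFAULT_LEVELS: tuple[tuple[int, int, int], ...] = (
    (49, 10, 12),
    (25, 6, 6),
    (13, 4, 3),
    (7, 2, 2),
)


class DegenerateTextureError(ValueError):
    """Raised when a template has (near-)zero intensity variance."""


@dataclass
class TaggedSequence:
    """A time-ordered stack of 2D frames for one LV slice, ED first, ES last.

    Frames are normalized to zero-mean unit-variance intensity.
    """

    frames: np.ndarray  # (T, rows, cols)
    pixel_size_mm: float
    slice_level: str  # 'basal' | 'midventricular' | 'apical'

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (T, rows, cols) stack with T >= 2")
        if self.slice_level not in ("basal", "midventricular", "apical"):
            raise ValueError(f"unknown slice_level {self.slice_level!r}")

    @classmethod
    def from_frames(
        cls, frames: np.ndarray, pixel_size_mm: float, slice_level: str
    ) -> "TaggedSequence":
        """Build a sequence, normalizing each frame to zero mean, unit variance."""
        frames = np.asarray(frames, dtype=np.float64)
        out = np.empty_like(frames)
        for t, f in enumerate(frames):
            sd = f.std()
            if sd == 0:
                raise ValueError(f"frame {t} has zero intensity variance")
            out[t] = (f - f.mean()) / sd
        return cls(out, pixel_size_mm, slice_level)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class TrajectoryField:
    """Tracked positions of all masked myocardial points across frames.

    ``positions[:, 0]`` equals ``seed_points`` exactly; the difference
    vector convention is V = P_ED - P_current, so V at frame 0 is zero.
    """

    seed_points: np.ndarray  # (N, 2) ED (x, y) pixel coords
    positions: np.ndarray  # (N, T, 2)
    ncc_peaks: np.ndarray  # (N, T), peak NCC of the match that placed each point
    mask: np.ndarray  # (rows, cols) bool, ED myocardium
    pixel_size_mm: float = 1.0
    slice_level: str = "midventricular"

    def __post_init__(self) -> None:
        if not np.array_equal(self.positions[:, 0], self.seed_points):
            raise ValueError("positions at frame 0 must equal the seed points")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def difference_vectors(self) -> np.ndarray:
        """V(x, y) = P_ED - P_current, shape (N, T, 2)."""
        return self.seed_points[:, None, :] - self.positions

    @property
    def displacements(self) -> np.ndarray:
        """u = P_current - P_ED, shape (N, T, 2)."""
        return self.positions - self.seed_points[:, None, :]


# -- single-template NCC ------------------------------------------------------


def _ncc_surface(template: np.ndarray, window: np.ndarray) -> np.ndarray:
    """NCC of ``template`` against every placement inside ``window``."""
    th, tw = template.shape
    t0 = template - template.mean()
    t_norm = np.sqrt((t0**2).sum())
    if t_norm < 1e-12:
        raise DegenerateTextureError("template has zero intensity variance")
    views = sliding_window_view(window, (th, tw))
    n = th * tw
    sums = views.sum(axis=(-2, -1))
    sq = (views**2).sum(axis=(-2, -1))
    cross = np.einsum("mnhw,hw->mn", views, t0, optimize=True)
    var = np.maximum(sq - sums**2 / n, 0.0)
    w_norm = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = cross / (t_norm * w_norm)
    ncc[w_norm < 1e-12] = 0.0
    return np.clip(ncc, -1.0, 1.0)


def _subpixel_peak(surface: np.ndarray, ij: tuple[int, int]) -> np.ndarray:
    """Quadratic 1D fits through the 3x3 neighbourhood of an integer peak."""
    i, j = ij
    out = np.array([float(j), float(i)])  # (x, y)
    if 0 < i < surface.shape[0] - 1:
        c0, c1, c2 = surface[i - 1, j], surface[i, j], surface[i + 1, j]
        denom = c0 - 2 * c1 + c2
        if abs(denom) > 1e-12:
            out[1] += float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    if 0 < j < surface.shape[1] - 1:
        c0, c1, c2 = surface[i, j - 1], surface[i, j], surface[i, j + 1]
        denom = c0 - 2 * c1 + c2
        if abs(denom) > 1e-12:
            out[0] += float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    return out


def ncc_match(template: np.ndarray, search_window: np.ndarray) -> tuple[np.ndarray, float]:
    """Best NCC placement of ``template`` inside ``search_window``.

    Returns
    -------
    offset : (2,) float array
        Subpixel (x, y) displacement of the template's best placement
        relative to the *centred* placement; (0, 0) means the template sits
        at the centre of the search window.
    peak : float
        NCC value at the integer peak, in [-1, 1].

    Raises
    ------
    DegenerateTextureError
        If the template has zero intensity variance (NCC undefined); the
        caller should fall back to the parent hierarchy level's estimate.
    """
    template = np.asarray(template, dtype=np.float64)
    search_window = np.asarray(search_window, dtype=np.float64)
    if template.shape[0] > search_window.shape[0] or template.shape[1] > search_window.shape[1]:
        raise ValueError("template must fit inside the search window")
    surface = _ncc_surface(template, search_window)
    mag = np.abs(surface)  # peak strength; sign reported separately
    center = (np.array(surface.shape) - 1) / 2.0
    # integer peak; ties broken toward the smaller displacement
    maxv = mag.max()
    cand = np.argwhere(mag >= maxv - 1e-12)
    d2 = ((cand - center) ** 2).sum(axis=1)
    i, j = cand[np.argmin(d2)]
    if mag[i, j] >= 1.0 - 1e-9:
        # perfect correlation: the integer peak is exact, refinement could
        # only shift it (identical frames must give identically zero offset)
        sub = np.array([float(j), float(i)])
    else:
        sub = _subpixel_peak(mag, (int(i), int(j)))
    offset = sub - center[::-1]  # convert (x, y) against centred placement
    return offset, float(surface[i, j])


# -- dense hierarchical matching ---------------------------------------------


def _interp_field(field: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                  points_xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (len(ys), len(xs), 2) grid field."""
    itp = RegularGridInterpolator(
        (ys, xs), field, method="linear", bounds_error=False, fill_value=None
    )
    pts = np.column_stack([points_xy[:, 1], points_xy[:, 0]])
    return itp(pts)


def hierarchical_match(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    mask: np.ndarray,
    levels: tuple[tuple[int, int, int], ...] = DEFAULT_LEVELS,
    smoothing_sigma: float = 1.0,
    return_peaks: bool = False,
    init_field: np.ndarray | None = None,
) -> np.ndarray:
    """Dense displacement field frame_a -> frame_b over the mask.

    Runs the coarse-to-fine NCC cascade on a control grid covering the
    mask, smooths each level's field, and seeds the next level by bilinear
    interpolation.  Returns a (rows, cols, 2) array of (x, y) displacements
    valid over (a dilation of) the mask; displacement magnitudes are
    bounded by the cascade's total search range.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have the same shape")
    if mask.shape != frame_a.shape:
        raise ValueError("mask must match the frame shape")
    if not mask.any():
        raise ValueError("empty mask")
    rows, cols = frame_a.shape

    # control points must cover the mask plus room for points that move
    region = ndimage.binary_dilation(mask, iterations=max(r for _, r, _ in levels))

    if init_field is not None:
        field = np.array(init_field, dtype=np.float64)
        if field.shape != (rows, cols, 2):
            raise ValueError("init_field must have shape (rows, cols, 2)")
    else:
        field = np.zeros((rows, cols, 2), dtype=np.float64)
    peak_dense = np.zeros((rows, cols), dtype=np.float64)
    n_fallback = 0
    for win, radius, stride in levels:
        half = win // 2
        gy = np.arange(half, rows - half, stride)
        gx = np.arange(half, cols - half, stride)
        if len(gy) < 2 or len(gx) < 2:
            continue  # image too small for this level; keep parent field
        gfield = np.zeros((len(gy), len(gx), 2), dtype=np.float64)
        gpeak = np.zeros((len(gy), len(gx)), dtype=np.float64)
        gvalid = np.zeros((len(gy), len(gx)), dtype=bool)
        for iy, y in enumerate(gy):
            for ix, x in enumerate(gx):
                if not region[y, x]:
                    continue
                pred = field[y, x]
                pred_int = np.rint(pred).astype(int)
                ty0, tx0 = y - half, x - half
                template = frame_a[ty0 : ty0 + win, tx0 : tx0 + win]
                sy0 = ty0 + pred_int[1] - radius
                sx0 = tx0 + pred_int[0] - radius
                if (
                    sy0 < 0
                    or sx0 < 0
                    or sy0 + win + 2 * radius > rows
                    or sx0 + win + 2 * radius > cols
                ):
                    gfield[iy, ix] = pred  # fallback: parent estimate
                    gvalid[iy, ix] = True
                    n_fallback += 1
                    continue
                window = frame_b[sy0 : sy0 + win + 2 * radius, sx0 : sx0 + win + 2 * radius]
                try:
                    offset, peak = ncc_match(template, window)
                except DegenerateTextureError:
                    gfield[iy, ix] = pred
                    gvalid[iy, ix] = True
                    n_fallback += 1
                    continue
                gfield[iy, ix] = pred_int + offset
                gpeak[iy, ix] = peak
                gvalid[iy, ix] = True
        if not gvalid.any():
            continue
        # fill unvisited grid nodes from nearest valid neighbour so that the
        # smoothing and interpolation below see a complete grid
        if not gvalid.all():
            idx = ndimage.distance_transform_edt(
                ~gvalid, return_distances=False, return_indices=True
            )
            gfield = gfield[tuple(idx)]
            gpeak = gpeak[tuple(idx)]
        for k in range(2):
            gfield[..., k] = ndimage.gaussian_filter(gfield[..., k], smoothing_sigma)
        # dense seed field for the next level
        jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
        pts = np.column_stack([jj.ravel(), ii.ravel()]).astype(float)
        field = _interp_field(gfield, gy.astype(float), gx.astype(float), pts).reshape(
            rows, cols, 2
        )
        peak_dense = _interp_field(
            gpeak[..., None], gy.astype(float), gx.astype(float), pts
        ).reshape(rows, cols)
    if n_fallback:
        warnings.warn(
            f"{n_fallback} control points fell back to the parent-level estimate "
            "(border or degenerate texture)",
            stacklevel=2,
        )
    if return_peaks:
        return field, peak_dense
    return field


def track_sequence(
    seq: TaggedSequence,
    mask: np.ndarray,
    levels: tuple[tuple[int, int, int], ...] = DEFAULT_LEVELS,
) -> TrajectoryField:
    """Track every masked point through the sequence.

    Every frame is registered to the end-diastolic frame directly
    (ED-referenced matching is drift-free: it does not accumulate
    per-pair bias the way frame-to-frame composition does).  The first
    frame pair runs the full coarse-to-fine cascade; for later frames the
    previous frame's displacement field — accurate to well under the
    finest search radius, since inter-frame motion is small — replaces
    the coarse levels as the seed, and only the finest level re-matches.
    This keeps every search inside half a tag period, which is what
    defeats picket-fence lobe locking once cumulative motion approaches
    the tag spacing.  ``positions[p][t]`` estimates the material point's
    location at frame ``t``; deterministic for fixed inputs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != seq.shape:
        raise ValueError("mask must match the frame shape")
    ys, xs = np.nonzero(mask)
    seeds = np.column_stack([xs, ys]).astype(np.float64)
    n, T = len(seeds), seq.n_frames
    positions = np.empty((n, T, 2), dtype=np.float64)
    positions[:, 0] = seeds
    peaks = np.ones((n, T), dtype=np.float64)
    prev_field = None
    for t in range(1, T):
        frame_levels = levels if prev_field is None else levels[-1:]
        fld, pk = hierarchical_match(
            seq.frames[0], seq.frames[t], mask, levels=frame_levels,
            return_peaks=True, init_field=prev_field,
        )
        positions[:, t] = seeds + fld[ys, xs]
        peaks[:, t] = pk[ys, xs]
        prev_field = fld
    return TrajectoryField(
        seed_points=seeds,
        positions=positions,
        ncc_peaks=peaks,
        mask=mask,
        pixel_size_mm=seq.pixel_size_mm,
        slice_level=seq.slice_level,
    )
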