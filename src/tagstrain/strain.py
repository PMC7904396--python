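"""Green-Lagrange strain from tracked trajectories, and AHA segmentation.

The strain reference configuration is end-diastole (ED).  For each masked
point the ED->frame deformation gradient is built from finite differences
of the tracked displacement on the regular ED pixel lattice::

    u = P_current - P_ED
    F = I + grad(u)          (gradients w.r.t. ED coordinates)
    E = (F^T F - I) / 2      (Green-Lagrange tensor, symmetric, E=0 at ED)

and projected onto the local circumferential direction, CS = e_c' E e_c,
with e_r the unit vector from the mask centroid to the point and e_c its
+90 deg (counterclockwise, y-up) rotation.  CS is a quadratic form, so the
stored y-down image orientation affects only the sign of e_c, never CS.
Healthy systolic shortening gives CS < 0 at end-systole.

An alternative "literal" convention is kept behind a switch: with the
difference vector V = P_ED - P_current and D = (I - grad V)^{-1}, the
tensor is E = (D^T D - I)/2.  Note D is then the *inverse* of F above, so
the two conventions are not equivalent; the ED-referenced form is the
default because it yields the expected negative end-systolic CS.

The myocardium is partitioned into the 16-segment AHA model: 6 basal,
6 midventricular and 4 apical equal-angle sectors anchored at the anterior
RV-insertion angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import TrajectoryField

__all__ = [
    "StrainField",
    "AHASegmentation",
    "displacement_gradient",
    "green_lagrange",
    "local_frames",
    "circumferential_strain",
    "partition_aha",
    "compute_strain_field",
    "plot_aha_overlay",
    "SEGMENT_NAMES",
    "SLICE_SEGMENT_IDS",
]

#: AHA segment ids per slice and their anatomical names, in counterclockwise
#: order starting at the anterior RV insertion (y-up display orientation).
SLICE_SEGMENT_IDS = {
    "basal": (1, 6, 5, 4, 3, 2),
    "midventricular": (7, 12, 11, 10, 9, 8),
    "apical": (13, 16, 15, 14),
}

SEGMENT_NAMES = {
    1: "anterior", 2: "anteroseptal", 3: "inferoseptal",
    4: "inferior", 5: "inferolateral", 6: "anterolateral",
    7: "anterior", 8: "anteroseptal", 9: "inferoseptal",
    10: "inferior", 11: "inferolateral", 12: "anterolateral",
    13: "anterior", 14: "septal", 15: "inferior", 16: "lateral",
}


@dataclass
class StrainField:
    """Per-point, per-frame strain tensors and circumferential projections.

    Arrays are indexed by trajectory point; ``valid`` marks points whose
    finite-difference stencil had at least one lattice neighbour per axis.
    """

    points: np.ndarray  # (N, 2) ED (x, y)
    E: np.ndarray  # (N, T, 2, 2) Green-Lagrange tensors
    cs: np.ndarray  # (N, T) circumferential strain, NaN where invalid
    e_r: np.ndarray  # (N, 2)
    e_c: np.ndarray  # (N, 2)
    valid: np.ndarray  # (N,) bool


@dataclass
class AHASegmentation:
    """Per-pixel AHA segment labels for one slice."""

    labels: np.ndarray  # (rows, cols) int, 0 outside the mask
    slice_level: str
    rv_insertion_angle_deg: float

    @property
    def segment_ids(self) -> tuple[int, ...]:
        return SLICE_SEGMENT_IDS[self.slice_level]

    def names(self) -> dict[int, str]:
        return {sid: SEGMENT_NAMES[sid] for sid in self.segment_ids}


# -- displacement gradients ---------------------------------------------------


def _lattice_arrays(traj: TrajectoryField, frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Scatter per-point displacements back onto the ED lattice (NaN elsewhere)."""
    rows, cols = traj.mask.shape
    u = np.full((rows, cols, 2), np.nan)
    seeds = np.rint(traj.seed_points).astype(int)
    disp = traj.displacements[:, frame]
    u[seeds[:, 1], seeds[:, 0]] = disp
    return u, traj.mask


def _masked_diff(f: np.ndarray, valid: np.ndarray, axis: int) -> np.ndarray:
    """Central differences where both neighbours are valid, one-sided at the
    mask boundary, NaN where no neighbour exists along the axis."""
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    vp = np.roll(valid, -1, axis=axis)
    vm = np.roll(valid, 1, axis=axis)
    # roll wraps around; kill the wrapped edge
    edge_hi = [slice(None)] * f.ndim
    edge_hi[axis] = -1
    edge_lo = [slice(None)] * f.ndim
    edge_lo[axis] = 0
    vp = vp.copy()
    vm = vm.copy()
    vp[tuple(edge_hi[: valid.ndim])] = False
    vm[tuple(edge_lo[: valid.ndim])] = False
    out = np.full_like(f, np.nan)
    central = vp & vm
    fwd = vp & ~vm
    bwd = vm & ~vp
    out[central] = ((fp - fm) / 2.0)[central]
    out[fwd] = (fp - f)[fwd]
    out[bwd] = (f - fm)[bwd]
    return out


def displacement_gradient(traj: TrajectoryField, frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-point displacement gradient grad(u) at ``frame``.

    Returns ``(G, valid)`` with ``G`` of shape (N, 2, 2),
    ``G[p, i, j] = d u_i / d x_j`` (x0 = x/column, x1 = y/row), computed by
    central differences on the ED lattice with one-sided differences at the
    mask boundary.  Points with no lattice neighbour along either axis are
    marked invalid and excluded from segment statistics downstream.

    The difference-vector gradient follows as ``grad(V) = -G`` since
    V = P_ED - P_current = -u.
    """
    u, mask = _lattice_arrays(traj, frame)
    vm = mask & np.isfinite(u[..., 0])
    du_dx = _masked_diff(u, np.broadcast_to(vm[..., None], u.shape), axis=1)
    du_dy = _masked_diff(u, np.broadcast_to(vm[..., None], u.shape), axis=0)
    seeds = np.rint(traj.seed_points).astype(int)
    sx, sy = seeds[:, 0], seeds[:, 1]
    G = np.empty((len(seeds), 2, 2))
    G[:, 0, 0] = du_dx[sy, sx, 0]
    G[:, 1, 0] = du_dx[sy, sx, 1]
    G[:, 0, 1] = du_dy[sy, sx, 0]
    G[:, 1, 1] = du_dy[sy, sx, 1]
    valid = np.isfinite(G).all(axis=(1, 2))
    return G, valid


def green_lagrange(G: np.ndarray, convention: str = "ed-referenced") -> np.ndarray:
    """Green-Lagrange tensor from displacement gradients.

    ``convention='ed-referenced'`` (default): F = I + grad(u),
    E = (F^T F - I)/2.  ``convention='literal'``: D = (I - grad V)^{-1}
    with grad V = -grad u, and E = (D^T D - I)/2.
    """
    G = np.asarray(G, dtype=float)
    I = np.eye(2)
    if convention == "ed-referenced":
        F = I + G
    elif convention == "literal":
        F = np.linalg.inv(I + G)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - I)
    return 0.5 * (E + np.swapaxes(E, -1, -2))  # enforce exact symmetry


def local_frames(points: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radial and circumferential unit vectors at each point.

    ``e_r`` points from the mask centroid to the point; ``e_c`` is ``e_r``
    rotated +90 deg counterclockwise in the displayed (y-up) orientation,
    which in stored (x = col, y = row-down) coordinates is
    ``e_c = (e_r_y, -e_r_x)``.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if len(ys) == 0:
        raise ValueError("empty mask has no centroid")
    centroid = np.array([xs.mean(), ys.mean()])
    d = np.atleast_2d(points) - centroid
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm < 1e-9):
        raise ValueError("point coincident with the mask centroid")
    e_r = d / norm[:, None]
    e_c = np.column_stack([e_r[:, 1], -e_r[:, 0]])
    return e_r, e_c


def circumferential_strain(E: np.ndarray, e_c: np.ndarray) -> np.ndarray:
    """CS = e_c' E e_c for tensors (..., 2, 2) and directions (..., 2)."""
    return np.einsum("...i,...ij,...j->...", e_c, E, e_c)


def compute_strain_field(
    traj: TrajectoryField, convention: str = "ed-referenced"
) -> StrainField:
    """Full strain pipeline over all frames of a trajectory field."""
    n, T = traj.positions.shape[:2]
    e_r, e_c = local_frames(traj.seed_points, traj.mask)
    E = np.zeros((n, T, 2, 2))
    cs = np.full((n, T), np.nan)
    cs[:, 0] = 0.0
    valid = np.ones(n, dtype=bool)
    for t in range(1, T):
        G, v = displacement_gradient(traj, t)
        Gc = np.where(v[:, None, None], G, 0.0)
        Et = green_lagrange(Gc, convention=convention)
        E[:, t] = np.where(v[:, None, None], Et, np.nan)
        cs[:, t] = np.where(v, circumferential_strain(Et, e_c), np.nan)
        valid &= v
    return StrainField(points=traj.seed_points, E=E, cs=cs, e_r=e_r, e_c=e_c, valid=valid)


# -- AHA partition ------------------------------------------------------------


def partition_aha(
    mask: np.ndarray, slice_level: str, rv_insertion_angle_deg: float
) -> AHASegmentation:
    """Assign each masked pixel its AHA segment id.

    The polar angle about the mask centroid (counterclockwise from the +x
    axis, y-up display orientation) is offset by the anterior RV-insertion
    angle; equal-angle sectors (60 deg for basal/mid, 90 deg for apical)
    are numbered counterclockwise starting at the insertion, in the order
    given by ``SLICE_SEGMENT_IDS``.  Rotating the insertion angle by one
    sector width permutes the ids cyclically.
    """
    if slice_level not in SLICE_SEGMENT_IDS:
        raise ValueError(f"unknown slice_level {slice_level!r}")
    if not 0.0 <= rv_insertion_angle_deg < 360.0:
        raise ValueError("rv_insertion_angle_deg must lie in [0, 360)")
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask has no centroid")
    cx, cy = xs.mean(), ys.mean()
    ids = SLICE_SEGMENT_IDS[slice_level]
    width = 360.0 / len(ids)
    theta = np.degrees(np.arctan2(cy - ys, xs - cx)) % 360.0  # y-up angle
    phi = (theta - rv_insertion_angle_deg) % 360.0
    sector = np.minimum((phi // width).astype(int), len(ids) - 1)
    labels = np.zeros(mask.shape, dtype=int)
    labels[ys, xs] = np.asarray(ids)[sector]
    return AHASegmentation(
        labels=labels, slice_level=slice_level,
        rv_insertion_angle_deg=rv_insertion_angle_deg,
    )


def plot_aha_overlay(segmentation: AHASegmentation, background: np.ndarray,
                     path) -> None:
    """Save a PNG of the AHA partition drawn over an image frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(background, cmap="gray", interpolation="nearest")
    lab = np.ma.masked_equal(segmentation.labels, 0)
    ax.imshow(lab, cmap="tab20", alpha=0.45, interpolation="nearest")
    for sid, name in segmentation.names().items():
        sel = segmentation.labels == sid
        if sel.any():
            ys, xs = np.nonzero(sel)
            ax.text(xs.mean(), ys.mean(), f"{sid}", color="w", ha="center",
                    va="center", fontsize=9)
    ax.set_title(f"{segmentation.slice_level} AHA segments")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
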