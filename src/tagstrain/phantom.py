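"""Synthetic grid-tagged short-axis left-ventricle phantom.

Generates cine stacks of an annular LV cross-section carrying a tag grid,
deforming by incompressible circumferential contraction with optional
regionally reduced contractility ("infarcted" sectors), rigid twist, tag
fading and additive Gaussian noise.  The motion is closed-form in both
directions, so every frame, the end-diastolic mask, and the pointwise
circumferential Green-Lagrange strain are available analytically — the
phantom is the ground-truth oracle for the tracking and strain stages.

Geometry and coordinates
------------------------
Images are stored row-major; pixel coordinates are 0-based, pixel-centred,
``(x = column, y = row)``.  The phantom is centred at the image centre.
Polar angles are measured counterclockwise from the +x axis in the
displayed (y-up) orientation.  Radii in the config are in millimetres and
converted through ``pixel_size_mm``.

Motion model
------------
A material point at end-diastolic (ED) radius ``r`` and angle ``theta``
moves at frame ``t`` to::

    r'(t)     = sqrt(r**2 - c(theta) * delta(t))
    theta'(t) = theta + twist * t / (n_frames - 1)

where ``delta(t)`` ramps linearly from 0 at ED to
``endo_radius_ed**2 - endo_radius_es**2`` at end-systole (ES, the last
frame) and ``c(theta)`` in [0, 1] is the local contractility (1 = full,
0 = akinetic).  With ``c = 1`` this is the area-preserving contraction of
an incompressible ring.  The circumferential stretch is
``lambda_c = r'/r`` and the circumferential Green-Lagrange strain is
``E_cc = (lambda_c**2 - 1) / 2``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhantomConfig",
    "GroundTruthMotion",
    "generate_phantom",
    "analytic_cs",
]

#: angular half-width (degrees) of the cosine ramp blending sector
#: contractility into the surrounding tissue
SECTOR_RAMP_HALF_DEG = 5.0


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic tagged-LV sequence.

    Defaults emulate the acquisition this phantom stands in for: 6 mm tag
    spacing and a mid-range 1.5 mm isotropic pixel.
    """

    image_size_px: tuple[int, int] = (128, 128)  # (rows, cols)
    pixel_size_mm: float = 1.5
    tag_spacing_mm: float = 6.0
    endo_radius_ed_mm: float = 25.0
    epi_radius_ed_mm: float = 35.0
    endo_radius_es_mm: float = 16.0
    n_frames: int = 8
    #: (start_angle_deg, end_angle_deg, contractility) triples; angles in
    #: [0, 360), counterclockwise, sector spans start -> end going CCW.
    infarct_sectors: tuple[tuple[float, float, float], ...] = ()
    twist_deg: float = 0.0
    noise_sd: float = 0.0
    tag_fading: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2 (ED..ES)")
        if not (0 < self.endo_radius_ed_mm < self.epi_radius_ed_mm):
            raise ValueError("need 0 < endo_radius_ed < epi_radius_ed")
        # equality permitted: endo_es == endo_ed is the motionless phantom
        if not (0 < self.endo_radius_es_mm <= self.endo_radius_ed_mm):
            raise ValueError("need 0 < endo_radius_es <= endo_radius_ed")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.tag_spacing_mm / self.pixel_size_mm < 2.0:
            raise ValueError("tags unresolvable: tag_spacing must span >= 2 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.tag_fading <= 1.0:
            raise ValueError("tag_fading must lie in [0, 1]")
        for a0, a1, c in self.infarct_sectors:
            if not (0.0 <= a0 < 360.0 and 0.0 <= a1 < 360.0):
                raise ValueError("sector angles must lie in [0, 360)")
            if not 0.0 <= c <= 1.0:
                raise ValueError("sector contractility must lie in [0, 1]")
        # Motion must stay defined on the whole annulus: worst case is a
        # fully contractile point at the endocardium at ES.
        if self.endo_radius_ed_mm**2 - self.delta_es_mm2 < 0:
            raise ValueError("motion undefined: r**2 - delta < 0 inside annulus")

    # -- derived quantities -------------------------------------------------

    @property
    def delta_es_mm2(self) -> float:
        """End-systolic value of the contraction parameter delta (mm^2)."""
        return self.endo_radius_ed_mm**2 - self.endo_radius_es_mm**2

    @property
    def center_px(self) -> tuple[float, float]:
        """Phantom centre in (x, y) pixel coordinates."""
        rows, cols = self.image_size_px
        return ((cols - 1) / 2.0, (rows - 1) / 2.0)

    def delta_mm2(self, frame: int) -> float:
        """Contraction parameter at ``frame``, linear ED -> ES ramp."""
        return self.delta_es_mm2 * frame / (self.n_frames - 1)

    def twist_rad(self, frame: int) -> float:
        return math.radians(self.twist_deg) * frame / (self.n_frames - 1)

    def contractility(self, theta_rad: np.ndarray) -> np.ndarray:
        """Local contractility c(theta), sectors blended by a cosine ramp.

        Inside a sector's core the contractility equals the sector value;
        across each boundary it ramps smoothly over 2*SECTOR_RAMP_HALF_DEG.
        Overlapping sectors combine by taking the strongest reduction.
        """
        theta_deg = np.degrees(np.asarray(theta_rad, dtype=float)) % 360.0
        c = np.ones_like(theta_deg)
        ramp = SECTOR_RAMP_HALF_DEG
        for a0, a1, c_sec in self.infarct_sectors:
            width = (a1 - a0) % 360.0
            if width == 0.0:
                continue
            # signed angular distance from sector start, in [0, 360)
            d = (theta_deg - a0) % 360.0
            # distance *into* the sector, negative outside; measured from the
            # nearer boundary
            inside = np.minimum(d, width - d)
            outside = np.minimum((a0 - theta_deg) % 360.0, (theta_deg - a1) % 360.0)
            dist = np.where(d <= width, inside, -outside)
            s = np.clip((dist + ramp) / (2.0 * ramp), 0.0, 1.0)
            w = 0.5 - 0.5 * np.cos(np.pi * s)  # 0 outside .. 1 in the core
            c = np.minimum(c, 1.0 + (c_sec - 1.0) * w)
        return c


@dataclass(frozen=True)
class GroundTruthMotion:
    """Analytic forward map and strain oracle attached to a config."""

    config: PhantomConfig

    # -- unit helpers -------------------------------------------------------

    def _to_mm(self, points_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """ED pixel coords (x, y) -> centred mm coords (x right, y up)."""
        cx, cy = self.config.center_px
        p = np.atleast_2d(np.asarray(points_px, dtype=float))
        x = (p[:, 0] - cx) * self.config.pixel_size_mm
        y = (cy - p[:, 1]) * self.config.pixel_size_mm
        return x, y

    def _to_px(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        cx, cy = self.config.center_px
        return np.stack(
            [cx + x_mm / self.config.pixel_size_mm,
             cy - y_mm / self.config.pixel_size_mm], axis=-1)

    # -- analytic motion ----------------------------------------------------

    def map_forward(self, points_px: np.ndarray, frame: int) -> np.ndarray:
        """Map ED points (N, 2) in pixel coords to their frame-``frame`` positions."""
        cfg = self.config
        x, y = self._to_mm(points_px)
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        r2p = r**2 - cfg.contractility(theta) * cfg.delta_mm2(frame)
        if np.any(r2p < -1e-9):
            raise ValueError("forward map undefined (r**2 - c*delta < 0)")
        rp = np.sqrt(np.maximum(r2p, 0.0))
        tp = theta + cfg.twist_rad(frame)
        return self._to_px(rp * np.cos(tp), rp * np.sin(tp))

    def lambda_c(self, points_px: np.ndarray, frame: int) -> np.ndarray:
        """Circumferential stretch at ED points (pixel coords).

        The image of an ED circle of radius r, parametrised by theta, has
        tangent (dr'/dtheta) e_r' + r' e_theta', so the stretch of the ED
        arc element r dtheta is sqrt((dr'/dtheta)**2 + r'**2) / r.  With
        uniform contractility dr'/dtheta = 0 and this reduces to r'/r;
        inside sector blending ramps the tangential gradient of r'
        contributes.  dc/dtheta is evaluated by a tiny central difference
        (the blending profile is C1, so this is accurate to ~1e-9).
        """
        cfg = self.config
        x, y = self._to_mm(points_px)
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        if np.any(r <= 0):
            raise ValueError("point at the phantom centre has no angle")
        delta = cfg.delta_mm2(frame)
        rp = np.sqrt(r**2 - cfg.contractility(theta) * delta)
        h = 1e-6
        dc = (cfg.contractility(theta + h) - cfg.contractility(theta - h)) / (2 * h)
        drp_dtheta = np.where(rp > 0, -delta * dc / (2 * np.maximum(rp, 1e-12)), 0.0)
        return np.sqrt(drp_dtheta**2 + rp**2) / r

    def e_cc(self, points_px: np.ndarray, frame: int) -> np.ndarray:
        """Analytic circumferential Green-Lagrange strain at ED points."""
        lam = self.lambda_c(points_px, frame)
        return 0.5 * (lam**2 - 1.0)

    def in_annulus(self, points_px: np.ndarray) -> np.ndarray:
        cfg = self.config
        x, y = self._to_mm(points_px)
        r = np.hypot(x, y)
        return (r >= cfg.endo_radius_ed_mm) & (r <= cfg.epi_radius_ed_mm)

    def sector_infarcted(self, theta_deg: float, threshold: float = 0.5) -> bool:
        """Whether contractility at ``theta_deg`` is below ``threshold``."""
        return bool(self.config.contractility(np.radians([theta_deg]))[0] < threshold)


def analytic_cs(config: PhantomConfig, point_px: Sequence[float], frame: int) -> float:
    """Closed-form circumferential strain for one ED point (pixel coords).

    Pure function of its inputs; frame 0 returns exactly 0.  Raises
    ``ValueError`` for points outside the ED annulus.
    """
    gt = GroundTruthMotion(config)
    p = np.asarray(point_px, dtype=float).reshape(1, 2)
    if not gt.in_annulus(p)[0]:
        raise ValueError("point outside the ED annulus")
    if frame == 0:
        return 0.0
    return float(gt.e_cc(p, frame)[0])


# -- rendering ----------------------------------------------------------------


def _tag_modulation(x_mm: np.ndarray, y_mm: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Product of two orthogonal raised cosines: 1 on tag lines, 0 between."""
    gx = 0.5 + 0.5 * np.cos(2.0 * np.pi * x_mm / spacing_mm)
    gy = 0.5 + 0.5 * np.cos(2.0 * np.pi * y_mm / spacing_mm)
    return gx * gy


def generate_phantom(
    config: PhantomConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruthMotion]:
    """Render the tagged cine stack, the ED myocardium mask, and ground truth.

    Returns
    -------
    frames : (n_frames, rows, cols) float64
        Frame 0 is end-diastole, the last frame end-systole.  The annulus
        carries a Lagrangian (advected) tag texture; the background and the
        blood pool are static.  Per-frame Gaussian noise of ``noise_sd`` is
        added; identical configs (incl. seed) give bit-identical stacks.
    mask : (rows, cols) bool
        ED annulus.
    ground_truth : GroundTruthMotion
    """
    cfg = config
    rows, cols = cfg.image_size_px
    cx, cy = cfg.center_px
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    # current (Eulerian) position of each pixel centre, centred mm, y-up
    X = (jj - cx) * cfg.pixel_size_mm
    Y = (cy - ii) * cfg.pixel_size_mm
    Rp = np.hypot(X, Y)
    Tp = np.arctan2(Y, X)

    r_ed = Rp  # at ED the map is the identity
    mask = (r_ed >= cfg.endo_radius_ed_mm) & (r_ed <= cfg.epi_radius_ed_mm)

    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((cfg.n_frames, rows, cols), dtype=np.float64)
    tissue, cavity, background = 1.0, 0.25, 0.5
    for t in range(cfg.n_frames):
        amp = (1.0 - cfg.tag_fading) ** t
        delta = cfg.delta_mm2(t)
        # invert the motion: angle is advected rigidly, radius analytically
        theta0 = Tp - cfg.twist_rad(t)
        c = cfg.contractility(theta0)
        r0 = np.sqrt(Rp**2 + c * delta)
        in_myo = (r0 >= cfg.endo_radius_ed_mm) & (r0 <= cfg.epi_radius_ed_mm)
        # material (ED) coordinates of the preimage; tags are imprinted at ED
        x0 = r0 * np.cos(theta0)
        y0 = r0 * np.sin(theta0)
        tag_myo = _tag_modulation(x0, y0, cfg.tag_spacing_mm)
        tag_static = _tag_modulation(X, Y, cfg.tag_spacing_mm)
        endo_now = np.sqrt(np.maximum(cfg.endo_radius_ed_mm**2 - c * delta, 0.0))
        in_cavity = ~in_myo & (Rp < endo_now)
        img = np.where(
            in_myo,
            tissue * (1.0 - 0.8 * amp * tag_myo),
            np.where(
                in_cavity,
                cavity,
                background * (1.0 - 0.8 * amp * tag_static),
            ),
        )
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[t] = img
    return frames, mask, GroundTruthMotion(cfg)
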