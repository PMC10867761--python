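"""Synthetic flat-mount phantoms with known ground-truth tortuosity.

A phantom retina is a set of radial vessels emanating from a disc center,
each a straight ray perturbed by a sinusoid of amplitude ``a`` perpendicular
to the radial direction.  The continuous centerline has a closed quadrature
form for its arc length, so the true arc-to-chord ratio of every vessel is
known before rasterization — amplitude is the single tortuosity dial, the
way disease shifts a scalar index in real cohorts ("NOX-like" low amplitude
vs "OIR-like" high amplitude).

Rasterization stamps a disc of the stroke radius along the centerline
sampled at 4 points per pixel of arc, which guarantees a gap-free stroke.
Everything is driven by one integer seed; the same seed reproduces the same
masks bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .errors import ValidationError
from .mask_io import BinaryMask, DiscCenter, save_mask

__all__ = [
    "SynthConfig",
    "VesselGroundTruth",
    "SynthGroundTruth",
    "Cohort",
    "generate_retina",
    "generate_cohort",
    "match_segments_to_truth",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic retina.

    Vessels run radially from ``start_radius_px`` to
    ``start_radius_px + vessel_length_px`` from the disc center, perturbed
    perpendicular to the ray by ``amplitude_px * sin(2*pi*t/wavelength_px +
    phase)`` with a random per-vessel phase.  The disc center defaults to
    the image center.
    """

    image_size: tuple[int, int] = (1024, 1024)
    disc_center: tuple[float, float] | None = None
    n_vessels: int = 8
    stroke_width_px: float = 5.0
    amplitude_px: float = 10.0
    wavelength_px: float = 100.0
    start_radius_px: float = 130.0
    vessel_length_px: float = 330.0
    branch_prob: float = 0.0
    rotation_rad: float = 0.0  # rigid rotation of the whole vessel fan
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        if rows <= 0 or cols <= 0:
            raise ValidationError("image_size must be positive")
        if self.n_vessels < 1:
            raise ValidationError("n_vessels must be >= 1")
        if self.stroke_width_px <= 0 or self.wavelength_px <= 0:
            raise ValidationError("stroke width and wavelength must be positive")
        if self.amplitude_px < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.vessel_length_px <= 0 or self.start_radius_px < 0:
            raise ValidationError("vessel extent must be positive")

    @property
    def disc(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    def validate_fit(self) -> None:
        """Vessels (including amplitude and stroke) must fit in the image."""
        reach = (
            self.start_radius_px
            + self.vessel_length_px
            + self.amplitude_px
            + self.stroke_width_px / 2.0
            + 1.0
        )
        dr, dc = self.disc
        rows, cols = self.image_size
        if dr - reach < 0 or dr + reach > rows - 1 or dc - reach < 0 or dc + reach > cols - 1:
            raise ValidationError(
                f"vessels of reach {reach:.1f}px from disc ({dr:.0f}, {dc:.0f}) "
                f"do not fit inside a {rows}x{cols} image"
            )


@dataclass(frozen=True)
class VesselGroundTruth:
    """Analytic truth for one vessel centerline."""

    vessel_id: str
    angle_rad: float
    phase_rad: float
    amplitude_px: float
    wavelength_px: float
    arc_length_px: float
    chord_length_px: float
    ratio: float  # arc / chord, >= 1, exactly 1 when amplitude == 0
    centerline: np.ndarray  # (n, 2) float (row, col) samples
    is_branch: bool = False


@dataclass(frozen=True)
class SynthGroundTruth:
    vessels: tuple[VesselGroundTruth, ...]
    config: SynthConfig


def _centerline(
    cfg: SynthConfig, angle: float, phase: float, amplitude: float, ts: np.ndarray
) -> np.ndarray:
    """Centerline samples at radial offsets ``ts`` (0 = vessel start)."""
    dr, dc = cfg.disc
    u = np.array([math.cos(angle), math.sin(angle)])  # radial unit (row, col)
    n = np.array([-u[1], u[0]])  # perpendicular unit
    radial = cfg.start_radius_px + ts
    offset = amplitude * np.sin(2.0 * math.pi * ts / cfg.wavelength_px + phase)
    return np.array([dr, dc]) + radial[:, None] * u + offset[:, None] * n


def _true_arc_length(
    cfg: SynthConfig, phase: float, amplitude: float, length: float
) -> float:
    """Quadrature arc length of t -> (t, a sin(2 pi t / lambda + phase))."""
    k = 2.0 * math.pi / cfg.wavelength_px

    def speed(t: float) -> float:
        return math.hypot(1.0, amplitude * k * math.cos(k * t + phase))

    val, _ = quad(speed, 0.0, length, limit=200)
    return val


def _stamp(canvas: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Set to True every pixel within ``radius`` of any sample point."""
    r_int = int(math.ceil(radius))
    dy, dx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = np.argwhere(dy**2 + dx**2 <= radius**2) - r_int
    centers = np.rint(points).astype(int)
    pix = (centers[:, None, :] + disk[None, :, :]).reshape(-1, 2)
    np.clip(pix[:, 0], 0, canvas.shape[0] - 1, out=pix[:, 0])
    np.clip(pix[:, 1], 0, canvas.shape[1] - 1, out=pix[:, 1])
    canvas[pix[:, 0], pix[:, 1]] = True


def generate_retina(
    config: SynthConfig, image_id: str = "synth"
) -> tuple[BinaryMask, DiscCenter, SynthGroundTruth]:
    """Generate one phantom retina with per-vessel analytic ground truth.

    Ground truth (arc length by quadrature on the continuous centerline,
    chord from the exact endpoints) is computed before rasterization and is
    unaffected by stroke width or pixelation.
    """
    config.validate_fit()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_size
    canvas = np.zeros((rows, cols), dtype=bool)

    base = rng.uniform(0.0, 2.0 * math.pi) + config.rotation_rad
    truths: list[VesselGroundTruth] = []
    # 4 samples per pixel of arc; amplitude lengthens the curve, so scale up
    n_samples = max(int(4 * config.vessel_length_px * (1 + config.amplitude_px / 10)), 64)
    for k in range(config.n_vessels):
        angle = base + 2.0 * math.pi * k / config.n_vessels
        phase = rng.uniform(0.0, 2.0 * math.pi)
        ts = np.linspace(0.0, config.vessel_length_px, n_samples)
        line = _centerline(config, angle, phase, config.amplitude_px, ts)
        arc = _true_arc_length(config, phase, config.amplitude_px, config.vessel_length_px)
        chord = float(np.linalg.norm(line[-1] - line[0]))
        truths.append(
            VesselGroundTruth(
                vessel_id=f"v{k:02d}",
                angle_rad=angle,
                phase_rad=phase,
                amplitude_px=config.amplitude_px,
                wavelength_px=config.wavelength_px,
                arc_length_px=arc,
                chord_length_px=chord,
                ratio=arc / chord,
                centerline=line,
            )
        )
        _stamp(canvas, line, config.stroke_width_px / 2.0)
        if rng.random() < config.branch_prob:
            # straight offshoot: ratio exactly 1, flagged so recovery tests
            # can match it separately from the trunk vessels
            t0 = rng.uniform(0.35, 0.65) * config.vessel_length_px
            side = 1.0 if rng.random() < 0.5 else -1.0
            b_angle = angle + side * rng.uniform(0.35, 0.7)
            p0 = _centerline(config, angle, phase, config.amplitude_px, np.array([t0]))[0]
            b_len = 0.5 * (config.vessel_length_px - t0)
            u = np.array([math.cos(b_angle), math.sin(b_angle)])
            bs = np.linspace(0.0, b_len, max(int(4 * b_len), 16))
            b_line = p0 + bs[:, None] * u
            _stamp(canvas, b_line, config.stroke_width_px / 2.0)
            truths.append(
                VesselGroundTruth(
                    vessel_id=f"v{k:02d}b",
                    angle_rad=b_angle,
                    phase_rad=0.0,
                    amplitude_px=0.0,
                    wavelength_px=config.wavelength_px,
                    arc_length_px=b_len,
                    chord_length_px=b_len,
                    ratio=1.0,
                    centerline=b_line,
                    is_branch=True,
                )
            )

    disc = DiscCenter(row=config.disc[0], col=config.disc[1], image_id=image_id)
    mask = BinaryMask(pixels=canvas, image_id=image_id)
    return mask, disc, SynthGroundTruth(vessels=tuple(truths), config=config)


def rasterize_curve(
    points: np.ndarray,
    image_size: tuple[int, int],
    stroke_width_px: float = 5.0,
    image_id: str = "curve",
) -> BinaryMask:
    """Rasterize an arbitrary continuous curve as a stroked binary mask.

    ``points`` are dense (row, col) samples of the curve (aim for >= 4 per
    pixel of arc); a disc of half the stroke width is stamped at each.
    Useful for building analytic test curves (circular arcs, sinusoids).
    """
    canvas = np.zeros(image_size, dtype=bool)
    _stamp(canvas, np.asarray(points, dtype=float), stroke_width_px / 2.0)
    return BinaryMask(pixels=canvas, image_id=image_id)


@dataclass(frozen=True)
class Cohort:
    """An in-memory synthetic cohort, optionally mirrored to disk."""

    masks: tuple[BinaryMask, ...]
    discs: tuple[DiscCenter, ...]
    groups: pd.DataFrame  # image_id, condition, timepoint
    truths: tuple[SynthGroundTruth, ...]
    mask_dir: Path | None = None
    disc_csv: Path | None = None
    group_csv: Path | None = None


def generate_cohort(
    group_configs: dict[str, SynthConfig],
    n_images: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
    timepoint: str = "P17",
) -> Cohort:
    """Generate ``n_images`` phantoms per group, reproducibly from one seed.

    Each group's :class:`SynthConfig` sets its amplitude (and any other
    knobs); per-image seeds are spawned deterministically from ``seed``.
    With ``out_dir`` the cohort is also written to disk as PNG masks plus
    ``disc_centers.csv`` and ``groups.csv``.
    """
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    labels = list(group_configs)
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(labels) * n_images
    ) % (2**31)
    masks, discs, truths, rows = [], [], [], []
    idx = 0
    for label in labels:
        cfg = group_configs[label]
        for i in range(n_images):
            image_id = f"{label}_{i:03d}"
            mask, disc, truth = generate_retina(
                replace(cfg, seed=int(child_seeds[idx])), image_id=image_id
            )
            masks.append(mask)
            discs.append(disc)
            truths.append(truth)
            rows.append(
                {"image_id": image_id, "condition": label, "timepoint": timepoint}
            )
            idx += 1
    groups = pd.DataFrame(rows)

    mask_dir = disc_csv = group_csv = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        mask_dir = out_dir / "masks"
        mask_dir.mkdir(parents=True, exist_ok=True)
        for mask in masks:
            save_mask(mask, mask_dir / f"{mask.image_id}.png")
        disc_csv = out_dir / "disc_centers.csv"
        pd.DataFrame(
            [{"image_id": d.image_id, "row": d.row, "col": d.col} for d in discs]
        ).to_csv(disc_csv, index=False)
        group_csv = out_dir / "groups.csv"
        groups.to_csv(group_csv, index=False)
    return Cohort(
        masks=tuple(masks),
        discs=tuple(discs),
        groups=groups,
        truths=tuple(truths),
        mask_dir=mask_dir,
        disc_csv=disc_csv,
        group_csv=group_csv,
    )


def match_segments_to_truth(segments, truth: SynthGroundTruth) -> dict[str, object]:
    """Match extracted segments to ground-truth vessels by centerline proximity.

    For each ground-truth vessel, returns the segment whose chain centroid is
    nearest that vessel's centerline centroid (or None if no segment lies
    within half the vessel length).  Intended for recovery checks on
    phantoms, where segments and vessels correspond one to one.
    """
    out: dict[str, object] = {}
    seg_centroids = [np.mean(np.asarray(s.chain, float), axis=0) for s in segments]
    for v in truth.vessels:
        target = v.centerline.mean(axis=0)
        best, best_d = None, np.inf
        for s, c in zip(segments, seg_centroids):
            d = float(np.linalg.norm(c - target))
            if d < best_d:
                best, best_d = s, d
        out[v.vessel_id] = best if best_d < v.arc_length_px / 2.0 else None
    return out
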