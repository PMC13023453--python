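"""Synthetic two-channel FISH scenes with known ground truth.

Generates the validation surfaces the pipeline is tested against:

* **colocalization controls** — the same positions observed in both
  channels (true separation 0), so any measured distance is technical
  error: injected chromatic aberration plus localization noise;
* **nanoruler emulations** — pairs at a fixed physical separation
  (e.g. 120 or 160 nm, matching commercial DNA-origami distance standards)
  with uniformly random 3D orientation.

Two noise modes are kept deliberately separate: per-axis Gaussian noise in
*point space* (tests the corrections and statistics in isolation) and
Poisson shot noise in *image space* after rendering spots as 3D Gaussians
(tests detection and sub-pixel localization).

The chromatic aberration is injected into channel B only; channel A is the
reference frame, matching the pipeline's correction direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .correct import AffineTransform3D
from .io import PAIR_COLUMNS, VoxelGrid3D, DEFAULT_VOXEL_SIZE_NM

#: Attempt budget for rejection sampling, per requested spot.
REJECTION_CAP_PER_SPOT = 100


@dataclass
class SceneSpec:
    """Parameters of a synthetic two-channel scene.

    Parameters
    ----------
    n_spots
        Number of spot pairs.
    bounds_nm
        Per-axis sampling interval for channel-A positions,
        ``((x0, x1), (y0, y1), (z0, z1))`` in nm.
    true_separation_nm
        Physical pair separation L; 0 is a colocalization control,
        120/160 emulate nanorulers.
    min_separation_nm
        Minimum distance between distinct channel-A spots (rejection
        sampling); must exceed 4x the rendered spot sigma when the scene
        will be rendered, so neighboring spots never merge.
    aberration
        Affine chromatic aberration applied to channel B (identity = none).
    noise_sigma_nm
        Per-axis Gaussian localization noise s.d. (x, y, z), applied
        independently to both channels in point space.
    seed
        Seed for all randomness; identical specs give bit-identical scenes.
    """

    n_spots: int
    bounds_nm: tuple[tuple[float, float], ...] = (
        (0.0, 40000.0),
        (0.0, 40000.0),
        (0.0, 10000.0),
    )
    true_separation_nm: float = 0.0
    min_separation_nm: float = 250.0
    aberration: AffineTransform3D = field(default_factory=AffineTransform3D.identity)
    noise_sigma_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be positive")
        if self.true_separation_nm < 0:
            raise ValueError("true_separation_nm must be non-negative")
        if self.min_separation_nm <= 0:
            raise ValueError("min_separation_nm must be positive")
        if len(self.bounds_nm) != 3 or any(b[1] <= b[0] for b in self.bounds_nm):
            raise ValueError("bounds_nm must be 3 non-empty (lo, hi) intervals")
        if any(s < 0 for s in self.noise_sigma_nm):
            raise ValueError("noise sigmas must be non-negative")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_spots": self.n_spots,
            "bounds_nm": [list(b) for b in self.bounds_nm],
            "true_separation_nm": self.true_separation_nm,
            "min_separation_nm": self.min_separation_nm,
            "aberration_matrix": [[float(v) for v in row] for row in self.aberration.matrix],
            "noise_sigma_nm": list(self.noise_sigma_nm),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SceneSpec":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.is_file() else str(text_or_path)
        d = json.loads(text)
        return cls(
            n_spots=d["n_spots"],
            bounds_nm=tuple(tuple(b) for b in d["bounds_nm"]),
            true_separation_nm=d["true_separation_nm"],
            min_separation_nm=d["min_separation_nm"],
            aberration=AffineTransform3D(matrix=np.asarray(d["aberration_matrix"])),
            noise_sigma_nm=tuple(d["noise_sigma_nm"]),
            seed=d["seed"],
        )


@dataclass
class GroundTruthScene:
    """A generated scene; pair identity is by index.

    ``true_a`` and ``true_b_pre`` are the noiseless pre-aberration positions
    (exactly ``true_separation_nm`` apart per pair); ``a`` and ``b`` are the
    observed positions after aberration (B only) and point-space noise.
    All arrays are (n, 3) physical nm in (x, y, z) order.
    """

    spec: SceneSpec
    true_a: np.ndarray
    true_b_pre: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def to_pairs(self, image_id: str = "synthetic") -> pd.DataFrame:
        """Observed positions as a pair table (ground-truth pairing by index)."""
        df = pd.DataFrame(
            {
                "image_id": image_id,
                "ax_nm": self.a[:, 0],
                "ay_nm": self.a[:, 1],
                "az_nm": self.a[:, 2],
                "bx_nm": self.b[:, 0],
                "by_nm": self.b[:, 1],
                "bz_nm": self.b[:, 2],
                "nucleus_label": 0,
            }
        )
        df["raw_distance_nm"] = np.linalg.norm(self.b - self.a, axis=1)
        return df[PAIR_COLUMNS]

    def to_truth_table(self, image_id: str = "synthetic") -> pd.DataFrame:
        """Pre-noise ground-truth positions, one row per pair."""
        return pd.DataFrame(
            {
                "image_id": image_id,
                "pair_index": np.arange(len(self.true_a)),
                "true_ax_nm": self.true_a[:, 0],
                "true_ay_nm": self.true_a[:, 1],
                "true_az_nm": self.true_a[:, 2],
                "true_bx_nm": self.true_b_pre[:, 0],
                "true_by_nm": self.true_b_pre[:, 1],
                "true_bz_nm": self.true_b_pre[:, 2],
                "true_separation_nm": self.spec.true_separation_nm,
            }
        )


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly isotropic random 3D unit vectors (normalized Gaussian draws)."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero draw has probability 0; guard anyway
    bad = norms[:, 0] == 0
    while np.any(bad):
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        bad = norms[:, 0] == 0
    return v / norms


def _sample_positions(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions in bounds with pairwise rejection at min_separation."""
    lo = np.array([b[0] for b in spec.bounds_nm])
    hi = np.array([b[1] for b in spec.bounds_nm])
    placed: list[np.ndarray] = []
    attempts = 0
    cap = REJECTION_CAP_PER_SPOT * spec.n_spots
    min_sq = spec.min_separation_nm**2
    while len(placed) < spec.n_spots:
        if attempts >= cap:
            raise RuntimeError(
                f"could not place {spec.n_spots} spots at min separation "
                f"{spec.min_separation_nm} nm within {cap} attempts; bounds too tight"
            )
        candidate = lo + (hi - lo) * rng.random(3)
        attempts += 1
        if placed:
            d2 = np.sum((np.asarray(placed) - candidate) ** 2, axis=1)
            if np.min(d2) < min_sq:
                continue
        placed.append(candidate)
    return np.asarray(placed)


def generate_scene(spec: SceneSpec) -> GroundTruthScene:
    """Generate a scene per its spec: positions, orientations, aberration, noise.

    Channel-A positions are uniform in the bounds with rejection sampling at
    ``min_separation_nm``.  Each pre-noise B position is ``A + L*u`` with
    ``u`` an independent isotropic unit vector; B then passes through the
    aberration, and per-axis Gaussian noise is added independently to both
    channels.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    true_a = _sample_positions(spec, rng)
    u = random_unit_vectors(spec.n_spots, rng)
    true_b_pre = true_a + spec.true_separation_nm * u
    b_aberrated = spec.aberration.apply(true_b_pre)
    sigma = np.asarray(spec.noise_sigma_nm, dtype=float)
    a_obs = true_a + rng.standard_normal(true_a.shape) * sigma
    b_obs = b_aberrated + rng.standard_normal(true_a.shape) * sigma
    return GroundTruthScene(spec=spec, true_a=true_a, true_b_pre=true_b_pre, a=a_obs, b=b_obs)


# ---------------------------------------------------------------------------
# Image-space rendering
# ---------------------------------------------------------------------------


def render_spots(
    positions_nm: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size_nm: Sequence[float] = DEFAULT_VOXEL_SIZE_NM,
    sigma_xy_nm: float = 130.0,
    sigma_z_nm: float = 300.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_model: str = "none",
    seed: int = 0,
    channel_label: str = "",
) -> VoxelGrid3D:
    """Render point emitters as 3D Gaussian spots into a voxel grid.

    Each spot contributes ``A * exp(-(dx^2+dy^2)/(2 sx^2) - dz^2/(2 sz^2))``
    evaluated at voxel centers, on a constant background.  With
    ``noise_model='poisson'`` the total expected counts are Poisson-sampled
    (deterministic given ``seed``).

    All positions must sit >= 3 sigma from every volume face.
    """
    if noise_model not in ("none", "poisson"):
        raise ValueError(f"noise_model must be 'none' or 'poisson', got {noise_model!r}")
    positions = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    nz, ny, nx = shape
    vx, vy, vz = voxel_size_nm
    extent = np.array([(nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz])
    margin = np.array([3 * sigma_xy_nm, 3 * sigma_xy_nm, 3 * sigma_z_nm])
    if len(positions) and (
        np.any(positions < margin) or np.any(positions > extent - margin)
    ):
        raise ValueError("spot positions must be >= 3 sigma inside the rendered volume")

    img = np.full(shape, float(background))
    # window half-sizes in voxels covering +-4.5 sigma
    hx = int(np.ceil(4.5 * sigma_xy_nm / vx))
    hy = int(np.ceil(4.5 * sigma_xy_nm / vy))
    hz = int(np.ceil(4.5 * sigma_z_nm / vz))
    for x0, y0, z0 in positions:
        cz, cy, cx = int(round(z0 / vz)), int(round(y0 / vy)), int(round(x0 / vx))
        zs = slice(max(cz - hz, 0), min(cz + hz + 1, nz))
        ys = slice(max(cy - hy, 0), min(cy + hy + 1, ny))
        xs = slice(max(cx - hx, 0), min(cx + hx + 1, nx))
        z = np.arange(zs.start, zs.stop) * vz - z0
        y = np.arange(ys.start, ys.stop) * vy - y0
        x = np.arange(xs.start, xs.stop) * vx - x0
        gz = np.exp(-(z**2) / (2 * sigma_z_nm**2))
        gy = np.exp(-(y**2) / (2 * sigma_xy_nm**2))
        gx = np.exp(-(x**2) / (2 * sigma_xy_nm**2))
        img[zs, ys, xs] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    if noise_model == "poisson":
        img = np.random.default_rng(seed).poisson(img).astype(float)
    return VoxelGrid3D(intensities=img, voxel_size_nm=tuple(voxel_size_nm), channel_label=channel_label)


def render_stack(
    scene: GroundTruthScene,
    channel: str,
    shape: tuple[int, int, int],
    voxel_size_nm: Sequence[float] = DEFAULT_VOXEL_SIZE_NM,
    sigma_xy_nm: float = 130.0,
    sigma_z_nm: float = 300.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_model: str = "none",
    seed: int = 0,
) -> VoxelGrid3D:
    """Render one channel of a scene (``channel`` is ``'A'`` or ``'B'``).

    Channel B is rendered at the aberrated positions; spot sigma must be
    small enough that ``scene.spec.min_separation_nm > 4 * max(sigma)``
    (spots never merge).
    """
    if channel not in ("A", "B"):
        raise ValueError("channel must be 'A' or 'B'")
    if scene.spec.min_separation_nm <= 4 * max(sigma_xy_nm, sigma_z_nm):
        raise ValueError(
            "min_separation_nm must exceed 4x the largest rendered sigma "
            "to keep spots separable"
        )
    positions = scene.a if channel == "A" else scene.b
    # decorrelate the two channels' shot noise
    ch_seed = seed if channel == "A" else seed + 1_000_003
    return render_spots(
        positions,
        shape=shape,
        voxel_size_nm=voxel_size_nm,
        sigma_xy_nm=sigma_xy_nm,
        sigma_z_nm=sigma_z_nm,
        amplitude=amplitude,
        background=background,
        noise_model=noise_model,
        seed=ch_seed,
        channel_label=channel,
    )


def render_nuclei(
    centers_nm: np.ndarray,
    radii_nm: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size_nm: Sequence[float] = DEFAULT_VOXEL_SIZE_NM,
    foreground: float = 1000.0,
    background: float = 50.0,
) -> tuple[VoxelGrid3D, np.ndarray]:
    """Render bright filled ellipsoids plus their exact label volume.

    ``centers_nm`` is (n, 3) in (x, y, z); ``radii_nm`` is (n, 3) per-axis
    semi-axes.  Returns the intensity grid and an int label volume
    (0 = background, ellipsoid i gets label i+1; overlaps take the later
    label).
    """
    centers = np.atleast_2d(np.asarray(centers_nm, dtype=float))
    radii = np.atleast_2d(np.asarray(radii_nm, dtype=float))
    nz, ny, nx = shape
    vx, vy, vz = voxel_size_nm
    z = np.arange(nz) * vz
    y = np.arange(ny) * vy
    x = np.arange(nx) * vx
    labels = np.zeros(shape, dtype=np.int32)
    for i, (c, r) in enumerate(zip(centers, radii)):
        dz = ((z - c[2]) / r[2]) ** 2
        dy = ((y - c[1]) / r[1]) ** 2
        dx = ((x - c[0]) / r[0]) ** 2
        inside = dz[:, None, None] + dy[None, :, None] + dx[None, None, :] <= 1.0
        labels[inside] = i + 1
    img = np.where(labels > 0, float(foreground), float(background))
    grid = VoxelGrid3D(intensities=img, voxel_size_nm=tuple(voxel_size_nm), channel_label="nuclei")
    return grid, labels


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def nanoruler_spec(
    separation_nm: float,
    n_spots: int,
    aberration: AffineTransform3D | None = None,
    noise_sigma_nm: tuple[float, float, float] = (20.0, 20.0, 20.0),
    seed: int = 0,
    bounds_nm: tuple[tuple[float, float], ...] | None = None,
) -> SceneSpec:
    """Preset for nanoruler-style scenes (separation 0 = colocalization control)."""
    kwargs = {}
    if bounds_nm is not None:
        kwargs["bounds_nm"] = bounds_nm
    return SceneSpec(
        n_spots=n_spots,
        true_separation_nm=separation_nm,
        aberration=aberration if aberration is not None else AffineTransform3D.identity(),
        noise_sigma_nm=noise_sigma_nm,
        seed=seed,
        **kwargs,
    )
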