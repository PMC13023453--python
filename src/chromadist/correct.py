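"""Chromatic aberration correction.

Two complementary, independently fitted corrections of the systematic
inter-channel offset that chromatic aberration introduces between the two
FISH channels:

* **LCC** (linear chromatic correction), :class:`LinearChromaticCorrection` —
  self-calibrating.  For isotropically oriented spot pairs the mean
  inter-channel difference should be zero, whether the pairs are colocalized
  or genuinely separated; LCC centers the paired differences, removes a
  per-axis linear (scaling) bias by ordinary least squares against the
  reference coordinate, and re-centers.

* **ACC** (affine chromatic correction), :class:`AffineChromaticCorrection` —
  a global 12-parameter affine map (translation, rotation, anisotropic
  scaling, shear) fitted by linear least squares (SVD) on *colocalized*
  calibration pairs, persisted as JSON and reapplied to measurement datasets
  acquired under the same optical conditions.

Both estimators correct the *moving* channel (``b``) into the *reference*
frame (``a``); reference coordinates are never touched.  Agreement between
the two methods is itself a diagnostic: they model the same optics with
different parameterizations, so divergence beyond a few nanometers signals
optical instability or an aberration field a global model cannot express.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, TransformerMixin

TRANSFORM_SCHEMA = "chromadist-transform/1"


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform3D:
    """4x4 homogeneous affine map between channel coordinate frames (nm).

    ``matrix`` is row-major with last row exactly ``(0, 0, 0, 1)``; the
    linear 3x3 block must be invertible.  Applied to row vectors of physical
    ``(x, y, z)`` coordinates as ``p' = M[:3,:3] @ p + M[:3,3]``.
    """

    matrix: np.ndarray
    reference_channel: str = ""
    moving_channel: str = ""
    n_pairs: int = 0
    created: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"affine matrix must be 4x4, got {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError(f"last row must be (0,0,0,1), got {m[3]}")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("linear 3x3 block is singular")
        self.matrix = m
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    @classmethod
    def identity(cls, **meta) -> "AffineTransform3D":
        return cls(matrix=np.eye(4), **meta)

    def apply(self, points_nm: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` or ``(3,)`` physical points through the transform."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points_nm).ndim == 1 else out

    def inverse(self) -> "AffineTransform3D":
        return AffineTransform3D(
            matrix=np.linalg.inv(self.matrix),
            reference_channel=self.moving_channel,
            moving_channel=self.reference_channel,
            n_pairs=self.n_pairs,
        )

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return the transform applying ``other`` first, then ``self``."""
        return AffineTransform3D(matrix=self.matrix @ other.matrix)


def compose_affine(
    translation_nm: Sequence[float] = (0.0, 0.0, 0.0),
    scales: Sequence[float] = (1.0, 1.0, 1.0),
    rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
    shear: Sequence[float] = (0.0, 0.0, 0.0),
) -> AffineTransform3D:
    """Build an affine from physical components (applied scale->shear->rotation->translation).

    Parameters
    ----------
    translation_nm : (tx, ty, tz)
    scales : per-axis (sx, sy, sz)
    rotation_deg : extrinsic Euler angles (rx, ry, rz), degrees
    shear : (sxy, sxz, syz) upper-triangular shear coefficients
    """
    s = np.diag(np.asarray(scales, dtype=float))
    sh = np.eye(3)
    sh[0, 1], sh[0, 2], sh[1, 2] = shear
    r = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()
    m = np.eye(4)
    m[:3, :3] = r @ sh @ s
    m[:3, 3] = np.asarray(translation_nm, dtype=float)
    return AffineTransform3D(matrix=m)


def apply_affine(t: AffineTransform3D, points_nm: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`AffineTransform3D.apply`."""
    return t.apply(points_nm)


def save_transform(t: AffineTransform3D, path: str | Path) -> None:
    """Persist a transform as versioned JSON (matrix bit-exact via repr floats)."""
    payload = {
        "schema": TRANSFORM_SCHEMA,
        "matrix": [[float(v) for v in row] for row in t.matrix],
        "reference_channel": t.reference_channel,
        "moving_channel": t.moving_channel,
        "n_pairs": int(t.n_pairs),
        "created": t.created,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_transform(path: str | Path) -> AffineTransform3D:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema") != TRANSFORM_SCHEMA:
        raise ValueError(
            f"unsupported transform schema {payload.get('schema')!r}; "
            f"expected {TRANSFORM_SCHEMA!r}"
        )
    return AffineTransform3D(
        matrix=np.asarray(payload["matrix"], dtype=float),
        reference_channel=payload.get("reference_channel", ""),
        moving_channel=payload.get("moving_channel", ""),
        n_pairs=int(payload.get("n_pairs", 0)),
        created=payload.get("created", ""),
    )


# ---------------------------------------------------------------------------
# Pair-table helpers
# ---------------------------------------------------------------------------


def _pair_coords(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Extract reference (a) and moving (b) coordinates as (n, 3) arrays.

    Accepts a pairs DataFrame (columns ax_nm..bz_nm) or an (n, 6) array
    ``[ax, ay, az, bx, by, bz]``.
    """
    if isinstance(pairs, pd.DataFrame):
        a = pairs[["ax_nm", "ay_nm", "az_nm"]].to_numpy(dtype=float)
        b = pairs[["bx_nm", "by_nm", "bz_nm"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("expected a pairs DataFrame or an (n, 6) array")
        a, b = arr[:, :3], arr[:, 3:]
    return a, b


def _rebuild_pairs(pairs, b_new: np.ndarray):
    """Return a copy of ``pairs`` with moving coordinates replaced and distances recomputed."""
    if isinstance(pairs, pd.DataFrame):
        out = pairs.copy()
        out[["bx_nm", "by_nm", "bz_nm"]] = b_new
        a = out[["ax_nm", "ay_nm", "az_nm"]].to_numpy(dtype=float)
        out["raw_distance_nm"] = np.linalg.norm(b_new - a, axis=1)
        return out
    arr = np.asarray(pairs, dtype=float).copy()
    arr[:, 3:] = b_new
    return arr


# ---------------------------------------------------------------------------
# LCC
# ---------------------------------------------------------------------------


class LinearChromaticCorrection(TransformerMixin, BaseEstimator):
    """Self-calibrating per-axis linear correction of paired differences.

    For each axis ``k``, with paired differences ``d_k = b_k - a_k``:

    1. subtract the mean difference ``mean_k`` (global translation),
    2. regress the centered difference on the reference coordinate ``a_k``
       by ordinary least squares, giving intercept ``alpha_k`` and scaling
       bias ``beta_k``,
    3. the total correction is ``b_k <- b_k - (mean_k + alpha_k + beta_k a_k)``,
       which leaves the corrected differences with exactly zero mean (OLS
       residuals are mean-free) — any residual translation is absorbed.

    Valid for colocalized *and* separated pairs, because isotropically
    oriented pairs contribute zero expected difference.

    Parameters
    ----------
    min_pairs : int
        Minimum number of training pairs (default 10).

    Attributes
    ----------
    mean_diff_ : (3,) ndarray — per-axis mean of b - a on the training pairs.
    intercept_ : (3,) ndarray — per-axis OLS intercept alpha_k.
    slope_ : (3,) ndarray — per-axis OLS slope beta_k (scaling bias).
    n_pairs_ : int
    residual_mean_ : (3,) ndarray — mean corrected difference (~0 by construction).
    """

    def __init__(self, min_pairs: int = 10):
        self.min_pairs = min_pairs

    def fit(self, X, y=None) -> "LinearChromaticCorrection":
        a, b = _pair_coords(X)
        n = len(a)
        if n < self.min_pairs:
            raise ValueError(f"LCC needs >= {self.min_pairs} pairs, got {n}")
        var = a.var(axis=0)
        if np.any(var <= 0):
            bad = "xyz"[int(np.argmin(var))]
            raise ValueError(f"reference coordinates degenerate along {bad} (zero variance)")

        d = b - a
        self.mean_diff_ = d.mean(axis=0)
        dc = d - self.mean_diff_
        self.intercept_ = np.empty(3)
        self.slope_ = np.empty(3)
        for k in range(3):
            design = np.column_stack([np.ones(n), a[:, k]])
            coef, *_ = np.linalg.lstsq(design, dc[:, k], rcond=None)
            self.intercept_[k], self.slope_[k] = coef
        self.n_pairs_ = n
        b_corr = self._correct(a, b)
        self.residual_mean_ = (b_corr - a).mean(axis=0)
        return self

    def _correct(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return b - (self.mean_diff_ + self.intercept_ + self.slope_ * a)

    def transform(self, X):
        """Correct the moving channel of a pair set; reference is untouched."""
        self._check_fitted()
        a, b = _pair_coords(X)
        return _rebuild_pairs(X, self._correct(a, b))

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise ValueError("LinearChromaticCorrection is not fitted")


def fit_lcc(pairs, min_pairs: int = 10) -> LinearChromaticCorrection:
    """Fit a :class:`LinearChromaticCorrection` on a pair table."""
    return LinearChromaticCorrection(min_pairs=min_pairs).fit(pairs)


def apply_lcc(model: LinearChromaticCorrection, pairs):
    """Apply a fitted LCC model; returns pairs with corrected moving coordinates."""
    return model.transform(pairs)


# ---------------------------------------------------------------------------
# ACC
# ---------------------------------------------------------------------------


class AffineChromaticCorrection(TransformerMixin, BaseEstimator):
    """Global 12-parameter affine correction fitted on colocalized pairs.

    Finds the affine map ``T`` minimizing ``sum_i ||T(b_i) - a_i||^2`` over
    translation, rotation, anisotropic scaling and shear, as a single linear
    least-squares problem solved through the SVD-based pseudo-inverse.  The
    fitted transform maps moving-channel coordinates into the reference
    frame and can be persisted (:func:`save_transform`) and reapplied to
    datasets that were acquired under the same optical conditions.

    Parameters
    ----------
    min_pairs : int
        Minimum pairs after filtering (default 20).
    coplanarity_rtol : float
        The smallest singular value of the centered moving-coordinate matrix
        must exceed ``coplanarity_rtol`` times the largest; otherwise the
        geometry is (nearly) coplanar and the 12-dof fit is rank-deficient.

    Attributes
    ----------
    transform_ : AffineTransform3D — the fitted b -> a map.
    rms_residual_nm_ : float — RMS of ``||T(b_i) - a_i||`` on the training pairs.
    n_pairs_ : int
    """

    def __init__(self, min_pairs: int = 20, coplanarity_rtol: float = 1e-6):
        self.min_pairs = min_pairs
        self.coplanarity_rtol = coplanarity_rtol

    def fit(self, X, y=None, *, reference_channel: str = "", moving_channel: str = ""):
        a, b = _pair_coords(X)
        n = len(a)
        if n < self.min_pairs:
            raise ValueError(f"ACC needs >= {self.min_pairs} pairs, got {n}")
        sv = np.linalg.svd(b - b.mean(axis=0), compute_uv=False)
        if sv[-1] <= self.coplanarity_rtol * sv[0]:
            raise ValueError(
                "moving-channel points are (nearly) coplanar; affine fit is degenerate "
                f"(singular values {sv})"
            )
        # center both point sets before the SVD solve: the raw design matrix
        # (coordinates ~1e4 nm against a unit intercept column) is badly
        # conditioned, centering removes that without changing the model
        mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
        coef, *_ = np.linalg.lstsq(b - mu_b, a - mu_a, rcond=None)  # (3, 3), SVD-based
        linear = coef.T
        m = np.eye(4)
        m[:3, :3] = linear
        m[:3, 3] = mu_a - linear @ mu_b
        self.transform_ = AffineTransform3D(
            matrix=m,
            reference_channel=reference_channel,
            moving_channel=moving_channel,
            n_pairs=n,
        )
        self.n_pairs_ = n
        self.rms_residual_nm_ = float(
            np.sqrt(np.mean(np.sum((self.transform_.apply(b) - a) ** 2, axis=1)))
        )
        return self

    def transform(self, X):
        """Correct a pair set's moving channel, or map an (n, 3) point array."""
        if not hasattr(self, "transform_"):
            raise ValueError("AffineChromaticCorrection is not fitted")
        arr = np.asarray(X) if not isinstance(X, pd.DataFrame) else None
        if arr is not None and arr.ndim == 2 and arr.shape[1] == 3:
            return self.transform_.apply(arr)
        a, b = _pair_coords(X)
        return _rebuild_pairs(X, self.transform_.apply(b))


def fit_acc(
    pairs,
    min_pairs: int = 20,
    reference_channel: str = "",
    moving_channel: str = "",
) -> AffineTransform3D:
    """Fit the ACC affine on aggregated, IQR-filtered pairs; returns the transform."""
    est = AffineChromaticCorrection(min_pairs=min_pairs)
    est.fit(pairs, reference_channel=reference_channel, moving_channel=moving_channel)
    return est.transform_


def apply_transform_to_pairs(t: AffineTransform3D, pairs):
    """Apply a stored/fitted affine to a pair table's moving channel."""
    a, b = _pair_coords(pairs)
    return _rebuild_pairs(pairs, t.apply(b))


# ---------------------------------------------------------------------------
# Agreement diagnostic
# ---------------------------------------------------------------------------


def correction_agreement(
    pairs,
    lcc: LinearChromaticCorrection,
    acc: AffineTransform3D,
    median_flag_threshold_nm: float = 10.0,
) -> dict:
    """Compare per-pair distances under the two corrections.

    Close agreement (a few nm on the median) indicates both models capture
    the aberration; divergence flags optical instability or a non-global
    aberration field.

    Returns a dict with the two corrected medians, their absolute
    difference, summary stats of per-pair distance deltas, and a
    ``diverged`` flag when the median difference exceeds the threshold.
    """
    d_lcc = _distances(apply_lcc(lcc, pairs))
    d_acc = _distances(apply_transform_to_pairs(acc, pairs))
    delta = d_acc - d_lcc
    median_lcc = float(np.median(d_lcc))
    median_acc = float(np.median(d_acc))
    median_diff = abs(median_acc - median_lcc)
    return {
        "n_pairs": int(len(d_lcc)),
        "median_lcc_nm": median_lcc,
        "median_acc_nm": median_acc,
        "median_abs_difference_nm": median_diff,
        "per_pair_delta_median_nm": float(np.median(delta)),
        "per_pair_delta_mad_nm": float(np.median(np.abs(delta - np.median(delta)))),
        "threshold_nm": float(median_flag_threshold_nm),
        "diverged": bool(median_diff > median_flag_threshold_nm),
    }


def _distances(pairs) -> np.ndarray:
    a, b = _pair_coords(pairs)
    return np.linalg.norm(b - a, axis=1)
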