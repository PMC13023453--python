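"""Nuclei segmentation and integer-voxel spot candidate detection.

The detector contract is deliberately narrow — a stack goes in, voxel-level
candidates come out — so that detection backends are interchangeable.  The
default backend is a scale-matched Laplacian-of-Gaussian blob detector
(anisotropy handled by per-axis sigmas in voxel units); an adapter accepts
externally produced coordinates or label masks, e.g. from a trained
segmentation model, through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import VoxelGrid3D, voxel_to_physical


@dataclass
class SpotCandidate:
    """A detected spot at integer-voxel resolution."""

    index: tuple[int, int, int]  # (z, y, x)
    response: float
    raw_intensity: float
    nucleus_label: int = 0


class SpotDetector(Protocol):
    """Anything that turns a stack into spot candidates."""

    def detect(self, stack: VoxelGrid3D) -> list[SpotCandidate]: ...


# ---------------------------------------------------------------------------
# Nuclei
# ---------------------------------------------------------------------------

#: 26-connectivity in 3D.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_nuclei(
    stack: VoxelGrid3D,
    smoothing_sigma_nm: float = 1000.0,
    min_volume_nm3: float = 1e9,
) -> np.ndarray:
    """Segment nuclei: smooth, Otsu threshold, fill holes per plane, size-filter.

    Returns an int label volume aligned to the stack (0 = background),
    labels consecutive, components 26-connected.  A constant stack yields
    zero labels.  ``min_volume_nm3`` default (1 µm^3) removes debris well
    below the size of any nucleus.
    """
    img = stack.intensities.astype(float)
    if np.ptp(img) == 0:
        return np.zeros(stack.shape, dtype=np.int32)
    vx, vy, vz = stack.voxel_size_nm
    sigma_vox = (smoothing_sigma_nm / vz, smoothing_sigma_nm / vy, smoothing_sigma_nm / vx)
    smoothed = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if np.ptp(smoothed) == 0:
        return np.zeros(stack.shape, dtype=np.int32)
    mask = smoothed > threshold_otsu(smoothed)
    for iz in range(mask.shape[0]):
        mask[iz] = ndimage.binary_fill_holes(mask[iz])
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return labels.astype(np.int32)
    min_voxels = min_volume_nm3 / (vx * vy * vz)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep > 0]
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    return relabel[labels]


# ---------------------------------------------------------------------------
# LoG spot detection
# ---------------------------------------------------------------------------


def detect_spots(
    stack: VoxelGrid3D,
    expected_sigma_nm: tuple[float, float] = (130.0, 300.0),
    threshold_policy: str | float = "auto",
    min_separation_nm: float = 500.0,
    k_mad: float = 8.0,
) -> list[SpotCandidate]:
    """Detect spots with a scale-matched 3D Laplacian-of-Gaussian filter.

    Parameters
    ----------
    expected_sigma_nm
        (lateral, axial) Gaussian spot sigma in nm; converted to per-axis
        voxel sigmas so the filter is matched despite voxel anisotropy.
    threshold_policy
        ``"auto"`` (response median + ``k_mad`` * MAD — conservative
        false-positive control) or an absolute response threshold.
    min_separation_nm
        Local maxima closer than this (physical distance) keep only the
        strongest; equal responses keep the lexicographically smallest
        voxel index.

    Returns candidates sorted by decreasing response.
    """
    sxy, sz = expected_sigma_nm
    if sxy <= 0 or sz <= 0:
        raise ValueError("expected sigmas must be positive")
    img = stack.intensities.astype(float)
    vx, vy, vz = stack.voxel_size_nm
    sigma_vox = np.array([sz / vz, sxy / vy, sxy / vx])
    # scale-normalized negative LoG: bright blobs give positive peaks
    response = -ndimage.gaussian_laplace(img, sigma=sigma_vox) * float(
        np.prod(sigma_vox) ** (2.0 / 3.0)
    )

    if threshold_policy == "auto":
        med = np.median(response)
        mad = np.median(np.abs(response - med))
        threshold = med + k_mad * mad
    else:
        threshold = float(threshold_policy)

    is_max = response == ndimage.maximum_filter(response, size=3, mode="reflect")
    zz, yy, xx = np.nonzero(is_max & (response > threshold))
    if len(zz) == 0:
        return []

    resp = response[zz, yy, xx]
    # strongest first; deterministic tie-break on voxel index
    order = np.lexsort((xx, yy, zz, -resp))
    idx = np.column_stack([zz, yy, xx])[order]
    resp = resp[order]
    phys = voxel_to_physical(idx, stack.voxel_size_nm)

    kept: list[int] = []
    min_sq = min_separation_nm**2
    for i in range(len(idx)):
        if kept:
            d2 = np.sum((phys[kept] - phys[i]) ** 2, axis=1)
            if np.min(d2) < min_sq:
                continue
        kept.append(i)

    return [
        SpotCandidate(
            index=tuple(int(v) for v in idx[i]),
            response=float(resp[i]),
            raw_intensity=float(img[tuple(idx[i])]),
        )
        for i in kept
    ]


class LoGDetector:
    """Default detector backend wrapping :func:`detect_spots`."""

    def __init__(
        self,
        expected_sigma_nm: tuple[float, float] = (130.0, 300.0),
        threshold_policy: str | float = "auto",
        min_separation_nm: float = 500.0,
        k_mad: float = 8.0,
    ):
        self.expected_sigma_nm = expected_sigma_nm
        self.threshold_policy = threshold_policy
        self.min_separation_nm = min_separation_nm
        self.k_mad = k_mad

    def detect(self, stack: VoxelGrid3D) -> list[SpotCandidate]:
        return detect_spots(
            stack,
            expected_sigma_nm=self.expected_sigma_nm,
            threshold_policy=self.threshold_policy,
            min_separation_nm=self.min_separation_nm,
            k_mad=self.k_mad,
        )


class ExternalCandidateAdapter:
    """Detector backend serving externally produced voxel coordinates.

    Reads a candidate CSV (columns ``iz, iy, ix`` and optionally
    ``response, raw_intensity``), e.g. exported from a learned detection
    model, and serves them through the detector interface.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def detect(self, stack: VoxelGrid3D) -> list[SpotCandidate]:
        df = pd.read_csv(self.path)
        missing = {"iz", "iy", "ix"} - set(df.columns)
        if missing:
            raise ValueError(f"candidate CSV missing columns: {sorted(missing)}")
        out = []
        for row in df.itertuples(index=False):
            index = (int(row.iz), int(row.iy), int(row.ix))
            if not all(0 <= i < s for i, s in zip(index, stack.shape)):
                raise ValueError(f"candidate index {index} outside stack {stack.shape}")
            out.append(
                SpotCandidate(
                    index=index,
                    response=float(getattr(row, "response", np.nan)),
                    raw_intensity=float(stack.intensities[index]),
                )
            )
        return out


def load_labels_tiff(path: str | Path) -> np.ndarray:
    """Load an externally produced nuclei label volume (int TIFF)."""
    labels = tifffile.imread(Path(path))
    if labels.ndim != 3:
        raise ValueError("label volume must be 3D (z, y, x)")
    return labels.astype(np.int32)


def filter_candidates_by_nuclei(
    candidates: Sequence[SpotCandidate],
    labels: np.ndarray,
) -> list[SpotCandidate]:
    """Keep only candidates inside segmented nuclei, annotating the label."""
    labels = np.asarray(labels)
    out = []
    for c in candidates:
        if not all(0 <= i < s for i, s in zip(c.index, labels.shape)):
            raise ValueError(
                f"candidate index {c.index} outside label volume {labels.shape}; "
                "labels must be aligned to the candidates' stack"
            )
        lab = int(labels[c.index])
        if lab > 0:
            out.append(
                SpotCandidate(
                    index=c.index,
                    response=c.response,
                    raw_intensity=c.raw_intensity,
                    nucleus_label=lab,
                )
            )
    return out


def candidates_to_table(candidates: Sequence[SpotCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iz": [c.index[0] for c in candidates],
            "iy": [c.index[1] for c in candidates],
            "ix": [c.index[2] for c in candidates],
            "response": [c.response for c in candidates],
            "raw_intensity": [c.raw_intensity for c in candidates],
            "nucleus_label": [c.nucleus_label for c in candidates],
        }
    )
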