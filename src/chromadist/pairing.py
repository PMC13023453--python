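"""Cross-channel spot pairing and pair filtering.

Centroids from the two channels are matched by *mutual* nearest neighbor:
a pair is kept only when each centroid is the other's closest cross-channel
partner.  Mutuality makes the match one-to-one — at the spot densities of
real FISH images a one-sided rule would let one bright spot absorb several
partners.  Before affine fitting, pair distances pass a median + k*IQR
fence that removes extreme outliers (mispairs) without ever discarding more
than a quarter of the data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import PAIR_COLUMNS, empty_pair_table

#: Above this many distance evaluations, mutual-NN switches from the exact
#: all-pairs matrix to KD-trees.
_BRUTE_FORCE_LIMIT = 10_000_000


def _mutual_nn(pa: np.ndarray, pb: np.ndarray) -> list[tuple[int, int, float]]:
    """Indices (ia, ib, distance) of mutual nearest neighbors.

    Distance ties are broken toward the smallest centroid index (argmin
    order), so the result is deterministic.
    """
    if len(pa) * len(pb) <= _BRUTE_FORCE_LIMIT:
        d = cdist(pa, pb)
        nn_a = d.argmin(axis=1)  # ties -> smallest index
        nn_b = d.argmin(axis=0)
        return [
            (ia, int(nn_a[ia]), float(d[ia, nn_a[ia]]))
            for ia in range(len(pa))
            if nn_b[nn_a[ia]] == ia
        ]
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    d_ab, nn_a = tree_b.query(pa, k=1)
    _, nn_b = tree_a.query(pb, k=1)
    return [
        (ia, int(nn_a[ia]), float(d_ab[ia]))
        for ia in range(len(pa))
        if nn_b[nn_a[ia]] == ia
    ]


def pair_spots(
    centroids_a: pd.DataFrame,
    centroids_b: pd.DataFrame,
    max_distance_nm: float = 1000.0,
    require_same_nucleus: bool = False,
) -> pd.DataFrame:
    """Pair reference (a) and moving (b) centroids of one image by mutual NN.

    Pairs farther apart than ``max_distance_nm`` are discarded (the default
    1 µm caps mispairing across neighboring loci while comfortably exceeding
    any plausible uncorrected chromatic offset).  With
    ``require_same_nucleus``, both centroids must carry the same positive
    nucleus label.  Each centroid appears in at most one pair.
    """
    if len(centroids_a) == 0 or len(centroids_b) == 0:
        return empty_pair_table()
    ids = set(centroids_a["image_id"]) | set(centroids_b["image_id"])
    if len(ids) > 1:
        raise ValueError(f"pair_spots expects centroids from one image, got ids {sorted(map(str, ids))}")
    image_id = next(iter(ids))

    pa = centroids_a[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    pb = centroids_b[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    rows = []
    for ia, ib, dist in _mutual_nn(pa, pb):
        if dist > max_distance_nm:
            continue
        lab_a = int(centroids_a["nucleus_label"].iloc[ia])
        lab_b = int(centroids_b["nucleus_label"].iloc[ib])
        if require_same_nucleus and (lab_a <= 0 or lab_a != lab_b):
            continue
        rows.append(
            {
                "image_id": image_id,
                "ax_nm": pa[ia, 0],
                "ay_nm": pa[ia, 1],
                "az_nm": pa[ia, 2],
                "bx_nm": pb[ib, 0],
                "by_nm": pb[ib, 1],
                "bz_nm": pb[ib, 2],
                "raw_distance_nm": dist,
                "nucleus_label": lab_a if lab_a == lab_b else 0,
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS) if rows else empty_pair_table()


def filter_pairs_iqr(pairs: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Outlier fence before affine fitting: keep distance <= median + k*IQR.

    The fence is inclusive (a degenerate IQR of 0 keeps everything at the
    common value).  As a guard against over-aggressive trimming when the
    IQR collapses, never remove more than 25% of the pairs: if the fence
    would, keep the smallest-distance 75% instead.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    n = len(pairs)
    if n < 4:
        raise ValueError(f"IQR filtering needs >= 4 pairs, got {n}")
    d = pairs["raw_distance_nm"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    cutoff = med + k * (q3 - q1)
    keep = d <= cutoff
    floor = int(np.ceil(0.75 * n))
    if keep.sum() < floor:
        order = np.argsort(d, kind="stable")
        keep = np.zeros(n, dtype=bool)
        keep[order[:floor]] = True
    return pairs.loc[keep].reset_index(drop=True)


def aggregate_pairs(per_image_pairs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-image pair tables, preserving image_id provenance.

    Caller is responsible for only aggregating images that share acquisition
    conditions (same optics, same aberration profile).
    """
    frames = [p for p in per_image_pairs if len(p) > 0]
    if not frames:
        return empty_pair_table()
    return pd.concat(frames, ignore_index=True)[PAIR_COLUMNS]
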