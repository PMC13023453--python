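"""Distance computation and robust distribution summaries.

Distances between paired centroids are summarized with the median and
interquartile range rather than mean/s.d. — FISH distance distributions are
heavy-tailed (mispairs, failed fits), and robust statistics limit the
influence of those outliers.  Quartiles use linear interpolation between
order statistics (numpy's default, the common "type 7" convention), fixed
here so IQR values are reproducible bit-for-bit.

Sign convention: component displacements are moving minus reference
(b - a), z positive toward increasing plane index.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

SUMMARY_COLUMNS = [
    "label",
    "n",
    "median_nm",
    "q1_nm",
    "q3_nm",
    "med_dx_nm",
    "med_dy_nm",
    "med_dz_nm",
    "med_abs_dx_nm",
    "med_abs_dy_nm",
    "med_abs_dz_nm",
]


@dataclass
class DistanceSummary:
    """Robust summary of one condition's distance distribution (nm).

    Per-axis displacement medians are reported both signed (``med_d*``,
    convention b - a, the quantity whose mean the linear correction drives
    to zero) and absolute (``med_abs_d*``, a magnitude-style readout); the
    two answer different questions and are labeled distinctly.
    """

    label: str
    n: int
    median_nm: float
    q1_nm: float
    q3_nm: float
    med_dx_nm: float = np.nan
    med_dy_nm: float = np.nan
    med_dz_nm: float = np.nan
    med_abs_dx_nm: float = np.nan
    med_abs_dy_nm: float = np.nan
    med_abs_dz_nm: float = np.nan

    @property
    def iqr_nm(self) -> float:
        return self.q3_nm - self.q1_nm


def pair_displacements(pairs: pd.DataFrame) -> pd.DataFrame:
    """Signed component displacements and 3D distance per pair.

    Returns columns ``dx_nm, dy_nm, dz_nm`` (moving - reference) and
    ``d3_nm`` = sqrt(dx^2 + dy^2 + dz^2), with image_id carried through.
    """
    a = pairs[["ax_nm", "ay_nm", "az_nm"]].to_numpy(dtype=float)
    b = pairs[["bx_nm", "by_nm", "bz_nm"]].to_numpy(dtype=float)
    d = b - a
    return pd.DataFrame(
        {
            "image_id": pairs["image_id"].to_numpy() if len(pairs) else [],
            "dx_nm": d[:, 0],
            "dy_nm": d[:, 1],
            "dz_nm": d[:, 2],
            "d3_nm": np.linalg.norm(d, axis=1),
        }
    )


def robust_summary(values: Sequence[float] | np.ndarray, label: str = "") -> DistanceSummary:
    """Median and quartiles (linear interpolation) of a distance sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("robust_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return DistanceSummary(label=label, n=int(v.size), median_nm=float(med), q1_nm=float(q1), q3_nm=float(q3))


def summarize_pairs(pairs: pd.DataFrame, label: str = "") -> DistanceSummary:
    """Full summary of a pair table: 3D distance quartiles + per-axis medians."""
    disp = pair_displacements(pairs)
    s = robust_summary(disp["d3_nm"], label=label)
    s.med_dx_nm = float(np.median(disp["dx_nm"]))
    s.med_dy_nm = float(np.median(disp["dy_nm"]))
    s.med_dz_nm = float(np.median(disp["dz_nm"]))
    s.med_abs_dx_nm = float(np.median(np.abs(disp["dx_nm"])))
    s.med_abs_dy_nm = float(np.median(np.abs(disp["dy_nm"])))
    s.med_abs_dz_nm = float(np.median(np.abs(disp["dz_nm"])))
    return s


def summaries_to_frame(summaries: Sequence[DistanceSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])[SUMMARY_COLUMNS]


def distribution_report(
    summaries: Sequence[DistanceSummary],
    raw_values: Mapping[str, Sequence[float]],
    output_dir: str | Path,
    basename: str = "distances",
) -> dict[str, Path]:
    """Write the distribution report: summary CSV, histogram and violin figures.

    ``raw_values`` maps each summary label to its distance sample.  The CSV
    is the machine-readable product; figures are for human inspection.
    Returns the paths written.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one summary")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    csv_path = out / f"{basename}_summary.csv"
    summaries_to_frame(summaries).to_csv(csv_path, index=False, float_format="%.17g")
    paths["summary_csv"] = csv_path

    long = pd.concat(
        [
            pd.DataFrame({"condition": label, "distance_nm": np.asarray(vals, dtype=float)})
            for label, vals in raw_values.items()
        ],
        ignore_index=True,
    )

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in long.groupby("condition", sort=False):
        ax.hist(grp["distance_nm"], bins=50, alpha=0.5, label=str(label), density=True)
    ax.set_xlabel("3D distance (nm)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    hist_path = out / f"{basename}_hist.png"
    fig.savefig(hist_path, dpi=120)
    plt.close(fig)
    paths["histogram"] = hist_path

    fig, ax = plt.subplots(figsize=(6, 4))
    sns.violinplot(data=long, y="condition", x="distance_nm", orient="h", cut=0, ax=ax)
    ax.set_xlabel("3D distance (nm)")
    violin_path = out / f"{basename}_violin.png"
    fig.savefig(violin_path, dpi=120)
    plt.close(fig)
    paths["violin"] = violin_path
    return paths
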