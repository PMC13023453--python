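"""End-to-end workflows: simulate, calibrate, measure.

``run_measure`` chains detection -> sub-pixel localization -> mutual-NN
pairing -> chromatic correction -> robust summaries over a set of stacks.
``run_calibrate`` runs the same chain on colocalization stacks and persists
the fitted affine transform for reuse on measurement datasets acquired
under the same optical conditions.  ``run_simulate`` writes synthetic
scenes (ground truth + rendered stacks) to disk.

Every run writes its resolved configuration next to its outputs, so the
"same conditions" requirement for transform reuse is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .correct import (
    AffineTransform3D,
    apply_lcc,
    apply_transform_to_pairs,
    correction_agreement,
    fit_acc,
    fit_lcc,
    load_transform,
    save_transform,
)
from .detect import LoGDetector, filter_candidates_by_nuclei, segment_nuclei
from .localize import localize_all
from .pairing import aggregate_pairs, filter_pairs_iqr, pair_spots
from .simulate import GroundTruthScene, SceneSpec, generate_scene, render_stack
from .stats import DistanceSummary, distribution_report, summarize_pairs

logger = logging.getLogger("chromadist")


class EmptyResultError(RuntimeError):
    """The pipeline ran but produced no pairs (maps to CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run.

    Exactly one reference and one moving channel; the nuclei channel is
    optional.  ``channel_indices`` maps channel labels to their index in
    the TIFF files.
    """

    voxel_size_nm: tuple[float, float, float] = cio.DEFAULT_VOXEL_SIZE_NM
    reference_channel: str = "A"
    moving_channel: str = "B"
    nuclei_channel: str | None = None
    channel_indices: dict[str, int] = field(default_factory=lambda: {"A": 0, "B": 1})
    axis_order: str = "CZYX"
    # detection
    expected_sigma_nm: tuple[float, float] = (130.0, 300.0)
    threshold_policy: str | float = "auto"
    detect_min_separation_nm: float = 500.0
    k_mad: float = 8.0
    # nuclei
    nuclei_smoothing_sigma_nm: float = 1000.0
    nuclei_min_volume_nm3: float = 1e9
    # localization
    crop_radii_nm: tuple[float, float] | None = None
    fallback_policy: str = "drop"
    # pairing
    max_pair_distance_nm: float = 1000.0
    require_same_nucleus: bool = False
    # correction
    method: str = "both"  # lcc | acc | both
    transform_path: str | None = None
    iqr_k: float = 1.5
    # run
    output_dir: str = "chromadist_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("lcc", "acc", "both"):
            raise ValueError("method must be 'lcc', 'acc' or 'both'")
        if self.reference_channel == self.moving_channel:
            raise ValueError("reference and moving channels must differ")
        for label in (self.reference_channel, self.moving_channel):
            if label not in self.channel_indices:
                raise ValueError(f"channel {label!r} missing from channel_indices")
        if self.nuclei_channel is not None and self.nuclei_channel not in self.channel_indices:
            raise ValueError(f"nuclei channel {self.nuclei_channel!r} missing from channel_indices")

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2, default=list)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PipelineConfig":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.is_file() else str(text_or_path)
        d = json.loads(text)
        for key in ("voxel_size_nm", "expected_sigma_nm", "crop_radii_nm"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def detector(self) -> LoGDetector:
        return LoGDetector(
            expected_sigma_nm=self.expected_sigma_nm,
            threshold_policy=self.threshold_policy,
            min_separation_nm=self.detect_min_separation_nm,
            k_mad=self.k_mad,
        )


def extract_pairs_for_image(
    config: PipelineConfig,
    stack_path: str | Path,
    image_id: str | None = None,
) -> pd.DataFrame:
    """Detection -> localization -> pairing for one stack; returns its pair table."""
    image_id = image_id if image_id is not None else Path(stack_path).stem
    grids = cio.load_stack(
        stack_path,
        channel_map={v: k for k, v in config.channel_indices.items()},
        voxel_size_nm=config.voxel_size_nm,
        axis_order=config.axis_order,
    )
    by_label = {g.channel_label: g for g in grids}
    detector = config.detector()

    labels = None
    if config.nuclei_channel is not None:
        labels = segment_nuclei(
            by_label[config.nuclei_channel],
            smoothing_sigma_nm=config.nuclei_smoothing_sigma_nm,
            min_volume_nm3=config.nuclei_min_volume_nm3,
        )
        logger.info("image %s: %d nuclei", image_id, int(labels.max()))

    centroids = {}
    for role, label in (("reference", config.reference_channel), ("moving", config.moving_channel)):
        stack = by_label[label]
        candidates = detector.detect(stack)
        if labels is not None:
            candidates = filter_candidates_by_nuclei(candidates, labels)
        table = localize_all(
            stack,
            candidates,
            image_id=image_id,
            channel_label=label,
            crop_radii_nm=config.crop_radii_nm,
            initial_sigma_nm=config.expected_sigma_nm,
            fallback_policy=config.fallback_policy,
        )
        logger.info(
            "image %s channel %s (%s): %d candidates, %d localized",
            image_id, label, role, len(candidates), len(table),
        )
        centroids[role] = table

    pairs = pair_spots(
        centroids["reference"],
        centroids["moving"],
        max_distance_nm=config.max_pair_distance_nm,
        require_same_nucleus=config.require_same_nucleus,
    )
    logger.info("image %s: %d pairs", image_id, len(pairs))
    return pairs


def run_measure(
    config: PipelineConfig,
    stack_paths: Sequence[str | Path],
    output_dir: str | Path | None = None,
) -> dict:
    """Measure inter-channel distances across stacks, with correction.

    LCC is always fitted in-run on the measured pairs.  ACC is loaded from
    ``config.transform_path`` when given (for non-colocalized measurement
    data, calibrated on a parallel colocalization experiment); otherwise it
    is fitted in-run on the IQR-filtered pairs (valid for colocalization
    data).  Writes pair tables, a summary CSV and report figures; returns
    the tables and summaries.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "resolved_config.json")

    per_image = [extract_pairs_for_image(config, p) for p in stack_paths]
    pairs = aggregate_pairs(per_image)
    if len(pairs) == 0:
        cio.write_results(cio.empty_pair_table(), out / "pairs_uncorrected.csv", allow_empty=True)
        raise EmptyResultError("no spot pairs found in any input stack")
    cio.write_results(pairs, out / "pairs_uncorrected.csv")

    summaries: list[DistanceSummary] = [summarize_pairs(pairs, label="uncorrected")]
    raw_values = {"uncorrected": pairs["raw_distance_nm"].to_numpy()}
    results: dict = {"pairs_uncorrected": pairs, "per_image_pair_counts": [len(p) for p in per_image]}

    lcc = acc = None
    if config.method in ("lcc", "both"):
        lcc = fit_lcc(pairs)
        corrected = apply_lcc(lcc, pairs)
        cio.write_results(corrected, out / "pairs_lcc.csv")
        summaries.append(summarize_pairs(corrected, label="lcc"))
        raw_values["lcc"] = corrected["raw_distance_nm"].to_numpy()
        results["pairs_lcc"] = corrected
        results["lcc"] = lcc
    if config.method in ("acc", "both"):
        if config.transform_path is not None:
            acc = load_transform(config.transform_path)
            for want, got in (
                (config.reference_channel, acc.reference_channel),
                (config.moving_channel, acc.moving_channel),
            ):
                if got and got != want:
                    raise ValueError(
                        f"stored transform channels ({acc.reference_channel!r} -> "
                        f"{acc.moving_channel!r}) do not match config "
                        f"({config.reference_channel!r} -> {config.moving_channel!r})"
                    )
        else:
            acc = fit_acc(
                filter_pairs_iqr(pairs, k=config.iqr_k),
                reference_channel=config.reference_channel,
                moving_channel=config.moving_channel,
            )
            save_transform(acc, out / "transform_acc.json")
        corrected = apply_transform_to_pairs(acc, pairs)
        cio.write_results(corrected, out / "pairs_acc.csv")
        summaries.append(summarize_pairs(corrected, label="acc"))
        raw_values["acc"] = corrected["raw_distance_nm"].to_numpy()
        results["pairs_acc"] = corrected
        results["acc"] = acc

    if config.method == "both":
        agreement = correction_agreement(pairs, lcc, acc)
        (out / "agreement.json").write_text(json.dumps(agreement, indent=2), encoding="utf-8")
        results["agreement"] = agreement
        logger.info(
            "ACC/LCC agreement: medians %.2f / %.2f nm (|diff| %.2f nm)%s",
            agreement["median_acc_nm"],
            agreement["median_lcc_nm"],
            agreement["median_abs_difference_nm"],
            " DIVERGED" if agreement["diverged"] else "",
        )

    distribution_report(summaries, raw_values, out)
    results["summaries"] = summaries
    return results


def run_calibrate(
    config: PipelineConfig,
    stack_paths: Sequence[str | Path],
    transform_out: str | Path,
) -> AffineTransform3D:
    """Fit the affine correction on colocalization stacks and persist it.

    The caller asserts the inputs are colocalization-type data (same target
    labeled in both channels) acquired under the measurement conditions.
    """
    per_image = [extract_pairs_for_image(config, p) for p in stack_paths]
    pairs = aggregate_pairs(per_image)
    if len(pairs) < 4:
        raise EmptyResultError(f"calibration found only {len(pairs)} pairs; cannot IQR-filter")
    filtered = filter_pairs_iqr(pairs, k=config.iqr_k)
    transform = fit_acc(
        filtered,
        reference_channel=config.reference_channel,
        moving_channel=config.moving_channel,
    )
    save_transform(transform, transform_out)
    logger.info(
        "calibrated affine on %d pairs (%d before filtering) from %d stacks",
        transform.n_pairs, len(pairs), len(stack_paths),
    )
    return transform


def run_simulate(
    spec: SceneSpec,
    output_dir: str | Path,
    render: bool = True,
    shape: tuple[int, int, int] = (16, 128, 128),
    voxel_size_nm: tuple[float, float, float] = cio.DEFAULT_VOXEL_SIZE_NM,
    sigma_xy_nm: float = 130.0,
    sigma_z_nm: float = 300.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_model: str = "poisson",
    image_id: str = "synthetic",
) -> GroundTruthScene:
    """Generate a scene and write ground truth (and optionally stacks) to disk.

    Writes ``truth.csv`` (pre-noise positions), ``pairs_truth.csv``
    (observed positions paired by ground-truth identity), the scene spec
    JSON for provenance, and — when rendering — a 2-channel TIFF stack.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = generate_scene(spec)
    spec.to_json(out / "scene_spec.json")
    cio.write_results(scene.to_truth_table(image_id), out / "truth.csv")
    cio.write_results(scene.to_pairs(image_id), out / "pairs_truth.csv")
    if render:
        grids = [
            render_stack(
                scene, ch, shape=shape, voxel_size_nm=voxel_size_nm,
                sigma_xy_nm=sigma_xy_nm, sigma_z_nm=sigma_z_nm,
                amplitude=amplitude, background=background,
                noise_model=noise_model, seed=spec.seed,
            )
            for ch in ("A", "B")
        ]
        cio.save_stack(out / f"{image_id}.tif", grids)
    return scene
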