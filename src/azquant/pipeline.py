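"""End-to-end orchestration: deconvolve → threshold → detect → segment →
profile → group statistics, with config, provenance and the synthetic
benchmark entry point.

Every run is driven by a single serializable :class:`PipelineConfig`; all
randomness flows from its root seed, so a run is reproducible bit-for-bit
from config + seed. The stage order mirrors the imaging analysis it
automates: per-compartment volumes are sampled, puncta are detected and
segmented in 3D, per-cluster intensities are extracted, the per-compartment
median and the per-sample heterogeneity H are computed, and groups are
compared with the nonparametric battery.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import segmentation as seg
from .heterogeneity import (
    CompartmentProfile,
    HeterogeneityResult,
    profile_from_records,
)
from .psf import PSFModel, fitted_window, richardson_lucy, synthetic_gaussian_psf
from .stack_io import ImageStack, write_cluster_table, write_json_summary
from .stats import TestResult, bh_fdr, kruskal_wallis, mann_whitney_u, oneway_anova_log
from .synthetic import NoiseModel, SceneConfig, generate_group_study

logger = logging.getLogger("azquant")

__all__ = [
    "SegmentationParams",
    "PipelineConfig",
    "SampleResult",
    "analyze_sample",
    "run_pipeline",
    "run_synthetic_benchmark",
]


@dataclass
class SegmentationParams:
    """Detection/measurement knobs, echoed into every output bundle."""

    threshold_mode: str = "mean_plus_k_sd"
    threshold_value: float = 3.0
    min_distance_um: float = 0.4
    noise_tolerance: float = 0.0
    fraction: float = 0.5
    floor: float = 0.0
    max_radius_um: float = 0.6
    split: str = "none"
    dilate: int = 0
    background_subtract: bool = True
    statistic: str = "mean"
    log_base: float = 2.0
    # intensities are extracted from the raw volume even when detection ran
    # on the deconvolved one; partial RL convergence distorts intensity
    # ratios, while ROI geometry benefits from the sharpened image
    measure_on: str = "raw"


@dataclass
class DeconvolutionParams:
    enabled: bool = True
    n_iter: int = 15
    epsilon: float = 1e-12
    # synthetic PSF used when no bead-derived PSF is supplied
    psf_sigma_um: tuple[float, float, float] = (0.5, 0.15, 0.15)


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    deconvolution: DeconvolutionParams = field(default_factory=DeconvolutionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    groups: dict[str, int] = field(default_factory=lambda: {"fed": 15, "starved": 15})
    h_true: dict[str, float] = field(default_factory=lambda: {"fed": 0.5, "starved": 0.25})
    comparisons: list[tuple[str, str]] = field(default_factory=lambda: [("fed", "starved")])
    test: str = "mann-whitney"
    fdr_q: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return _clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        if "scene" in d and isinstance(d["scene"], dict):
            sc = dict(d["scene"])
            for key in ("shape", "counts", "log_amp_mean", "log_amp_sd", "margin_um"):
                if key in sc and isinstance(sc[key], list):
                    sc[key] = tuple(sc[key])
            if "voxel_size" in sc and isinstance(sc["voxel_size"], (list, dict)):
                vs = sc["voxel_size"]
                sc["voxel_size"] = (
                    (vs["z"], vs["y"], vs["x"]) if isinstance(vs, dict) else tuple(vs)
                )
            d["scene"] = SceneConfig(**sc)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if "deconvolution" in d and isinstance(d["deconvolution"], dict):
            dc = dict(d["deconvolution"])
            if "psf_sigma_um" in dc and isinstance(dc["psf_sigma_um"], list):
                dc["psf_sigma_um"] = tuple(dc["psf_sigma_um"])
            d["deconvolution"] = DeconvolutionParams(**dc)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "comparisons" in d:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


@dataclass
class SampleResult:
    sample_id: str
    group: str
    records: list[seg.ClusterRecord]
    profile: CompartmentProfile
    heterogeneity: HeterogeneityResult | None
    threshold: float
    n_seeds: int

    @property
    def H(self) -> float:
        return self.heterogeneity.H if self.heterogeneity is not None else np.nan


def analyze_sample(
    stack: ImageStack,
    compartment_labels: np.ndarray,
    compartment_names: dict[int, str],
    params: SegmentationParams,
    psf: PSFModel | None = None,
    deconv: DeconvolutionParams | None = None,
    sample_id: str = "",
    group: str = "",
    channel: str | int = 0,
) -> SampleResult:
    """Run the single-sample measurement chain on one stack.

    Optional Richardson–Lucy deconvolution with ``psf`` precedes detection.
    When ``background_subtract`` is on, the median intensity of
    sub-threshold voxels is subtracted from every per-cluster intensity
    statistic, so compartment medians estimate signal above background (a
    ratio-preserving correction for the additive background level).
    """
    raw = stack.channel(channel).astype(float)
    vol_detect = raw
    if deconv is not None and deconv.enabled:
        if psf is None:
            psf = synthetic_gaussian_psf(
                deconv.psf_sigma_um,
                window=fitted_window(stack.shape_zyx),
                voxel_size=stack.voxel_size,
            )
        vol_detect = richardson_lucy(raw, psf, n_iter=deconv.n_iter, epsilon=deconv.epsilon)
    mask, threshold = seg.apply_intensity_threshold(
        vol_detect, mode=params.threshold_mode, value=params.threshold_value
    )
    mask &= compartment_labels > 0
    seeds = seg.find_maxima_3d(
        vol_detect,
        stack.voxel_size,
        mask=mask,
        min_distance_um=params.min_distance_um,
        noise_tolerance=params.noise_tolerance,
    )
    labels, _ = seg.segment_spots(
        vol_detect,
        seeds,
        stack.voxel_size,
        fraction=params.fraction,
        floor=params.floor,
        max_radius_um=params.max_radius_um,
        split=params.split,
        dilate=params.dilate,
        stats=False,
    )
    vol_measure = raw if params.measure_on == "raw" else vol_detect
    records = seg.compute_cluster_stats(
        labels,
        vol_measure,
        stack.voxel_size,
        seeds=seeds,
        compartments=compartment_labels,
        compartment_names=compartment_names,
    )
    if params.background_subtract:
        bg_mask, _ = seg.apply_intensity_threshold(
            vol_measure, mode=params.threshold_mode, value=params.threshold_value
        )
        below = vol_measure[(~bg_mask) & (compartment_labels > 0)]
        bg = float(np.median(below)) if below.size else 0.0
        for r in records:
            r.sum_intensity -= bg * r.volume_voxels
            r.mean_intensity -= bg
            r.median_intensity -= bg
            r.max_intensity -= bg
        records = [r for r in records if r.mean_intensity > 0]
    for r in records:
        r.sample_id = sample_id
    compartments = [compartment_names[k] for k in sorted(compartment_names)]
    profile, het = profile_from_records(
        records,
        sample_id=sample_id,
        compartments=compartments,
        statistic=params.statistic,
        log_base=params.log_base,
    )
    logger.info(
        "sample %s: threshold=%.3g seeds=%d clusters/compartment=%s H=%s",
        sample_id,
        threshold,
        len(seeds),
        profile.counts.tolist(),
        f"{het.H:.4f}" if het else "undefined",
    )
    return SampleResult(sample_id, group, records, profile, het, threshold, len(seeds))


def _compare_groups(
    results: Sequence[SampleResult],
    comparisons: Sequence[tuple[str, str]],
    test: str,
    fdr_q: float,
) -> list[TestResult]:
    by_group: dict[str, list[float]] = {}
    for r in results:
        if r.heterogeneity is not None:
            by_group.setdefault(r.group, []).append(r.H)
    out: list[TestResult] = []
    for a, b in comparisons:
        if test == "mann-whitney":
            tr = mann_whitney_u(by_group[a], by_group[b])
        elif test == "kruskal-wallis":
            tr = kruskal_wallis([by_group[a], by_group[b]])
        elif test == "anova-log":
            tr = oneway_anova_log([by_group[a], by_group[b]])
        else:
            raise ValueError(f"unknown group test {test!r}")
        tr.family = "group-comparisons"
        tr.notes["comparison"] = f"{a} vs {b}"
        out.append(tr)
    if len(out) > 1:
        adj, _ = bh_fdr([t.pvalue for t in out], q=fdr_q)
        for t, a_p in zip(out, adj):
            t.adjusted_p = float(a_p)
    return out


def run_pipeline(
    config: PipelineConfig,
    output_dir: str | Path | None = None,
    psf: PSFModel | None = None,
) -> dict[str, Any]:
    """Run the full synthetic-cohort pipeline described by ``config``.

    Generates the group study, analyzes each sample, compares groups, and
    (when ``output_dir`` is given) writes the cluster table CSV, per-sample
    summary CSV/JSON and the echoed config. A sample failing analysis is
    logged and excluded; it does not abort the cohort.
    """
    if not config.groups or all(n == 0 for n in config.groups.values()):
        raise ValueError("empty cohort: no samples configured")
    render_psf = psf or synthetic_gaussian_psf(
        config.deconvolution.psf_sigma_um,
        window=fitted_window(config.scene.shape),
        voxel_size=config.scene.voxel_size,
    )
    samples = generate_group_study(
        config.groups,
        config.h_true,
        config.scene,
        render_psf,
        config.noise,
        seed=config.seed,
    )
    results: list[SampleResult] = []
    for i, s in enumerate(samples):
        sid = f"{s.group}-{i:03d}"
        try:
            results.append(
                analyze_sample(
                    s.stack,
                    s.scene.compartment_labels,
                    s.scene.compartment_names,
                    config.segmentation,
                    psf=render_psf,
                    deconv=config.deconvolution,
                    sample_id=sid,
                    group=s.group,
                )
            )
        except Exception as exc:  # keep the cohort alive
            logger.error("sample %s failed: %s", sid, exc)
    tests = _compare_groups(results, config.comparisons, config.test, config.fdr_q)
    bundle = {
        "config": config.to_dict(),
        "samples": results,
        "tests": tests,
        "true_H": {s.group + "-" + f"{i:03d}": s.scene.true_H for i, s in enumerate(samples)},
    }
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        all_records = [r for res in results for r in res.records]
        write_cluster_table(all_records, output_dir / "clusters.csv")
        rows = []
        for res in results:
            row = {"sample_id": res.sample_id, "group": res.group, "H": res.H}
            for c, m, nm in zip(
                res.profile.compartments, res.profile.medians, res.profile.normalized
            ):
                row[f"median_{c}"] = m
                row[f"normalized_{c}"] = nm
            rows.append(row)
        pd.DataFrame(rows).to_csv(output_dir / "samples.csv", index=False, float_format="%.10g")
        write_json_summary(
            {
                "tests": [dataclasses.asdict(t) for t in tests],
                "config": config.to_dict(),
            },
            output_dir / "summary.json",
        )
        config.to_yaml(output_dir / "config.yaml")
    return bundle


def run_synthetic_benchmark(
    seed: int = 0,
    n_power_runs: int = 50,
    n_per_group: int = 15,
    small_scene: SceneConfig | None = None,
) -> dict[str, Any]:
    """Detection, recovery and power metrics on reduced synthetic scenes.

    Uses a small grid per run so the whole benchmark is desk-scale; returns
    a dict of metric tables (see the acceptance script for the full-size
    recovery experiment).
    """
    from .benchmarks import (
        detection_benchmark,
        power_benchmark,
        recovery_benchmark,
    )

    scene = small_scene or SceneConfig(
        shape=(16, 48, 120),
        counts=(15,) * 5,
        min_separation_um=0.5,
        margin_um=(0.8, 0.4, 0.4),
        seed=seed,
    )
    out: dict[str, Any] = {}
    out["detection"] = detection_benchmark(seed=seed)
    out["recovery"] = recovery_benchmark(n_samples=3, seed=seed, scene=scene)
    out["power"] = power_benchmark(
        n_runs=n_power_runs, n_per_group=n_per_group, seed=seed
    )
    return out
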