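"""Full slice-wise pipeline: preprocess -> k-means -> quantum dragonfly
refinement -> contour initialization -> level-set segmentation, restacked
into an output mask volume with a per-slice run report.

One global seed deterministically derives every per-slice seed
(SeedSequence of (global seed, slice index)), so identical config + seed
produce bit-identical segmentations.  Slices without brain foreground or
without a surviving tumor cluster yield empty segmentations with a
warning in the report, never an abort.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy import ndimage

from . import contour as contour_mod
from . import cluster as kmeans_mod
from . import level_set as ls_mod
from . import metrics as metrics_mod
from . import qda as qda_mod
from .mri_io import Volume, load_mask, load_volume, save_mask, slices_to_volume, volume_to_slices
from .preprocess import PreprocessConfig, preprocess_slice

__all__ = ["PipelineConfig", "run_pipeline", "segment_volume", "run_evaluate"]


@dataclass
class ClusteringConfig:
    """min_separation gates tumor candidacy: the tumor cluster's centroid
    must sit at least this many pooled within-cluster standard deviations
    away from its nearest neighbor centroid.  A quantile split of a single
    noise mode yields gaps of ~1-3 sd, a genuinely distinct hyperintense
    population far more."""

    K: int = 4
    tol: float | None = None
    max_iter: int = 100
    tumor_strategy: str = "brightest"
    min_separation: float = 5.0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.tumor_strategy not in ("brightest", "outlier"):
            raise ValueError(f"unknown tumor_strategy {self.tumor_strategy!r}")


@dataclass
class ContourConfig:
    """min_area drops clustering speckle; max_area_fraction drops
    candidate components larger than this fraction of the brain mask
    (tumor-free slices elect a whole normal-tissue class as the brightest
    cluster, which no plausible tumor cross-section approaches)."""

    min_area: int = 20
    max_area_fraction: float = 0.08
    cleanup: bool = True


@dataclass
class LevelSetConfig:
    Wa: float = 1.0
    Wc: float = 1.0
    nu: float = 0.3
    sigma: float = 1.5
    dt_override: float | None = None
    max_iters: int = 1000
    reinit_every: int = 80
    convergence_tol: float = 1e-3
    include_advection_term: bool = True
    init_dilation: int = 0

    def params(self) -> ls_mod.LevelSetParams:
        return ls_mod.LevelSetParams(
            Wa=self.Wa,
            Wc=self.Wc,
            nu=self.nu,
            dt_override=self.dt_override,
            max_iters=self.max_iters,
            reinit_every=self.reinit_every,
            convergence_tol=self.convergence_tol,
            include_advection_term=self.include_advection_term,
        )


@dataclass
class QDASection:
    n_agents: int = 20
    n_iter: int = 100
    theta: float = 0.02 * np.pi
    mutation_prob: float = 0.1
    mutation_k: float = 1.0
    levy_beta: float = 1.5
    stagnation_window: int = 15
    stagnation_tol: float = 1e-6
    init_spread: float = 0.1
    fitness_mode: str = "unsupervised"
    printed_cohesion_sign: bool = False

    def config(self, seed: int) -> qda_mod.QDAConfig:
        return qda_mod.QDAConfig(seed=seed, **asdict(self))


def _build_section(cls, values: dict[str, Any], name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys in section {name!r}: {sorted(unknown)}")
    return cls(**values)


@dataclass
class PipelineConfig:
    """Nested configuration mirroring each stage's keys, plus the global
    seed, the slicing plane, and the optional warm start (seed slice k's
    swarm from slice k-1's best centroids)."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    qda: QDASection = field(default_factory=QDASection)
    contour: ContourConfig = field(default_factory=ContourConfig)
    level_set: LevelSetConfig = field(default_factory=LevelSetConfig)
    seed: int = 0
    plane: str = "axial"
    warm_start: bool = False

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw or {})
        sections = {
            "preprocess": PreprocessConfig,
            "clustering": ClusteringConfig,
            "qda": QDASection,
            "contour": ContourConfig,
            "level_set": LevelSetConfig,
        }
        kwargs: dict[str, Any] = {}
        for name, section_cls in sections.items():
            if name in raw:
                kwargs[name] = _build_section(section_cls, raw.pop(name), name)
        for scalar in ("seed", "plane", "warm_start"):
            if scalar in raw:
                kwargs[scalar] = raw.pop(scalar)
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict[str, Any]:
        """Full config as a plain dict (logged so runs are self-describing)."""
        return asdict(self)


def _slice_seed(global_seed: int, index: int) -> int:
    return int(np.random.SeedSequence((global_seed, index)).generate_state(1)[0])


def _tumor_cluster_separated(
    pixels: np.ndarray, model, tumor_idx: int, min_separation: float
) -> bool:
    """True when the tumor centroid is a distinct intensity population.

    The gap to the nearest other centroid is compared against the pooled
    within-cluster standard deviation of the two clusters involved.
    """
    cents = model.centroids
    others = np.delete(np.arange(cents.size), tumor_idx)
    nearest = others[np.argmin(np.abs(cents[others] - cents[tumor_idx]))]
    gap = abs(cents[tumor_idx] - cents[nearest])
    members_t = pixels[model.labels == tumor_idx]
    members_n = pixels[model.labels == nearest]
    if members_t.size < 2 or members_n.size < 2:
        return gap > 0
    pooled = np.sqrt((members_t.var() + members_n.var()) / 2.0)
    if pooled == 0:
        return gap > 0
    return gap >= min_separation * pooled


def segment_slice_full(sl, cfg: PipelineConfig, seed: int,
                       warm_centroids: np.ndarray | None = None) -> dict[str, Any]:
    """Run the whole per-slice pipeline; returns a record with the mask."""
    t0 = time.perf_counter()
    rec: dict[str, Any] = {"index": sl.index, "warnings": []}
    shape = sl.data.shape
    pre = preprocess_slice(sl, cfg.preprocess)
    if pre.empty:
        rec["warnings"].append("empty-brain")
        rec["mask"] = np.zeros(shape, dtype=bool)
        rec["seconds"] = time.perf_counter() - t0
        return rec
    # cluster and evolve on the diffused intensities: global equalization
    # flattens the histogram by construction, which erases the intensity
    # gap the tissue clustering relies on (the equalized slice is kept as
    # the display-contrast product)
    work = pre.smooth if pre.smooth is not None else pre.clean
    pixels = work.data[pre.brain_mask]
    if np.unique(pixels).size < cfg.clustering.K:
        rec["warnings"].append("too-few-distinct-intensities")
        rec["mask"] = np.zeros(shape, dtype=bool)
        rec["seconds"] = time.perf_counter() - t0
        return rec

    km = kmeans_mod.kmeans(
        pixels,
        K=cfg.clustering.K,
        tol=cfg.clustering.tol,
        max_iter=cfg.clustering.max_iter,
    )
    bounds = qda_mod.Bounds(float(pixels.min()), float(pixels.max()) + 1e-9)
    seed_model = km
    if warm_centroids is not None and warm_centroids.size == cfg.clustering.K:
        warm = np.sort(np.asarray(bounds.clip(warm_centroids)))
        seed_model = kmeans_mod.ClusterModel(
            centroids=warm,
            labels=kmeans_mod.assign(pixels, warm),
            objective=0.0,
            K=cfg.clustering.K,
        )
    best, history = qda_mod.optimize(
        pixels, seed_model, cfg.qda.config(seed), bounds
    )
    rec["kmeans_objective"] = km.objective
    rec["qda_iterations"] = len(history) - 1
    rec["qda_final_fitness"] = history[-1]
    rec["centroids"] = best.centroids.tolist()

    tumor_idx = kmeans_mod.identify_tumor_cluster(
        best, cfg.clustering.tumor_strategy, brain_mean=float(pixels.mean())
    )
    if not _tumor_cluster_separated(
        pixels, best, tumor_idx, cfg.clustering.min_separation
    ):
        rec["warnings"].append("no-tumor-cluster")
        rec["mask"] = np.zeros(shape, dtype=bool)
        rec["levelset_iterations"] = 0
        rec["seconds"] = time.perf_counter() - t0
        return rec
    label_img = np.zeros(shape, dtype=np.int64) - 1
    label_img[pre.brain_mask] = best.labels
    max_area = int(cfg.contour.max_area_fraction * int(pre.brain_mask.sum()))
    init_mask, empty = contour_mod.tumor_mask(
        label_img,
        tumor_idx,
        min_area=cfg.contour.min_area,
        max_area=max_area,
        cleanup=cfg.contour.cleanup,
    )
    if empty:
        rec["warnings"].append("no-tumor-cluster")
        rec["mask"] = np.zeros(shape, dtype=bool)
        rec["levelset_iterations"] = 0
        rec["seconds"] = time.perf_counter() - t0
        return rec

    params = cfg.level_set.params()
    seg = ls_mod.segment_slice(
        work,
        init_mask,
        params,
        sigma=cfg.level_set.sigma,
        init_dilation=cfg.level_set.init_dilation,
    )
    seg &= pre.brain_mask  # tumor tissue lies inside the brain
    if cfg.contour.cleanup and seg.any():
        # re-apply the minimum-lesion-size rule: components the evolution
        # shrank below it are noise residue, not tumor
        lab_seg, _ = ndimage.label(seg)
        sizes = np.bincount(lab_seg.ravel())[1:]
        keep = 1 + np.flatnonzero(sizes >= cfg.contour.min_area)
        seg = np.isin(lab_seg, keep)
    rec["mask"] = seg
    rec["tumor_pixels"] = int(seg.sum())
    rec["seconds"] = time.perf_counter() - t0
    return rec


def segment_volume(vol: Volume, cfg: PipelineConfig | None = None) -> tuple[Volume, dict]:
    """Segment every slice of a volume; returns (mask volume, report)."""
    cfg = cfg or PipelineConfig()
    slices = volume_to_slices(vol, cfg.plane)
    records = []
    masks = []
    warm: np.ndarray | None = None
    for sl in slices:
        rec = segment_slice_full(
            sl, cfg, _slice_seed(cfg.seed, sl.index), warm_centroids=warm
        )
        if cfg.warm_start and "centroids" in rec:
            warm = np.asarray(rec["centroids"])
        masks.append(rec.pop("mask"))
        records.append(rec)
    mask_data = [m.astype(np.float64) for m in masks]
    seg = slices_to_volume(mask_data, vol, cfg.plane)
    report = {
        "config": cfg.resolved(),
        "n_slices": len(records),
        "n_warned": sum(1 for r in records if r["warnings"]),
        "total_tumor_voxels": int(seg.data.sum()),
        "slices": records,
    }
    return Volume(seg.data > 0, vol.spacing, vol.affine), report


def run_pipeline(
    input_path: str | Path,
    cfg: PipelineConfig | None = None,
    out_path: str | Path | None = None,
) -> tuple[Path | None, dict]:
    """Load a NIfTI volume, segment it, optionally write the mask."""
    vol = load_volume(input_path)
    seg, report = segment_volume(vol, cfg)
    if out_path is not None:
        save_mask(out_path, seg.data > 0, vol)
        return Path(out_path), report
    return None, report


def run_evaluate(pred_path: str | Path, truth_path: str | Path) -> dict:
    """Metric report between a predicted and a ground-truth mask volume."""
    pred = load_mask(pred_path)
    truth = load_mask(truth_path)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    img = load_volume(pred_path)
    return metrics_mod.evaluate_masks(pred, truth, spacing=img.spacing)
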