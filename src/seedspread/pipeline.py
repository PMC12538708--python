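"""End-to-end virtual Taguchi experiment.

Replays the device-screening protocol with the simulator standing in for
the hardware: for each of the 18 design runs and each of the three
replicate sample groups (soybeans only, +1 % *A. artemisiifolia*, +1 %
*A. trifida*), a batch of scenes is generated at the run's factor
levels, each scene is scored with grid-binned Moran's I, and the per-run
observations feed the response table, ANOVA and optimal-level selection.

Factor levels reach the simulator through a declared knob map
(factor -> level -> ProcessParams overrides, merged in factor order);
the default map lets the two speed factors set the layout regime —
mirroring the physical study, where they dominate uniformity — and
leaves the remaining factors inert. Every scene's seed is derived from
the master seed by a counter-based scheme (SeedSequence spawn key =
(run, group, image)), so any scene can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import scene_sim, segmentation, taguchi, uniformity
from .scene_sim import ProcessParams

__all__ = [
    "PipelineConfig",
    "VirtualExperimentResult",
    "DEFAULT_KNOB_MAP",
    "DEFAULT_GROUPS",
    "run_virtual_experiment",
    "score_design_runs",
]

log = logging.getLogger("seedspread")

#: Default factor-level -> simulator-knob overrides. The conveyor motor
#: speed picks the point-process regime (slow belt -> pile-ups/clusters;
#: mid speed -> well-singulated hard-core layouts; fast -> random
#: thinning toward CSR), the roller speed scales seed throughput, and
#: the remaining four factors are inert by default (their physical
#: effects were minor). ``count_scale`` multiplies the group's seed
#: counts; all other keys override ProcessParams fields.
DEFAULT_KNOB_MAP: dict = {
    "motor_speed": {
        "50": {
            "process": "thomas",
            "cluster_parent_intensity": 3.0e-4,
            "cluster_sd_mm": 12.0,
        },
        "150": {"process": "hardcore", "hardcore_radius_mm": 10.0},
        "250": {"process": "poisson"},
    },
    "roller_speed": {
        "50": {"count_scale": 0.8},
        "150": {"count_scale": 1.0},
        "250": {"count_scale": 1.2},
    },
}

#: Replicate sample groups of the screening protocol: soybeans only,
#: then soybeans spiked with ~1 % (by count) of each weed species.
DEFAULT_GROUPS: tuple = (
    ("soy_only", {"soybean": 280}),
    ("plus_artemisiifolia", {"soybean": 280, "a_artemisiifolia": 3}),
    ("plus_trifida", {"soybean": 280, "a_trifida": 3}),
)

_PROCESS_FIELDS = {f.name for f in dataclasses.fields(ProcessParams)}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the virtual experiment.

    ``score_from`` selects the scoring path: ``"ground_truth_mask"``
    (fast; rasterise the layout's exact mask) or ``"hsv"`` (full chain:
    RGB render, optional unsharp sharpen, HSV threshold). Grid tiles are
    derived from the raster size and (n_rows, n_cols) and must divide it
    exactly.
    """

    base_params: ProcessParams = ProcessParams(process="poisson")
    knob_map: dict = field(default_factory=lambda: DEFAULT_KNOB_MAP)
    groups: tuple = DEFAULT_GROUPS
    images_per_run: int = 100
    belt_width_mm: float = 384.0
    belt_height_mm: float = 216.0
    px_per_mm: float = 10.0
    n_rows: int = 6
    n_cols: int = 8
    scheme: str = "queen"
    score_from: str = "ground_truth_mask"
    hsv_ranges: dict = field(default_factory=lambda: dict(segmentation.DEFAULT_HSV_RANGES))
    sharpen: bool = False
    master_seed: int = 0

    def __post_init__(self):
        if self.images_per_run < 1:
            raise ValueError("images_per_run must be >= 1")
        if self.score_from not in ("ground_truth_mask", "hsv"):
            raise ValueError("score_from must be 'ground_truth_mask' or 'hsv'")

    def tile_shape_px(self) -> tuple[int, int]:
        w = int(round(self.belt_width_mm * self.px_per_mm))
        h = int(round(self.belt_height_mm * self.px_per_mm))
        if w % self.n_cols or h % self.n_rows:
            raise ValueError(
                f"raster {w}x{h} not divisible into {self.n_rows}x{self.n_cols} tiles"
            )
        return w // self.n_cols, h // self.n_rows

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "base_params" in raw:
            raw["base_params"] = ProcessParams(**raw["base_params"])
        if "groups" in raw:
            raw["groups"] = tuple(
                (name, {k: int(v) for k, v in counts.items()}) for name, counts in raw["groups"]
            )
        return cls(**raw)


def scene_seed(master_seed: int, run: int, group: int, image: int) -> int:
    """Deterministic per-scene seed: counter-keyed SeedSequence draw."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(run, group, image))
    return int(ss.generate_state(1)[0] % (2**31))


def _params_for_run(
    cfg: PipelineConfig, design: taguchi.TaguchiDesign, run_idx: int, counts: dict
) -> ProcessParams:
    """Merge knob overrides for this run's factor levels onto the base
    params, honouring factor order; sanitise process-specific fields."""
    overrides: dict = {}
    for j, (name, levels) in enumerate(design.factors):
        level_label = levels[design.runs[run_idx, j]]
        overrides.update(cfg.knob_map.get(name, {}).get(level_label, {}))
    count_scale = float(overrides.pop("count_scale", 1.0))
    unknown = set(overrides) - _PROCESS_FIELDS
    if unknown:
        raise ValueError(f"unknown knob(s) in knob_map: {sorted(unknown)}")
    merged = {**dataclasses.asdict(cfg.base_params), **overrides}
    process = merged["process"]
    if process != "hardcore":
        merged["hardcore_radius_mm"] = 0.0
    if process != "thomas":
        for k in ("cluster_parent_intensity", "cluster_mean_children", "cluster_sd_mm"):
            merged[k] = 0.0
    merged["mix_counts"] = {
        label: max(int(round(k * count_scale)), 0) for label, k in counts.items()
    }
    return ProcessParams(**merged)


def _score_scene(cfg: PipelineConfig, layout: scene_sim.LayoutScene, weights) -> float:
    tile_w, tile_h = cfg.tile_shape_px()
    if cfg.score_from == "ground_truth_mask":
        mask = scene_sim.layout_mask(layout)
    else:
        image, _, _ = scene_sim.render_scene(layout)
        if cfg.sharpen:
            image = segmentation.unsharp_sharpen(image)
        mask = segmentation.hsv_segment(image, **cfg.hsv_ranges)
    props = segmentation.grid_proportions(mask, tile_w_px=tile_w, tile_h_px=tile_h)
    return uniformity.morans_i(props, weights).i


def score_design_runs(
    cfg: PipelineConfig,
    design: taguchi.TaguchiDesign,
    run_indices=None,
) -> tuple[list, list]:
    """Generate and score scenes for the given runs (all by default).

    Returns ``(observations, manifest)``: per requested run, the flat
    list of per-image Moran's I values over all groups, plus one
    manifest entry per scene recording its derivation (run, group,
    image, seed, process) and score.
    """
    weights = uniformity.build_weights(cfg.n_rows, cfg.n_cols, cfg.scheme)
    run_indices = list(range(design.n_runs)) if run_indices is None else list(run_indices)
    observations: list = []
    manifest: list = []
    for r in run_indices:
        t0 = time.perf_counter()
        run_obs: list = []
        for g, (group_name, counts) in enumerate(cfg.groups):
            params = _params_for_run(cfg, design, r, counts)
            for i in range(cfg.images_per_run):
                seed = scene_seed(cfg.master_seed, r, g, i)
                try:
                    layout = scene_sim.sample_layout(
                        params,
                        seed=seed,
                        belt_width_mm=cfg.belt_width_mm,
                        belt_height_mm=cfg.belt_height_mm,
                        px_per_mm=cfg.px_per_mm,
                    )
                    i_val = _score_scene(cfg, layout, weights)
                except Exception as exc:
                    raise RuntimeError(
                        f"run {r + 1}, group {group_name!r}, image {i}: {exc}"
                    ) from exc
                run_obs.append(i_val)
                manifest.append(
                    {
                        "run": r + 1,
                        "group": group_name,
                        "image": i,
                        "seed": seed,
                        "process": params.process,
                        "moran_i": i_val,
                    }
                )
        observations.append(run_obs)
        log.info("run %d scored in %.2f s", r + 1, time.perf_counter() - t0)
    return observations, manifest


@dataclass(frozen=True)
class VirtualExperimentResult:
    """Everything the virtual experiment produced."""

    runset: taguchi.TaguchiRunSet
    response: taguchi.ResponseTable
    anova_mean: taguchi.AnovaTable
    anova_sn: taguchi.AnovaTable
    optimal: dict
    manifest: list

    @staticmethod
    def _records(table: taguchi.AnovaTable) -> list:
        recs = table.to_frame().to_dict(orient="records")
        for rec in recs:
            for k, v in rec.items():
                if isinstance(v, float) and not np.isfinite(v):
                    rec[k] = None
        return recs

    def report(self) -> dict:
        rt = self.response
        return {
            "run_means": self.runset.run_means().tolist(),
            "run_sn_db": self.runset.run_sn().tolist(),
            "response": {
                "level_means": {f: rt.level_means[f].tolist() for f in rt.factor_names()},
                "level_sn": {f: rt.level_sn[f].tolist() for f in rt.factor_names()},
                "rank_mean": rt.ranks("mean"),
                "rank_sn": rt.ranks("sn"),
            },
            "anova_mean": self._records(self.anova_mean),
            "anova_sn": self._records(self.anova_sn),
            "optimal_levels": self.optimal,
            "n_scenes": len(self.manifest),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "csv").mkdir(parents=True, exist_ok=True)
        self.runset.to_csv(out / "csv" / "observations.csv")
        self.response.to_csv(out / "csv" / "response_table.csv")
        self.anova_mean.to_csv(out / "csv" / "anova_mean.csv")
        self.anova_sn.to_csv(out / "csv" / "anova_sn.csv")
        (out / "report.json").write_text(json.dumps(self.report(), indent=2) + "\n")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2) + "\n")


def run_virtual_experiment(
    cfg: PipelineConfig, design: taguchi.TaguchiDesign | None = None
) -> VirtualExperimentResult:
    """Run the full 18-run virtual screening and aggregate the analysis."""
    design = design or taguchi.l18_design()
    observations, manifest = score_design_runs(cfg, design)
    runset = taguchi.TaguchiRunSet(
        design=design, observations=tuple(tuple(o) for o in observations)
    )
    response = taguchi.response_table(runset)
    return VirtualExperimentResult(
        runset=runset,
        response=response,
        anova_mean=taguchi.anova(runset, "mean"),
        anova_sn=taguchi.anova(runset, "sn"),
        optimal=taguchi.optimal_levels(response),
        manifest=manifest,
    )
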