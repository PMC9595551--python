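"""End-to-end runs: simulate/load -> segment -> label -> measure -> summarize.

A run is fully described by a serializable :class:`RunConfig`; re-running an
archived config reproduces the outputs (bit-identically for deterministic
stages, identically given the seed for stochastic ones).  Every run can
archive its intermediate artifacts (mask, label map, per-label records) plus
a machine-readable report with the threshold used, spacing, windows,
versions, seed, and per-stage attrition counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .errors import ConfigError, LacunaError
from .labeling import LabelMap, exclude_border, label_components
from .morphometry import measure_all
from .phantom import PhantomParams, make_phantom, preset_params
from .quantify import (COUNT_WINDOW, MORPHO_WINDOW, SampleSummary, as_window,
                       fold_change, summarize)
from .segmentation import segment
from .volume_io import (VoxelGrid, mask_to_grid, read_volume, write_records,
                        write_volume)

log = logging.getLogger("lacuna3d")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (fully serializable)."""

    input_path: str | None = None       # volume on disk, or ...
    preset: str | None = None           # ... a phantom preset (ip/op/t/f)
    sample_id: str = "sample"
    spacing: tuple[float, float, float] | None = None
    shape: tuple[int, int, int] = (200, 200, 200)   # phantom domain
    seed: int = 0
    threshold: float | None = None      # None -> per-volume mean threshold
    windows: tuple = (COUNT_WINDOW, MORPHO_WINDOW)
    morpho_window: tuple[float, float] = MORPHO_WINDOW
    exclude_border: bool = False
    min_feret_mode: str = "orthogonal"
    blur_sigma_um: float = 0.0          # phantom degradation
    noise_sd: float = 0.0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "windows" in d:
            d["windows"] = tuple(tuple(w) for w in d["windows"])
        if "morpho_window" in d:
            d["morpho_window"] = tuple(d["morpho_window"])
        known = cls.__dataclass_fields__
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunResult:
    summary: SampleSummary
    records: list
    labelmap: LabelMap
    threshold_used: float
    report: dict
    truth: object | None = None


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order; see module docstring."""
    if (config.input_path is None) == (config.preset is None):
        raise ConfigError("exactly one of input_path or preset must be given")

    truth = None
    if config.preset is not None:
        params = preset_params(
            config.preset,
            shape=tuple(config.shape),
            spacing=tuple(config.spacing) if config.spacing else (1.0, 1.0, 1.0),
            seed=config.seed,
            blur_sigma_um=config.blur_sigma_um,
            noise_sd=config.noise_sd,
            name=config.sample_id,
        )
        log.info("simulate: preset=%s shape=%s seed=%d", config.preset, params.shape, params.seed)
        grid, _, truth = make_phantom(params)
        log.info("simulate: planted %d lacunae + %d canals in %.4f mm^3",
                 len(truth.lacunae), len(truth.canals), truth.domain_volume_mm3)
    else:
        grid = read_volume(config.input_path, spacing=config.spacing)
        if config.sample_id != "sample":
            grid.name = config.sample_id
        log.info("load: %s shape=%s spacing=%s", config.input_path, grid.shape, grid.spacing)

    mask, threshold_used = segment(grid, threshold=config.threshold)
    n_void = int(mask.data.sum())
    log.info("segment: threshold=%.6g void voxels=%d/%d (%.3f%%)",
             threshold_used, n_void, mask.data.size, 100 * mask.void_fraction)

    labelmap = label_components(mask)
    n_components = labelmap.n_labels
    log.info("label: %d 6-connected components", n_components)
    if config.exclude_border:
        labelmap = exclude_border(labelmap)
        log.info("label: border exclusion dropped %d components",
                 n_components - labelmap.n_labels)

    all_volumes = labelmap.volumes_um3()
    windows = [as_window(w) for w in config.windows]
    union_mask = np.zeros(len(all_volumes), dtype=bool)
    for w in windows + [as_window(config.morpho_window)]:
        union_mask |= w.contains(all_volumes)
    measured_ids = np.flatnonzero(union_mask) + 1
    log.info("filter: %d/%d labels inside the union of windows",
             len(measured_ids), len(all_volumes))

    records = measure_all(labelmap, label_ids=measured_ids,
                          min_feret_mode=config.min_feret_mode)

    summary = summarize(
        config.sample_id,
        records,
        analyzed_volume_mm3=grid.physical_volume_mm3,
        windows=windows,
        morpho_window=config.morpho_window,
        all_volumes_um3=all_volumes,
    )

    report = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config": config.to_dict(),
        "threshold_used": threshold_used,
        "threshold_source": "mean" if config.threshold is None else "override",
        "spacing_um": list(grid.spacing),
        "analyzed_volume_mm3": grid.physical_volume_mm3,
        "windows_um3": [[w.low, w.high] for w in windows],
        "min_feret_mode": config.min_feret_mode,
        "border_excluded": config.exclude_border,
        "seed": config.seed,
        "attrition": {
            "total_voxels": int(mask.data.size),
            "void_voxels": n_void,
            "components": n_components,
            "components_after_border_policy": labelmap.n_labels,
            "components_measured": int(len(measured_ids)),
            "counts_per_window": dict(summary.counts),
        },
    }
    if truth is not None:
        report["planted"] = {
            "lacunae": len(truth.lacunae),
            "canals": len(truth.canals),
            "concentration_per_mm3": truth.planted_concentration_per_mm3,
        }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_volume(mask_to_grid(mask), outdir / "mask.tif")
        write_volume(VoxelGrid(labelmap.data.astype(np.int32), labelmap.spacing,
                               name=grid.name), outdir / "labels.tif")
        write_records(records, outdir / "records.csv")
        _dump_json(summary.to_dict(), outdir / "summary.json")
        _dump_json(report, outdir / "run_report.json")
        _dump_json(config.to_dict(), outdir / "config.json")
        if truth is not None:
            truth.to_frame().to_csv(outdir / "truth.csv", index=False)

    return RunResult(summary=summary, records=records, labelmap=labelmap,
                     threshold_used=threshold_used, report=report, truth=truth)


def compare_groups(results_a, results_b, windows=(COUNT_WINDOW, MORPHO_WINDOW)) -> dict:
    """Per-sample concentrations per window plus the group fold-change
    (mean concentration of A over mean concentration of B)."""
    summaries_a = [r.summary if isinstance(r, RunResult) else r for r in results_a]
    summaries_b = [r.summary if isinstance(r, RunResult) else r for r in results_b]
    if not summaries_a or not summaries_b:
        raise ConfigError("both groups need at least one run")
    windows = [as_window(w) for w in windows]
    out = {
        "group_a": [s.to_dict() for s in summaries_a],
        "group_b": [s.to_dict() for s in summaries_b],
        "fold_change": {
            w.key: fold_change(summaries_a, summaries_b, w) for w in windows
        },
    }
    return out


def render_comparison(comparison: dict) -> str:
    """Human-readable group-comparison table."""
    lines = []
    for grp in ("group_a", "group_b"):
        lines.append(f"{grp}:")
        for s in comparison[grp]:
            concs = ", ".join(
                f"{k}: {v:,.0f}/mm^3" for k, v in s["concentrations_per_mm3"].items()
            )
            lines.append(f"  {s['sample_id']}: {concs}")
    lines.append("fold change (mean A / mean B):")
    for k, v in comparison["fold_change"].items():
        lines.append(f"  {k} um^3: {v:.3f}")
    return "\n".join(lines)
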