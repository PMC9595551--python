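"""Volume-window filtering, concentrations, histograms, sample summaries.

The counting procedure retains only objects with volumes inside a window of
10-2000 um^3 (objects below ~10 um^3 sit at the scan's resolution limit;
objects above 2000 um^3 are vascular canals and cavities, not lacunae).
Morphometric statistics use the narrower 20-2000 um^3 window.  Window
bounds are inclusive on both sides.

Lacuna concentration is the number of retained labels per mm^3 of analyzed
volume; by default the analyzed volume is the full scan volume (the scans'
fields of view are bone-filled), optionally a segmented bone volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import NumericError
from .morphometry import LacunaRecord

#: counting window (um^3)
COUNT_WINDOW = (10.0, 2000.0)
#: morphometry window (um^3)
MORPHO_WINDOW = (20.0, 2000.0)


@dataclass(frozen=True)
class VolumeWindow:
    """Inclusive object-volume window [low, high] in um^3."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise NumericError(f"need 0 < low < high, got [{self.low}, {self.high}]")

    @property
    def key(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return f"{fmt(self.low)}-{fmt(self.high)}"

    def contains(self, volume_um3) -> np.ndarray:
        v = np.asarray(volume_um3, dtype=np.float64)
        return (v >= self.low) & (v <= self.high)


def as_window(w) -> VolumeWindow:
    return w if isinstance(w, VolumeWindow) else VolumeWindow(*w)


def filter_by_volume(records: Sequence[LacunaRecord], window) -> list[LacunaRecord]:
    """Keep records whose volume lies in the window (stable order)."""
    window = as_window(window)
    return [r for r in records if window.contains(r.volume_um3)]


def concentration(count: int, analyzed_volume_mm3: float) -> float:
    """Objects per mm^3 of analyzed volume."""
    if not analyzed_volume_mm3 > 0:
        raise NumericError(f"analyzed volume must be positive, got {analyzed_volume_mm3}")
    return count / analyzed_volume_mm3


def volume_histogram(volumes_um3, bin_edges) -> np.ndarray:
    """Counts per half-open bin [e_i, e_{i+1}); values >= the last edge (or
    below the first) fall outside and are not counted."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise NumericError("bin edges must be strictly increasing with >= 2 entries")
    v = np.asarray(volumes_um3, dtype=np.float64)
    idx = np.searchsorted(edges, v, side="right") - 1
    inside = (idx >= 0) & (idx < len(edges) - 1) & (v < edges[-1])
    return np.bincount(idx[inside], minlength=len(edges) - 1)


@dataclass
class SampleSummary:
    """Per-sample analog of the published count and morphometry tables."""

    sample_id: str
    analyzed_volume_mm3: float
    counts: dict[str, int]
    concentrations_per_mm3: dict[str, float]
    n_morphometry: int
    volume_mean_um3: float
    volume_sd_um3: float
    ar_mean: float
    ar_sd: float
    morpho_window: str = "20-2000"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "analyzed_volume_mm3": self.analyzed_volume_mm3,
            "counts": dict(self.counts),
            "concentrations_per_mm3": dict(self.concentrations_per_mm3),
            "n_morphometry": self.n_morphometry,
            "volume_mean_um3": self.volume_mean_um3,
            "volume_sd_um3": self.volume_sd_um3,
            "ar_mean": self.ar_mean,
            "ar_sd": self.ar_sd,
            "morpho_window": self.morpho_window,
        }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator); NaN where undefined."""
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def summarize(
    sample_id: str,
    records: Sequence[LacunaRecord],
    analyzed_volume_mm3: float,
    windows: Iterable = (COUNT_WINDOW, MORPHO_WINDOW),
    morpho_window=MORPHO_WINDOW,
    all_volumes_um3=None,
) -> SampleSummary:
    """Counts and concentrations per window plus volume/AR statistics.

    Counts are taken over ``all_volumes_um3`` (every label's volume, e.g.
    straight from the label map) when given, so that window counting does
    not depend on which labels received full morphometry; otherwise over
    the records.  Volume/AR means +/- sample SD are computed on records
    inside ``morpho_window``.
    """
    if not analyzed_volume_mm3 > 0:
        raise NumericError(f"analyzed volume must be positive, got {analyzed_volume_mm3}")
    windows = [as_window(w) for w in windows]
    morpho_window = as_window(morpho_window)

    if all_volumes_um3 is None:
        all_volumes = np.array([r.volume_um3 for r in records], dtype=np.float64)
    else:
        all_volumes = np.asarray(all_volumes_um3, dtype=np.float64)

    counts = {w.key: int(w.contains(all_volumes).sum()) for w in windows}
    concs = {k: concentration(c, analyzed_volume_mm3) for k, c in counts.items()}

    morpho = filter_by_volume(records, morpho_window)
    vols = np.array([r.volume_um3 for r in morpho], dtype=np.float64)
    ars = np.array([r.aspect_ratio for r in morpho], dtype=np.float64)
    vmean, vsd = _mean_sd(vols)
    armean, arsd = _mean_sd(ars)

    return SampleSummary(
        sample_id=sample_id,
        analyzed_volume_mm3=float(analyzed_volume_mm3),
        counts=counts,
        concentrations_per_mm3=concs,
        n_morphometry=len(morpho),
        volume_mean_um3=vmean,
        volume_sd_um3=vsd,
        ar_mean=armean,
        ar_sd=arsd,
        morpho_window=morpho_window.key,
    )


def fold_change(
    group_a: Sequence[SampleSummary], group_b: Sequence[SampleSummary], window
) -> float:
    """Mean concentration of group A over mean concentration of group B."""
    window = as_window(window)
    if not group_a or not group_b:
        raise NumericError("fold change needs at least one summary per group")
    try:
        a = np.mean([s.concentrations_per_mm3[window.key] for s in group_a])
        b = np.mean([s.concentrations_per_mm3[window.key] for s in group_b])
    except KeyError as exc:
        raise NumericError(f"window {window.key} missing from a summary") from exc
    if b == 0:
        raise NumericError("zero denominator in fold change")
    return float(a / b)
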