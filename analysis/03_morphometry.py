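#!/usr/bin/env python
"""Morphometric table and volume histograms for the simulated cohort.

From the per-run record CSVs written by 02_count_lacunae.py, tabulates mean
+/- SD lacuna volume and aspect ratio psi_A on the 20-2000 um^3 window (the
analog of a per-sample morphometry table) and bins the volume distribution
from 20 to 1200 um^3 — the range where the right-skewed shape of the
distribution is visible.

Writes results/morphometry_by_sample.csv and results/volume_histograms.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lacuna3d import volume_histogram

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
EDGES = np.linspace(20, 1200, 31)


def main():
    manifest_path = ROOT / "scratch" / "phantoms" / "manifest.json"
    if not manifest_path.exists():
        raise SystemExit("run analysis/01 and analysis/02 first")
    manifest = json.loads(manifest_path.read_text())

    rows, hist_rows = [], []
    for entry in manifest:
        sample = entry["sample_id"]
        rec_path = ROOT / "scratch" / "runs" / sample / "records.csv"
        if not rec_path.exists():
            raise SystemExit(f"missing {rec_path}; run analysis/02 first")
        rec = pd.read_csv(rec_path)
        morpho = rec[(rec.volume_um3 >= 20) & (rec.volume_um3 <= 2000)]
        rows.append({
            "sample": sample,
            "n_labels": len(morpho),
            "avg_vol_um3": round(morpho.volume_um3.mean(), 1),
            "vol_sd_um3": round(morpho.volume_um3.std(ddof=1), 1),
            "avg_ar": round(morpho.aspect_ratio.mean(), 3),
            "ar_sd": round(morpho.aspect_ratio.std(ddof=1), 3),
        })
        counts = volume_histogram(morpho.volume_um3.to_numpy(), EDGES)
        for lo, hi, c in zip(EDGES[:-1], EDGES[1:], counts):
            hist_rows.append({"sample": sample, "bin_low_um3": lo,
                              "bin_high_um3": hi, "count": int(c)})

    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "morphometry_by_sample.csv", index=False)
    pd.DataFrame(hist_rows).to_csv(RESULTS / "volume_histograms.csv", index=False)
    print(df.to_string(index=False))
    print(f"\n-> {RESULTS / 'morphometry_by_sample.csv'}")
    print(f"-> {RESULTS / 'volume_histograms.csv'}")


if __name__ == "__main__":
    main()
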