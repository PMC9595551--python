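#!/usr/bin/env python
"""Generate the eight-sample phantom cohort: two replicates each of the
inner-petrous (ip), outer-petrous (op), mastoid (t) and femur (f) presets,
mimicking a study design of duplicate micro-CT scans per bone type.

Volumes and truth rosters land under scratch/phantoms/ (regenerated on
demand; not a deliverable), plus a manifest the downstream scripts read.
The mastoid replicates are degraded (blur + noise) to emulate the poorer
image quality of plastic-embedded scans, with a fixed shared threshold used
downstream for them.
"""

import json
from pathlib import Path

from lacuna3d import make_phantom, preset_params, write_volume

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "phantoms"

SHAPE = (150, 150, 150)
SPACING = (0.9, 0.9, 0.9)
COHORT = [  # (sample_id, preset, seed, blur_um, noise_sd)
    ("IP_a", "ip", 11, 0.0, 0.0),
    ("IP_b", "ip", 12, 0.0, 0.0),
    ("OP_a", "op", 21, 0.0, 0.0),
    ("OP_b", "op", 22, 0.0, 0.0),
    ("T_a", "t", 31, 0.9, 4.0),
    ("T_b", "t", 32, 0.9, 4.0),
    ("F_a", "f", 41, 0.0, 0.0),
    ("F_b", "f", 42, 0.0, 0.0),
]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sample_id, preset, seed, blur, noise in COHORT:
        params = preset_params(preset, shape=SHAPE, spacing=SPACING, seed=seed,
                               blur_sigma_um=blur, noise_sd=noise, name=sample_id)
        grid, _, truth = make_phantom(params)
        vol_path = OUT / f"{sample_id}.tif"
        write_volume(grid, vol_path)
        truth.to_frame().to_csv(OUT / f"{sample_id}_truth.csv", index=False)
        manifest.append({
            "sample_id": sample_id, "preset": preset, "seed": seed,
            "blur_sigma_um": blur, "noise_sd": noise,
            "volume": str(vol_path), "spacing_um": list(SPACING),
            "planted_lacunae": len(truth.lacunae),
            "planted_concentration_per_mm3": truth.planted_concentration_per_mm3,
        })
        print(f"{sample_id}: planted {len(truth.lacunae)} lacunae "
              f"({truth.planted_concentration_per_mm3:,.0f}/mm^3), "
              f"{len(truth.canals)} canals -> {vol_path.name}")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"manifest -> {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
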