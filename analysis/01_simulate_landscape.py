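#!/usr/bin/env python
"""Generate the default synthetic landscape bundle and summarise it.

Writes the raster bundle under scratch/landscape/ (rasters are bulky) and prints the headline
properties of the generated study system (domain, clipping accounting,
disturbance extent, land-cover composition).
"""

from pathlib import Path

import numpy as np

from borealtrend import io as btio
from borealtrend.landscape import LandscapeConfig, generate_landscape
from borealtrend.sampling import LANDCOVER_CODES

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "landscape"


def main() -> None:
    cfg = LandscapeConfig(seed=SEED)
    bundle = generate_landscape(cfg)
    btio.write_bundle(bundle, OUT)

    ny, nx = bundle.landcover.shape
    print(f"domain: {cfg.lon_min}..{cfg.lon_max} E x {cfg.lat_min}..{cfg.lat_max} N "
          f"at {cfg.resolution} deg ({ny} x {nx} pixels, "
          f"{bundle.cover.shape[0]} years)")
    print(f"cover clip accounting: {bundle.clip_fraction:.4%} of values clipped")
    disturbed = float((bundle.dist_type.values > 0).mean())
    print(f"disturbed area: {disturbed:.1%} of pixels "
          f"({len(bundle.truth.disturbances)} patches, years "
          f"{bundle.truth.disturbances['year'].min()}-{bundle.truth.disturbances['year'].max()})")
    codes, counts = np.unique(bundle.landcover.values, return_counts=True)
    comp = ", ".join(f"{LANDCOVER_CODES[int(c)]} {n / counts.sum():.1%}"
                     for c, n in zip(codes, counts))
    print(f"land cover: {comp}")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main()
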