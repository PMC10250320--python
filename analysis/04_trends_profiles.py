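#!/usr/bin/env python
"""Profile summaries: binned SBD running means, zonal/stratum statistics,
the coarse trend map and the range-shrinkage metric.

Reads results/plot_table.csv and the landscape bundle; writes
results/binned_profile.csv, results/zone_stats.csv,
results/disturbance_stats.csv, results/treed_fraction.csv and
scratch/trend_map.tif (rasters are bulky), and prints the headline
zonal numbers.
"""

from pathlib import Path

import numpy as np

from borealtrend import io as btio
from borealtrend.pipeline import pixel_trend_raster
from borealtrend.profiles import coarse_trend_map
from borealtrend.profiles import (binned_running_mean, range_shrinkage_metric,
                                  stratified_stats)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = btio.read_table(ROOT / "plot_table.csv")
    bundle = btio.read_bundle(ROOT.parent / "scratch" / "landscape")

    prof = binned_running_mean(table, "slope_abs")
    btio.write_table(ROOT / "binned_profile.csv", prof.to_frame())

    zones = stratified_stats(table, ["zone"])
    btio.write_table(ROOT / "zone_stats.csv", zones)
    dist = stratified_stats(table, ["disturbance_category"])
    btio.write_table(ROOT / "disturbance_stats.csv", dist)

    valid = table["slope_abs"].notna()
    print(f"biome-wide trend: {table.loc[valid, 'slope_abs'].mean():+.3f} "
          f"+/- {table.loc[valid, 'slope_abs'].std(ddof=1):.3f} %/yr "
          f"(n = {int(valid.sum())})")
    for _, row in zones.iterrows():
        print(f"  {row['zone']:18s} {row['mean']:+.3f} +/- {row['sd']:.3f} %/yr "
              f"(n = {row['n']})")

    shrink = range_shrinkage_metric(table, ("cover_first_epoch", "cover_last_epoch"))
    btio.write_table(ROOT / "treed_fraction.csv", shrink.treed_fraction)
    print(f"treed-belt SBD span: {shrink.span[0]:.3f} -> {shrink.span[1]:.3f} "
          f"(shrinkage {shrink.shrinkage:+.3f} sbd units; southern edge "
          f"{shrink.south_edge[0]:+.3f} -> {shrink.south_edge[1]:+.3f})")

    trend_map = coarse_trend_map(pixel_trend_raster(bundle.cover), 4)
    btio.write_geotiff(ROOT.parent / "scratch" / "trend_map.tif", trend_map, nodata=-9999.0)
    print(f"coarse trend map written ({trend_map.shape[0]} x {trend_map.shape[1]} cells; "
          f"grand mean {float(np.nanmean(trend_map.values)):+.4f} %/yr)")


if __name__ == "__main__":
    main()
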