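#!/usr/bin/env python
"""Stage 3 — deduct the environmental baseline from the hair values.

Kriges the soil baseline at each sett's exact coordinates (the model route),
deducts it from the hair d13C/d15N values, estimates trophic position,
collapses repeated samples to genotyped individuals, and attaches the 14-day
pre-sampling weather means with their two principal components (PC1
"Temperature", PC2 "Climate"). Writes results/corrected.csv and
results/individual.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from isobase.correction import (aggregate_by_individual, attach_weather,
                                correct_table, extract_baseline)
from isobase.isoscape import dedupe_samples, empirical_semivariogram, fit_variogram
from isobase.pipeline import read_tables, write_tables
from isobase.stats import pca_weather


def main() -> None:
    tables = read_tables(soil_path="results/data/soil.csv",
                         hair_path="results/data/hair.csv",
                         weather_path="results/data/weather.csv")
    soil = dedupe_samples(tables["soil"])
    hair, weather = tables["hair"], tables["weather"]
    coords = hair[["x", "y"]].to_numpy(float)
    bases = {}
    for iso in ("d13C", "d15N"):
        model = fit_variogram(empirical_semivariogram(soil, iso)).model
        bases[iso] = extract_baseline(model, coords, soil, iso)
    corrected = correct_table(hair, bases["d13C"].values, bases["d15N"].values,
                              base_variance_d13C=bases["d13C"].kriging_variance,
                              base_variance_d15N=bases["d15N"].kriging_variance)
    corrected = attach_weather(corrected, weather)
    wcols = [c for c in corrected.columns if c.startswith("w14_")]
    comps = pca_weather(corrected[wcols])
    corrected["PC1"] = comps.pc1
    corrected["PC2"] = comps.pc2
    print("weather PCA variance explained:",
          [round(float(v), 2) for v in comps.variance_explained])
    indiv = aggregate_by_individual(corrected)
    write_tables({"corrected": corrected, "individual": indiv}, "results")
    print(f"corrected {len(corrected)} hair rows; {len(indiv)} individuals")
    print("per-class mean trophic position (corrected d15N):")
    print(corrected.groupby("land_class")["trophic_position"].mean().round(2).to_string())


if __name__ == "__main__":
    main()
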