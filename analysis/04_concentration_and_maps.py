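"""Regional concentration of lines and model-minus-data difference maps.

Computes the share of detected lines concentrated in the 'south' region
tag (the sixteen destinations nearest the origin) for both years, refits
the best retail spec from the ranking, and exports a difference GeoJSON
(positive = model overestimates) on synthetic square boundaries built
around each territory centroid.
"""

import json
from pathlib import Path

import pandas as pd

from countylines.data_model import load_study
from countylines.estimation import ModelSpec, fit_model
from countylines.evaluation import concentration_share, difference_map

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def synthetic_boundaries(study, half_km: float = 20.0) -> dict:
    """Synthetic square cells around territory centroids (a stand-in for
    real administrative boundaries, for attribute export only)."""
    features = []
    for t in study.territories:
        x, y = t.lon, t.lat
        ring = [[x - half_km, y - half_km], [x + half_km, y - half_km],
                [x + half_km, y + half_km], [x - half_km, y + half_km],
                [x - half_km, y - half_km]]
        features.append({
            "type": "Feature",
            "properties": {"id": t.id, "name": t.name, "region_tag": t.region_tag},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": features}


def main() -> None:
    study = load_study(DATA)
    south = [t.id for t in study.territories if t.region_tag == "south"]
    print(f"'south' region: {len(south)} of {len(study.destination_ids)} destinations")
    for year in sorted(study.lines):
        share = concentration_share(study.lines[year], south)
        print(f"  {year}: {100 * share:.2f}% of lines fall in the south set")

    ranking = pd.read_csv(OUT / "ranking.csv")
    best = ranking.iloc[0]
    covs = tuple(best["covariates"].split("+")) if isinstance(best["covariates"], str) and best["covariates"] else ()
    spec = ModelSpec(best["family"], covs, best["loss"], str(best["train_year"]))
    fit = fit_model(spec, study)

    boundaries = synthetic_boundaries(study)
    for year in sorted(study.lines):
        annotated = difference_map(study.lines[year], fit.predictions[year], boundaries)
        path = OUT / f"difference_{year}.geojson"
        path.write_text(json.dumps(annotated))
        diffs = [f["properties"]["difference"] for f in annotated["features"]
                 if "difference" in f["properties"]]
        over = sum(d > 0 for d in diffs)
        print(f"wrote {path}: {over}/{len(diffs)} territories overestimated by the model")


if __name__ == "__main__":
    main()
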