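"""Calibrate one model per family on the 2019 fold and inspect parameters.

Fits the gravity model, the radiation model and the retail model with the
two ground-truth covariates (misuse admissions, knife crime) using the
Poissonian loss on the 2019 counts, then compares the fitted retail
parameters with the generating truth. Writes results/analysis/fits.json.
"""

import json
from pathlib import Path

from countylines.data_model import load_study
from countylines.estimation import ModelSpec, fit_model
from countylines.evaluation import sorensen_dice

DATA = Path("results/analysis/data")
OUT = Path("results/analysis/fits.json")

SPECS = [
    ModelSpec("gravity", (), "poisson", "2019"),
    ModelSpec("radiation", (), "poisson", "2019"),
    ModelSpec("retail", ("knife_crimes", "misuse_admissions"), "poisson", "2019"),
]


def main() -> None:
    study = load_study(DATA)
    truth = json.loads((DATA / "truth.json").read_text())["params"]
    payload = {}
    for spec in SPECS:
        fit = fit_model(spec, study)
        s_val = sorensen_dice(study.lines["2020"], fit.predictions["2020"])
        payload[spec.spec_id] = {
            "theta_hat": fit.theta_hat,
            "train_loss": fit.train_loss,
            "validation_S_2020": s_val,
            "converged": fit.converged,
        }
        print(f"{spec.spec_id}")
        print(f"  theta: {{{', '.join(f'{k}={v:.4g}' for k, v in fit.theta_hat.items())}}}")
        print(f"  validation S (2020): {s_val:.4f}")
    retail = payload[SPECS[2].spec_id]["theta_hat"]
    print("retail recovery vs truth:")
    for name, hat in retail.items():
        true = truth.get(name)
        if true is not None:
            print(f"  {name}: fitted {hat:.4g}, truth {true:.4g} "
                  f"({100 * (hat - true) / true:+.1f}%)")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(payload, indent=2, sort_keys=True))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
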