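"""Motility velocity distributions: untreated versus compound-treated motor,
Gaussian-fitted mean sliding velocities and motile fractions.

Writes: results/motility.csv
"""

from pathlib import Path

import pandas as pd

from myokin import analyze_velocities
from myokin import reference as ref
from myokin.synthetic import SyntheticSpec, derive_seed, gen_velocity_sample

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1


def main() -> None:
    rows = []
    for cond, p in ref.MOTILITY.items():
        spec = SyntheticSpec(
            "velocity_sample",
            {"mean": p["mean"], "sd": p["sd"], "n": 300, "motile_fraction": p["motile_fraction"]},
            (0.0,),
            noise_sd=0.0,
            seed=derive_seed(SEED, f"motility_{cond}"),
        )
        res = analyze_velocities(gen_velocity_sample(spec).y)
        rows.append({"condition": cond, "mean_um_s": res.mean, "sd_um_s": res.sd,
                     "motile_fraction": res.motile_fraction,
                     "printed_mean": p["mean"], "n_filaments": res.n})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "motility.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print("\nsliding velocity increases ~1.6-fold and the motile fraction "
          "rises above 95% with the compound")


if __name__ == "__main__":
    main()
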