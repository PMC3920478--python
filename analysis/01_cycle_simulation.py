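"""Simulate the actomyosin ATPase cycle for the control and compound-treated
conditions and compare the network's steady-state turnover with the
series-of-steps closed form and the measured steady-state constants.

Writes: results/cycle_trajectory_{control,emd}.csv,
        results/actin_activation_model.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from myokin import reference as ref
from myokin.kinetic_model import series_of_steps_rate, simulate_cycle, steady_state_rate

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    conds = {"control": ref.control_rates(), "emd": ref.emd_rates()}
    rows = []
    for name, rates in conds.items():
        traj = simulate_cycle(rates, 1000.0, 50.0, np.linspace(0, 200, 400))
        traj.to_csv(OUT / f"cycle_trajectory_{name}.csv")
        closed = series_of_steps_rate([rates.k2, rates.k_hyd, rates.k4, rates.kAD])
        sat = steady_state_rate(rates, 1e5, 1e5)
        basal = steady_state_rate(rates, 1e5, 0.0)
        print(
            f"{name}: saturating flux {sat:.4f} /s, series-of-steps {closed:.4f} /s, "
            f"basal {basal:.4f} /s"
        )
        for actin in np.linspace(0, 100, 21):
            rows.append(
                {
                    "condition": name,
                    "actin_uM": actin,
                    "rate_per_s": steady_state_rate(rates, 1000.0, float(actin)),
                }
            )
    pd.DataFrame(rows).to_csv(OUT / "actin_activation_model.csv", index=False)
    print(f"model activation curves written to {OUT/'actin_activation_model.csv'}")
    print(
        "note: flux arithmetic from the microscopic constants gives ~0.086 /s at "
        "saturation, below the fitted kcat of 0.12 /s — both values are retained."
    )


if __name__ == "__main__":
    main()
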