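"""Forward behaviour of the relocation-sensor compartment model.

Simulates the nuclear-to-cytoplasmic ratio for step increases of kinase
activity of different amplitudes, tabulates the steady-state calibration
curve (activity vs ratio), and measures how fast the sensor returns to its
basal enrichment after complete kinase shutoff (the inhibitor experiment).

Writes results/model/step_responses.csv, calibration.csv, recovery.csv
and a summary figure; prints the headline numbers.

Usage: python analysis/01_model_forward.py [--out results/model]
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from skars.model import (
    ActivityProfile,
    SensorModelParams,
    build_calibration,
    simulate_relocation,
    steady_state,
    steady_state_ratio,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results/model"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params = SensorModelParams()
    times = np.arange(0.0, 31.0, 0.25)

    # step responses: activity rises from the 0.2 baseline to various plateaus
    step = {}
    for amax in (0.2, 0.4, 0.6, 0.8, 1.0):
        profile = ActivityProfile(a0=0.2, amax=amax, t_on=5.0, tau_rise=1.0)
        step[f"amax_{amax:.1f}"] = simulate_relocation(params, profile, times)
    steps = pd.DataFrame({"time_min": times, **step})
    steps.to_csv(args.out / "step_responses.csv", index=False)

    curve = build_calibration(params)
    pd.DataFrame({"activity": curve.activities, "ratio": curve.ratios}).to_csv(
        args.out / "calibration.csv", index=False
    )

    # recovery after complete kinase shutoff, starting fully relocated
    recovery = simulate_relocation(
        params, ActivityProfile(a0=0.0, amax=0.0), times, initial=steady_state(params, 1.0)
    )
    pd.DataFrame({"time_min": times, "ratio": recovery}).to_csv(
        args.out / "recovery.csv", index=False
    )
    basal = steady_state_ratio(params, 0.0)
    frac = (recovery - recovery[0]) / (basal - recovery[0])
    t90 = times[np.argmax(frac >= 0.9)]

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for name, trace in step.items():
        axes[0].plot(times, trace, label=name.replace("amax_", "plateau "))
    axes[0].set(xlabel="time (min)", ylabel="nucl/cyto ratio [-]", title="step responses")
    axes[0].legend(fontsize=7)
    axes[1].plot(curve.activities, curve.ratios, "o-")
    axes[1].set(xlabel="kinase activity", ylabel="steady-state ratio [-]", title="calibration")
    axes[2].plot(times, recovery)
    axes[2].axvline(t90, ls="--", c="grey")
    axes[2].set(xlabel="time (min)", ylabel="ratio [-]", title="recovery after shutoff")
    fig.tight_layout()
    fig.savefig(args.out / "model_forward.png", dpi=150)

    print(f"basal enrichment at zero activity: {basal:.3f}")
    print(f"ratio at full activity: {steady_state_ratio(params, 1.0):.3f}")
    print(f"90% recovery after shutoff: {t90:.1f} min")
    print(f"outputs in {args.out}/")


if __name__ == "__main__":
    main()
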