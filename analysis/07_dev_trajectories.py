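"""Developmental expression trajectories of module hub genes.

Normalizes the age-indexed expression series with the two-stage compound
z-score, averages the 50 hub genes of each module per age, fits the GCV
smoothing spline, writes the trajectory tables and a summary figure, and
reports which planted temporal shape each module shows.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from studyconf import DATA_DIR, OUT_DIR

from brainmod import io
from brainmod.dev import compound_zscore, hub_trajectory
from brainmod.synth import BIRTH_DAYS, age_to_days


def classify(tr) -> str:
    """Coarse label for the smoothed trajectory.

    The compound z-score centres every array, so modules with no planted
    shape show a small dip mirroring the shaped modules; the flat threshold
    allows for that.
    """
    v = tr.smooth_values
    peak = tr.smooth_ages[np.argmax(v)]
    if np.ptp(v) < 0.5:
        return "flat"
    if v[-1] >= v.max() - 0.15 * np.ptp(v) and v[-1] > v[0] + 0.3:
        return "increasing into adulthood"
    if BIRTH_DAYS <= peak <= age_to_days(2, "yrs"):
        return "peaked in infancy"
    return "other"


def main() -> None:
    dev = io.read_expression(DATA_DIR / "dev_expression.tsv")
    meta = pd.read_csv(DATA_DIR / "dev_arrays.tsv", sep="\t", index_col=0)
    hubs = io.read_gmt(OUT_DIR / "module_hubs.gmt")

    z = compound_zscore(dev)
    fig, axes = plt.subplots(1, len(hubs) + 1, figsize=(4 * (len(hubs) + 1), 3.2),
                             sharey=True)
    frames = []
    for ax, (name, genes) in zip(axes, sorted(hubs.items())):
        tr = hub_trajectory(z, meta, genes)
        kind = classify(tr)
        df = tr.to_frame()
        df["module"] = name
        frames.append(df)
        ax.plot(tr.ages_days, tr.mean_score, "o", ms=3)
        ax.plot(tr.smooth_ages, tr.smooth_values, "--")
        ax.axvline(BIRTH_DAYS, color="grey", lw=0.5)
        ax.set_xscale("log")
        ax.set_title(f"{name}\n{kind}", fontsize=9)
        ax.set_xlabel("age (days post conception)")
        peak_y = tr.smooth_ages[np.argmax(tr.smooth_values)] / 365.25
        print(
            f"{name}: {kind} (hub n = {len(genes)}, range {np.ptp(tr.smooth_values):.2f}, "
            f"peak at {peak_y:.1f} y post conception)"
        )

    whole = hub_trajectory(z, meta, list(z.index))
    axes[-1].plot(whole.ages_days, whole.mean_score, "o", ms=3)
    axes[-1].plot(whole.smooth_ages, whole.smooth_values, "--")
    axes[-1].set_xscale("log")
    axes[-1].set_title("all genes\n" + classify(whole), fontsize=9)
    print(f"all genes: {classify(whole)}")

    pd.concat(frames).to_csv(OUT_DIR / "dev_trajectories.tsv", sep="\t", index=False)
    fig.tight_layout()
    fig.savefig(OUT_DIR / "dev_trajectories.png", dpi=120)


if __name__ == "__main__":
    main()
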