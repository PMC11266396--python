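"""Figures: per-individual event rasters, group activity and the average day.

Reads the tables written by the previous steps and renders three summary
figures (PNG) — a per-module event heat strip for two contrasting
individuals, the smoothed group activity over the experiment, and the
average-day profile with its light regime.
"""

import argparse
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import beambreak as bb


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--log-dir", default="scratch/logs")
    ap.add_argument("--results-dir", default="results")
    ap.add_argument("--out-dir", default="results/figures")
    args = ap.parse_args()

    config = bb.load_config(os.path.join(args.log_dir, "experiment.yaml"))
    events = pd.read_csv(os.path.join(args.results_dir, "event_series.csv"),
                         parse_dates=["bin_start"])
    group = pd.read_csv(os.path.join(args.results_dir, "group_activity.csv"),
                        parse_dates=["bin_start"])
    avg = pd.read_csv(os.path.join(args.results_dir, "average_day.csv"))
    os.makedirs(args.out_dir, exist_ok=True)

    # two contrasting individuals: most surface-attracted vs most depth-seeking
    gains = {i.column_id: i.agent.phototaxis_gain for i in config.individuals}
    cols = [c for c in events["column_id"].unique()]
    pos = max(cols, key=lambda c: gains[c])
    neg = min(cols, key=lambda c: gains[c])
    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    for ax, col in zip(axes, (pos, neg)):
        sub = events[events["column_id"] == col]
        mat = sub.pivot(index="module", columns="bin_start", values="smoothed")
        ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis",
                  interpolation="nearest")
        ax.set_yticks(range(5), [f"p{m}" for m in mat.index])
        ax.set_title(f"{col} (phototaxis gain {gains[col]:+.1f})")
    axes[-1].set_xlabel("10-min bin")
    fig.tight_layout()
    fig.savefig(os.path.join(args.out_dir, "event_heatmaps.png"), dpi=120)

    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(group["bin_start"], group["mean"], lw=0.8, color="k")
    ax.fill_between(group["bin_start"], group["mean"] - group["sem"],
                    group["mean"] + group["sem"], alpha=0.3, color="k")
    ax.set_ylabel("normalized activity")
    ax.set_title("group mean upward-swimming activity")
    fig.tight_layout()
    fig.savefig(os.path.join(args.out_dir, "group_activity.png"), dpi=120)

    fig, ax = plt.subplots(figsize=(7, 3.2))
    hours = avg["minute_of_day"] / 60.0
    ax.plot(hours, avg["mean"], color="k")
    ax.fill_between(hours, avg["mean"] - avg["sem"], avg["mean"] + avg["sem"],
                    alpha=0.3, color="k")
    light = bb.light_intensity(config.regime, hours.to_numpy())
    ax.fill_between(hours, 0, (light > 0) * avg["mean"].max() * 0.05,
                    color="gold", alpha=0.6, label="lights on")
    ax.set_xlabel("local time (h)")
    ax.set_ylabel("normalized activity")
    ax.set_title("average day (mean +/- s.e.m.)")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(os.path.join(args.out_dir, "average_day.png"), dpi=120)
    print(f"wrote 3 figures to {args.out_dir}")


if __name__ == "__main__":
    main()
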