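"""Optional static plots of simulation and analysis outputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .engine import OUTPUT_COLUMNS

_COLORS = {
    "prop_ltpa": "tab:red",
    "prop_low": "tab:blue",
    "prop_mid": "tab:green",
    "prop_high": "black",
}
_LABELS = {
    "prop_ltpa": "practicing LTPA",
    "prop_low": "low intention",
    "prop_mid": "intermediate intention",
    "prop_high": "high intention",
}


def plot_timeseries(df: pd.DataFrame, path: str | Path, stride: int = 52) -> None:
    """Yearly replicate-mean trajectories of the four population outputs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    yearly = df[df["week"] % stride == 0]
    mean = yearly.groupby("week")[OUTPUT_COLUMNS].mean()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in OUTPUT_COLUMNS:
        ax.plot(mean.index / stride, mean[col], color=_COLORS[col],
                label=_LABELS[col])
    ax.set_xlabel("year")
    ax.set_ylabel("proportion of the population")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_consistency(table: pd.DataFrame, path: str | Path,
                     week: int | None = None) -> None:
    """Median and maximum folded A scores versus replication count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if week is None:
        week = int(table["week"].max())
    sub = table[table["week"] == week]
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for stat, ax in zip(("median_A", "max_A"), axes):
        for out in OUTPUT_COLUMNS:
            line = sub[sub["output"] == out].sort_values("m")
            ax.plot(line["m"], line[stat], marker="o", color=_COLORS[out],
                    label=_LABELS[out])
        ax.axhline(0.56, ls="--", lw=0.8, color="gray")
        ax.set_ylabel(stat.replace("_", " "))
        ax.set_ylim(0.45, 1.02)
    axes[0].legend(frameon=False, fontsize=9)
    axes[1].set_xlabel("replications per set (m)")
    fig.suptitle(f"A-test consistency at week {week}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
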