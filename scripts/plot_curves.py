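#!/usr/bin/env python
"""Plot sequestration-flux curves (log residence-time axis).

Reads the CSV files written by `oceancp seqcurve` (or
SequestrationCurve.to_csv) and renders per-pool and total fluxes for
carbon and phosphorus plus the molar C:P ratio of the totals.

Usage:
    python scripts/plot_curves.py seqflux_C.csv seqflux_P.csv -o curves.png
"""

from __future__ import annotations

import argparse

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

MOLAR_MASS = {"C": 12.011, "P": 30.974}


def plot_curve(ax, df: pd.DataFrame, element: str) -> None:
    t = df["t_years"].values
    for col in df.columns:
        if col in ("t_years", "total"):
            continue
        ax.plot(t, df[col], label=col, lw=1.2)
    ax.plot(t, df["total"], "k-", label="total", lw=2)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("residence time horizon t [y]")
    ax.set_ylabel(f"$\\Phi_{{\\tau \\geq t}}$ [Pg {element} y$^{{-1}}$]")
    ax.legend(fontsize=8)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("carbon_csv")
    ap.add_argument("phosphorus_csv")
    ap.add_argument("-o", "--out", default="seqflux_curves.png")
    args = ap.parse_args()

    dfc = pd.read_csv(args.carbon_csv)
    dfp = pd.read_csv(args.phosphorus_csv)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    plot_curve(axes[0], dfc, "C")
    axes[0].set_title("carbon")
    plot_curve(axes[1], dfp, "P")
    axes[1].set_title("phosphorus")

    t = dfc["t_years"].values
    ratio = (dfc["total"] / MOLAR_MASS["C"]) / (dfp["total"] / MOLAR_MASS["P"])
    axes[2].plot(t, ratio, "k-")
    axes[2].axhline(106.0, color="grey", ls=":", label="Redfield 106:1")
    axes[2].set_xscale("log")
    axes[2].set_xlabel("residence time horizon t [y]")
    axes[2].set_ylabel("molar C:P of total flux")
    axes[2].set_title("sequestration stoichiometry")
    axes[2].legend(fontsize=8)
    # the t=0 point cannot sit on a log axis; start at the first positive t
    for ax in axes:
        ax.set_xlim(left=max(t[t > 0].min(), 1e-3))
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
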