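"""Optional plotting helpers that read the experiment CSVs.

Kept deliberately thin: experiments emit data, not figures.  Requires
matplotlib (``pip install decoysim[plot]``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _axes():
    import matplotlib.pyplot as plt
    return plt.subplots()


def plot_fano_vs_n(csv_path: str | Path, out_path: str | Path) -> None:
    """Fano factor of the free TF against decoy number, one line per k_d."""
    frame = pd.read_csv(csv_path)
    fig, ax = _axes()
    for k_d, group in frame.groupby("k_d"):
        ax.plot(group["N"], group["analytic_fano_xf"], label=f"$k_d$ = {k_d:g}")
    ax.set_xscale("log")
    ax.set_xlabel("decoy sites $N$")
    ax.set_ylabel("Fano factor of free TF")
    ax.legend()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")


def plot_autocorrelation(csv_path: str | Path, out_path: str | Path) -> None:
    """Autocorrelation curves per variant with the exponential reference."""
    frame = pd.read_csv(csv_path)
    fig, ax = _axes()
    for label, group in frame.groupby("variant"):
        ax.plot(group["tau"], group["R"], label=label)
    ref = frame.drop_duplicates("tau").sort_values("tau")
    ax.plot(ref["tau"], ref["exp_reference"], "k--",
            label=r"$e^{-\gamma_f \tau}$")
    ax.set_xlabel(r"lag $\tau$ (hr)")
    ax.set_ylabel(r"$R(\tau)$")
    ax.legend()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
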