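"""Summary plots for pipeline outputs (bar charts and response curves)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .quantify import BinnedResponse

__all__ = ["plot_rates", "plot_specificity", "plot_response"]


def plot_rates(rates: pd.DataFrame, path) -> None:
    """Absolute and relative co-introduction rate per region."""
    fig, ax = plt.subplots(figsize=(5, 3))
    x = range(len(rates))
    ax.bar([i - 0.2 for i in x], rates.absolute_co, width=0.4, label="absolute")
    ax.bar([i + 0.2 for i in x], rates.relative_co, width=0.4, label="relative")
    ax.set_xticks(list(x), rates.region, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("co-introduction rate")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_specificity(spec: pd.DataFrame, path) -> None:
    """Induction specificity S per condition (SD over regions where available)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    yerr = None
    if "sd_irradiated_um2" in spec and "mean_unirradiated_um2" in spec:
        yerr = spec.sd_irradiated_um2 / spec.mean_unirradiated_um2
        if not yerr.notna().all():
            yerr = None  # SD undefined with a single region per arm
    ax.bar(spec.condition.astype(str), spec.S, yerr=yerr, capsize=3, color="#777")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("irradiation condition")
    ax.set_ylabel("induction specificity S")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_response(responses: dict[str, BinnedResponse], path) -> None:
    """Binned stain-vs-reporter curves (mean ± SD band per sample)."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    for label, resp in responses.items():
        x, m, s = resp.bin_centers, resp.mean_stain, resp.sd_stain
        line, = ax.plot(x, m, marker="o", ms=3, label=label)
        ax.fill_between(x, m - s, m + s, alpha=0.2, color=line.get_color())
    ax.set_xlabel("reporter intensity (a.u.)")
    ax.set_ylabel("stain intensity (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
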