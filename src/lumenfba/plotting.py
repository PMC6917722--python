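"""Minimal plotting helpers (matplotlib); figure styling is not a goal."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import DoseResponse, ScreenResult  # noqa: E402

__all__ = ["plot_dose_response", "plot_screen_heatmap"]


def plot_dose_response(result: DoseResponse, ax=None):
    """Objective (and tracked fluxes) versus dose."""
    if ax is None:
        _, ax = plt.subplots()
    records = result.records
    ax.plot(records["dose"], records["objective"], marker="o", label="objective")
    for col in records.columns[3:]:
        ax.plot(records["dose"], records[col], linestyle="--", label=col)
    ax.set_xlabel("dose (g)")
    ax.set_ylabel("flux (mmol/gDW/h)")
    title = result.prebiotic + (" (control)" if result.control else "")
    ax.set_title(title)
    ax.legend(fontsize="small")
    return ax


def plot_screen_heatmap(result: ScreenResult, ax=None):
    """Maximum secretion flux per organism and metabolite."""
    if ax is None:
        _, ax = plt.subplots()
    cols = [c for c in result.summary.columns if c.startswith("max_")]
    data = result.summary.set_index("organism")[cols]
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cols)), [c[4:] for c in cols])
    ax.set_yticks(range(len(data)), data.index, fontsize="x-small")
    plt.colorbar(im, ax=ax, label="max secretion flux")
    return ax
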