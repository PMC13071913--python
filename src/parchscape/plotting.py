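"""Thin, optional rendering layer over the TSV plot-data exports.

Everything scientific lives in :mod:`parchscape.hydro_stats` and
:mod:`parchscape.pipeline`; these helpers only draw what those modules
computed.  Matplotlib is imported lazily so headless analysis never
touches it.
"""

from __future__ import annotations

from .hydro_stats import DensityEstimate, ViolinSummary

__all__ = ["plot_densities", "plot_violin_summaries"]


def plot_densities(densities: dict[str, DensityEstimate], ax=None):
    """Overlay labeled density curves; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, d in sorted(densities.items()):
        ax.plot(d.grid, d.density, label=name)
    ax.set_xlabel("PARCH value")
    ax.set_ylabel("probability density")
    ax.legend()
    return ax


def plot_violin_summaries(summaries: dict[str, ViolinSummary], ax=None):
    """Box-style rendering of five-number summaries; returns the Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = sorted(summaries)
    for i, name in enumerate(names):
        s = summaries[name]
        ax.vlines(i, s.min, s.max, color="0.6")
        ax.vlines(i, s.q1, s.q3, color="C0", lw=6)
        ax.plot(i, s.median, "k_", ms=12)
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_ylabel("PARCH value")
    return ax
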