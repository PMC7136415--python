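"""Plot helpers: periodogram traces and bout-length distributions."""

from __future__ import annotations

import numpy as np


def plot_periodogram(result, ax=None, hours: bool = True):
    """Q statistic vs period with the Bonferroni significance threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = result.periods_hours if hours else result.periods_bins
    ax.plot(x, result.q_stat, lw=0.8, label=r"$Q_P$")
    ax.plot(x, result.threshold, "k-", lw=1.0, label="threshold (Bonferroni 0.05)")
    ax.set_xlabel("period (h)" if hours else "period (bins)")
    ax.set_ylabel(r"$Q_P$")
    ax.set_title(f"chi-square periodogram ({result.range_label.lower()})")
    ax.legend(frameon=False)
    return ax


def plot_bout_distribution(table, ax=None):
    """Observed vs geometric-model bout-length distribution, log-x as usual."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if table.empty:
        ax.set_title("no qualifying bouts")
        return ax
    ax.plot(table.lengths, table.observed, "-", label="observed")
    ax.plot(table.lengths, table.predicted, "--", label="geometric model")
    ax.set_xscale("log")
    ax.set_xlabel("bout length (bins)")
    ax.set_ylabel("probability")
    state = "activity" if table.state == 1 else "rest"
    ax.set_title(f"{state} bouts (exit prob {table.exit_prob:.3f}, n={table.n_bouts})")
    ax.legend(frameon=False)
    return ax


def plot_split_half(split_results, ax=None):
    """Scatter of first- vs second-half estimates across a cohort."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, marker in (("alpha", "o"), ("beta", "s")):
        xs, ys = [], []
        for res in split_results:
            tab = res.table()
            sel = tab["param"] == name
            xs.extend(tab.loc[sel, "first_half"])
            ys.extend(tab.loc[sel, "second_half"])
        ax.plot(xs, ys, marker, ms=4, alpha=0.7, label=name)
    lim = ax.get_xlim()
    ax.plot(lim, lim, "k:", lw=0.8)
    ax.set_xlabel("first-half estimate")
    ax.set_ylabel("second-half estimate")
    ax.legend(frameon=False)
    return ax
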