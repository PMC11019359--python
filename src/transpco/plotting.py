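"""QQ and power-curve plotting helpers (requires matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["qq_plot", "power_curve"]


def qq_plot(pvalues, ax=None, label=None):
    """Observed vs expected -log10(p) under uniformity, with the identity line."""
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, 1.0))
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, obs, ".", ms=3, label=label)
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if label:
        ax.legend()
    return ax


def power_curve(tables, x_values, x_label, ax=None):
    """Power versus a swept parameter for each method, with 95% CI bars.

    ``tables`` is a sequence of PowerTable, one per x value.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    methods = list(tables[0].table["method"])
    for m in methods:
        y = [t.power(m) for t in tables]
        err = [1.96 * t.mc_se(m) for t in tables]
        ax.errorbar(x_values, y, yerr=err, marker="o", capsize=3, label=m)
    ax.set_xlabel(x_label)
    ax.set_ylabel("power")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
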