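"""Simple beta(l)-versus-lag curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .explore import SmoothLagFit


def plot_lag_fit(
    fit: SmoothLagFit, path: "str | Path", title: str = "", alpha: float = 0.05
) -> None:
    """Smoothed lag-coefficient curve with pointwise ~95% band."""
    t = fit.table
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.fill_between(
        t["lag"], t["beta"] - 1.96 * t["se"], t["beta"] + 1.96 * t["se"],
        alpha=0.25, label="pointwise 95% band",
    )
    ax.plot(t["lag"], t["beta"], marker="o", ms=3, lw=1.2, label="beta(l)")
    sig = t[t["p"] < alpha]
    if not sig.empty:
        ax.plot(sig["lag"], sig["beta"], "o", ms=5, color="crimson", label="p < alpha")
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("standardized coefficient")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
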