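"""Optional matplotlib figures for the conformation report."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def afactor_vs_lifetime(results: dict, path) -> None:
    """Scatter of per-sample A-factor vs lifetime for several conditions."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, res in results.items():
        ax.plot(res.lifetimes, res.sample_a_factors, "o--", label=label)
    ax.set_xscale("log")
    ax.set_xlabel("lifetime (ns)")
    ax.set_ylabel("fractional amplitude")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def percent_change_bars(changes: dict, path) -> None:
    """Paired bar chart of percentage changes in A-factors and lifetimes."""
    n = len(changes["A"])
    idx = range(1, n + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7, 3.2), sharey=False)
    ax1.bar([f"A{i}" for i in idx], changes["A"], color="tab:blue")
    ax1.set_ylabel("% change in A factor")
    ax2.bar([f"tau{i}" for i in idx], changes["tau"], color="tab:orange")
    ax2.set_ylabel("% change in lifetime")
    for ax in (ax1, ax2):
        ax.axhline(0.0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
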