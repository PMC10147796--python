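"""Bar-chart rendering of an activation report (group means + log ratios)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import ActivationReport

__all__ = ["plot_report"]


def plot_report(report: ActivationReport, path: str | Path | None = None):
    """Two panels: per-region group means, and log10(group/control) with
    stars marking comparisons significant at the report's alpha."""
    frame = report.frame
    regions = list(dict.fromkeys(frame["region"]))
    groups = list(dict.fromkeys(frame["group"]))
    x = range(len(regions))
    width = 0.8 / (len(groups) + 1)

    fig, (ax_mean, ax_ratio) = plt.subplots(2, 1, figsize=(12, 7), sharex=True)
    ctrl = frame.drop_duplicates("region").set_index("region")["mean_control"]
    ax_mean.bar([i - 0.4 for i in x], ctrl.reindex(regions), width,
                label=report.control_group, color="0.6")
    for gi, g in enumerate(groups):
        sub = frame[frame["group"] == g].set_index("region").reindex(regions)
        offs = -0.4 + (gi + 1) * width
        ax_mean.bar([i + offs for i in x], sub["mean"], width, label=g)
        bars = ax_ratio.bar([i + offs for i in x], sub["log10_ratio"], width,
                            label=g)
        for rect, sig in zip(bars, sub["significant"]):
            if bool(sig):
                y = rect.get_height()
                ax_ratio.annotate("*", (rect.get_x() + rect.get_width() / 2, y),
                                  ha="center",
                                  va="bottom" if y >= 0 else "top")
    ax_mean.set_ylabel("mean stained-area fraction")
    ax_mean.legend(fontsize=8, ncol=len(groups) + 1)
    ax_ratio.axhline(0, color="k", lw=0.5)
    ax_ratio.set_ylabel(f"log{report.log_base:g}(group / control)")
    ax_ratio.set_xticks(list(x), regions, rotation=60)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
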