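"""Optional matplotlib renderings of the analysis outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import PsaSample, TornadoEntry, ceac  # noqa: E402

__all__ = ["tornado_plot", "ce_plane_plot", "ceac_plot"]


def tornado_plot(
    entries: Sequence[TornadoEntry],
    base_icer: float,
    path: str | Path,
    max_bars: int = 12,
) -> None:
    """Horizontal tornado: ICER at each parameter's bounds vs the base."""
    shown = list(entries[:max_bars])[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="black", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane_plot(
    samples: Sequence[PsaSample], wtp: float, path: str | Path
) -> None:
    """Incremental cost vs incremental QALYs, with the WTP ray."""
    d_eff = np.array([s.delta_qalys for s in samples])
    d_cost = np.array([s.delta_cost for s in samples])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(d_eff, d_cost, s=8, alpha=0.4, edgecolors="none")
    span = np.array([min(0.0, d_eff.min()), max(0.0, d_eff.max())])
    ax.plot(span, wtp * span, color="crimson", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(
    samples: Sequence[PsaSample], wtp_grid, path: str | Path, wtp_marker: float | None = None
) -> None:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    wtp_grid = np.asarray(wtp_grid, float)
    prob = ceac(samples, wtp_grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(wtp_grid, prob)
    if wtp_marker is not None:
        ax.axvline(wtp_marker, color="crimson", lw=1, ls="--", label="WTP threshold")
        ax.legend(fontsize=8)
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
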