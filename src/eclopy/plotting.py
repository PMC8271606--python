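"""Presentation figures: marker traces, onset box plots, emergence histogram
with correlogram.  Purely cosmetic; no analysis happens here."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gating import GatingParams
from .rhythm import Correlogram, EventRecord, RhythmResult

__all__ = ["plot_trace", "plot_record", "plot_outputs"]


def _shade_subjective_days(ax, t_max: float, params: GatingParams) -> None:
    # gray = subjective night, white = subjective day; gates hatched
    t = 0.0
    while t < t_max:
        open_t = params.next_gate_open(t) if not params.in_gate(t) else t
        close_t = min(open_t + params.gate_width_h, t_max)
        if open_t < t_max:
            ax.axvspan(open_t, close_t, color="gold", alpha=0.15, lw=0)
        t = open_t + params.tau_h


def plot_trace(trace, onset_t=None, emergence_t=None, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    ax.plot(trace.t_h, trace.values, lw=0.8, color="navy")
    if onset_t is not None:
        ax.axvline(onset_t, color="green", ls="--", lw=1, label="onset")
    if emergence_t is not None:
        ax.axvline(emergence_t, color="red", ls=":", lw=1, label="emergence")
    ax.set_xlabel("time in DD (h)")
    ax.set_ylabel(trace.channel)
    ax.set_title(trace.animal_id)
    if onset_t is not None or emergence_t is not None:
        ax.legend(loc="upper left", fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_record(record: EventRecord, correlogram: Correlogram | None = None,
                result: RhythmResult | None = None,
                params: GatingParams | None = None, path=None):
    ncols = 2 if correlogram is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 2.8))
    axes = np.atleast_1d(axes)
    ax = axes[0]
    ax.bar(record.bin_start_t_h, record.counts, width=record.bin_h,
           align="edge", color="k")
    if params is not None:
        _shade_subjective_days(ax, record.span_h, params)
    ax.set_xlabel("time in DD (h)")
    ax.set_ylabel("flies / bin")
    if correlogram is not None:
        ax2 = axes[1]
        ax2.plot(correlogram.lags_h, correlogram.coefficients, lw=0.9, color="k")
        ax2.axhline(0, color="gray", lw=0.5)
        ax2.set_xlabel("lag (h)")
        ax2.set_ylabel("autocorrelation")
        if result is not None:
            label = f"RI = {result.ri:.2f}"
            if result.period_h is not None:
                label += f", p = {result.period_h:.1f} h"
            ax2.annotate(label, xy=(0.55, 0.85), xycoords="axes fraction",
                         fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def plot_outputs(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write standard figures for a pipeline result bundle; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for animal, entry in bundle.get("animals", {}).items():
        p = out_dir / f"trace_{animal}.png"
        plot_trace(entry["roughness_trace"], entry.get("onset_t_h"),
                   entry.get("emergence_t_h"), path=p)
        written.append(p)
    if "record" in bundle:
        p = out_dir / "record.png"
        plot_record(bundle["record"], bundle.get("correlogram"),
                    bundle.get("rhythm_result"), bundle.get("gating_params"),
                    path=p)
        written.append(p)
    return written
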