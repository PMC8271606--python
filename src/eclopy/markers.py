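"""Developmental markers extracted from stabilized image series.

Three per-frame channels track progress through the last day of
metamorphosis:

``wing_intensity``
    Mean intensity over the wing region of interest.  Wings darken over
    hours (darker wings give smaller values) and the empty puparium left
    behind at emergence produces a sudden brightness increase.

``roughness_sd``
    Local-texture roughness: the sum, over interior ROI pixels, of the
    population standard deviation of each pixel's 3x3 neighborhood.  Rises
    as the molting fluid over the head is resorbed and the smooth bright
    reflection breaks up ("head roughening").

``roughness_borders``
    Patch-perimeter roughness: supra-threshold pixels are grouped into
    8-connected patches and the crack-edge perimeters are summed.  Patch
    fragmentation increases total perimeter, so this index also rises
    during roughening.

Onset of roughening is detected on the high-pass-filtered roughness trace
(first sustained excursion above a robust noise threshold); emergence is
the largest signed step of the channel's expected sign (brightness jump on
the wing channel, roughness collapse on the roughness channels).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .imaging import AnimalSeries
from .synthetic_data import Rect

__all__ = [
    "MarkerTrace",
    "Patch",
    "OnsetSummary",
    "wing_trace",
    "roughness_sd",
    "segment_patches",
    "roughness_borders",
    "roughness_trace",
    "highpass",
    "detect_onset",
    "detect_emergence",
    "summarize_onsets",
    "group_compare",
    "traces_to_frame",
]

CHANNELS = ("wing_intensity", "roughness_sd", "roughness_borders")


@dataclass
class MarkerTrace:
    animal_id: str
    channel: str
    t_h: np.ndarray
    values: np.ndarray
    filtered: bool = False  # high-pass output is signed; raw indices are not

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_h.shape != self.values.shape:
            raise ValueError("t_h and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if (self.channel.startswith("roughness") and not self.filtered
                and np.any(self.values < -1e-9)):
            raise ValueError("roughness values must be >= 0")

    def __len__(self) -> int:
        return len(self.t_h)

    @property
    def cadence_h(self) -> float:
        return float(np.median(np.diff(self.t_h)))


@dataclass
class Patch:
    """8-connected supra-threshold component with crack-edge perimeter."""

    pixels: np.ndarray  # (k, 2) row/col coordinates within the ROI
    area: int
    perimeter: int

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("patch area must be >= 1")
        if self.perimeter < 4 or self.perimeter % 2:
            raise ValueError("crack-edge perimeter must be even and >= 4")


@dataclass
class OnsetSummary:
    animal_id: str
    onset_t_h: float
    emergence_t_h: float
    duration_h: float
    time_to_onset_h: float


def _roi_view(frame: np.ndarray, roi: Rect | None) -> np.ndarray:
    if roi is None:
        return np.asarray(frame, dtype=float)
    r0, c0, h, w = roi
    fh, fw = frame.shape
    if r0 < 0 or c0 < 0 or r0 + h > fh or c0 + w > fw:
        raise ValueError(f"roi {roi} outside frame {fh}x{fw}")
    return np.asarray(frame[r0 : r0 + h, c0 : c0 + w], dtype=float)


# -- per-frame operators -------------------------------------------------------


def wing_trace(series: AnimalSeries) -> MarkerTrace:
    """Mean intensity over the wing ROI, per frame."""
    if series.wing_roi is None:
        raise ValueError("series has no wing_roi")
    values = [float(_roi_view(f, series.wing_roi).mean()) for f in series.frames]
    return MarkerTrace(series.animal_id, "wing_intensity", series.t_h, np.array(values))


def roughness_sd(frame: np.ndarray, roi: Rect | None = None,
                 mode: str = "neighborhood") -> float:
    """Sum of local 3x3 standard deviations over interior ROI pixels.

    ``mode='neighborhood'`` (default) takes the population SD of the 9
    intensities in each interior pixel's 3x3 neighborhood — the standard
    local-SD texture operator, invariant to an additive offset and
    homogeneous of degree 1 in intensity scale.  ``mode='differences'``
    instead takes the population SD of the 8 signed differences between the
    center and its neighbors, an alternative reading of "SD between each
    pixel and those immediately surrounding it".
    """
    img = _roi_view(frame, roi)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("roi must be at least 3x3")
    windows = sliding_window_view(img, (3, 3))
    if mode == "neighborhood":
        sds = windows.std(axis=(-2, -1))
    elif mode == "differences":
        centers = windows[..., 1, 1]
        diffs = windows.reshape(*windows.shape[:2], 9) - centers[..., None]
        diffs = np.delete(diffs, 4, axis=-1)  # drop the center-center zero
        sds = diffs.std(axis=-1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(sds.sum())


def segment_patches(frame: np.ndarray, roi: Rect | None,
                    threshold: float) -> list[Patch]:
    """8-connected components of pixels >= threshold within the ROI.

    Perimeter is the crack-edge count: pixel edges adjoining a sub-threshold
    or out-of-ROI pixel.  It is additive under patch splitting, unlike
    boundary-pixel counts.
    """
    img = _roi_view(frame, roi)
    mask = img >= threshold
    labels = cc_label(mask, connectivity=2)
    patches: list[Patch] = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        area = int(m.sum())
        horiz = int(np.count_nonzero(m[:, :-1] & m[:, 1:]))
        vert = int(np.count_nonzero(m[:-1, :] & m[1:, :]))
        perimeter = 4 * area - 2 * (horiz + vert)
        coords = np.argwhere(m)
        patches.append(Patch(pixels=coords, area=area, perimeter=perimeter))
    return patches


def roughness_borders(frame: np.ndarray, roi: Rect | None,
                      threshold: float) -> float:
    """Sum of crack-edge patch perimeters ("Borders" roughness index)."""
    return float(sum(p.perimeter for p in segment_patches(frame, roi, threshold)))


def roughness_trace(series: AnimalSeries, algorithm: str = "sd",
                    threshold: float | None = None,
                    sd_mode: str = "neighborhood") -> MarkerTrace:
    """Per-frame roughness index over the head ROI.

    For the ``borders`` algorithm the patch threshold is fixed per animal:
    Otsu on the head ROI of the first stabilized frame, then frozen for the
    whole series, so fragmentation is not confounded with illumination
    drift.  An explicit ``threshold`` overrides this.
    """
    if series.head_roi is None:
        raise ValueError("series has no head_roi")
    if algorithm == "sd":
        values = [roughness_sd(f, series.head_roi, mode=sd_mode)
                  for f in series.frames]
        channel = "roughness_sd"
    elif algorithm == "borders":
        if threshold is None:
            first = _roi_view(series.frames[0], series.head_roi)
            threshold = float(threshold_otsu(first))
        values = [roughness_borders(f, series.head_roi, threshold)
                  for f in series.frames]
        channel = "roughness_borders"
    else:
        raise ValueError(f"algorithm must be 'sd' or 'borders', got {algorithm!r}")
    return MarkerTrace(series.animal_id, channel, series.t_h, np.array(values))


# -- trace processing ----------------------------------------------------------


def _window_samples(trace_dt: float, window_h: float) -> int:
    w = int(round(window_h / trace_dt))
    w = max(3, w)
    return w if w % 2 else w + 1  # odd for a symmetric centered window


def highpass(trace: MarkerTrace, window_h: float = 6.0) -> MarkerTrace:
    """Value minus the centered moving average over ``window_h`` (window
    truncated at the record ends); timestamps preserved."""
    if len(trace) < 3:
        raise ValueError("trace must have at least 3 samples")
    w = _window_samples(trace.cadence_h, window_h)
    baseline = (
        pd.Series(trace.values).rolling(w, center=True, min_periods=1).mean()
    )
    return MarkerTrace(trace.animal_id, trace.channel, trace.t_h,
                       trace.values - baseline.to_numpy(), filtered=True)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_emergence(trace: MarkerTrace, k_jump: float = 6.0) -> float | None:
    """Time of the abrupt appearance change at eclosion, or None.

    The expected step sign follows the channel: the wing trace jumps up when
    the empty puparium appears; the roughness traces collapse.  The largest
    signed step must exceed the typical step (median) by ``k_jump`` robust
    SDs (MAD x 1.4826) of all steps; a perfectly steady ramp therefore never
    yields a detection even when every step is identical.
    """
    if len(trace) < 3:
        raise ValueError("trace must have at least 3 samples")
    sign = 1.0 if trace.channel == "wing_intensity" else -1.0
    diffs = sign * np.diff(trace.values)
    i = int(np.argmax(diffs))
    robust_sd = 1.4826 * _mad(diffs)
    excursion = diffs[i] - float(np.median(diffs))
    if excursion >= k_jump * robust_sd and excursion > 1e-9:
        return float(trace.t_h[i + 1])
    return None


def detect_onset(trace: MarkerTrace, window_h: float = 6.0, k_mad: float = 4.0,
                 min_run: int = 5) -> float | None:
    """First sustained excursion of the high-pass-filtered roughness trace.

    The post-emergence portion is excluded first; baseline noise is the MAD
    of the filtered values over the first quarter of the record (global MAD
    as a fallback for a degenerate zero-MAD baseline).  An excursion is a
    run of at least ``min_run`` consecutive samples with ``|filtered| >
    k_mad x MAD``; the onset is the time of the extremum of the first such
    excursion.  The excursion is two-sided and anchored at its extremum
    because a centered moving-average high-pass turns a flat-to-ramp change
    point into a *negative* lobe whose minimum falls exactly on the kink;
    a one-sided first-crossing rule would systematically miss or misplace
    ramp-like onsets.  Returns None when nothing crosses.
    """
    if trace.t_h[-1] - trace.t_h[0] < 6.0:
        raise ValueError("trace must cover at least 6 h of baseline")
    emergence = detect_emergence(trace)
    t, v = trace.t_h, trace.values
    if emergence is not None:
        keep = t < emergence
        t, v = t[keep], v[keep]
    if len(t) < 3:
        return None
    hp = highpass(
        MarkerTrace(trace.animal_id, trace.channel, t, v), window_h
    ).values
    quarter = max(3, len(hp) // 4)
    mad = _mad(hp[:quarter])
    if mad == 0:
        mad = _mad(hp)
    if mad == 0:
        return None
    above = np.abs(hp) > k_mad * mad
    run_start, run = None, 0
    for i, flag in enumerate(above):
        if flag:
            run_start = i if run == 0 else run_start
            run += 1
        else:
            if run >= min_run:
                break
            run = 0
    if run < min_run:
        return None
    end = run_start + run
    while end < len(above) and above[end]:
        end += 1
    seg = slice(run_start, end)
    return float(t[seg][int(np.argmax(np.abs(hp[seg])))])


def summarize_onsets(
    traces, dd_start_t_h: float = 0.0, groups: dict | None = None, **detect_kwargs
):
    """Per-animal onset/emergence summaries from roughness traces.

    Returns ``(summaries, excluded, group_table)``: animals whose onset or
    emergence cannot be detected, or whose emergence precedes the onset, are
    reported in ``excluded`` with a reason rather than silently dropped.
    ``group_table`` gives quartile summaries of both Fig-2-style quantities
    (time to roughening start, roughening duration) per group when a
    ``animal_id -> group`` mapping is supplied (single group otherwise).
    """
    summaries: list[OnsetSummary] = []
    excluded: list[tuple[str, str]] = []
    for trace in traces:
        onset = detect_onset(trace, **detect_kwargs)
        emergence = detect_emergence(trace)
        if onset is None:
            excluded.append((trace.animal_id, "no roughening onset detected"))
            continue
        if emergence is None:
            excluded.append((trace.animal_id, "no emergence detected"))
            continue
        if emergence <= onset:
            excluded.append((trace.animal_id, "emergence precedes onset (invalid)"))
            continue
        summaries.append(
            OnsetSummary(
                animal_id=trace.animal_id,
                onset_t_h=onset,
                emergence_t_h=emergence,
                duration_h=emergence - onset,
                time_to_onset_h=onset - dd_start_t_h,
            )
        )
    rows = []
    for s in summaries:
        grp = groups.get(s.animal_id, "all") if groups else "all"
        rows.append((grp, s.time_to_onset_h, s.duration_h))
    if rows:
        df = pd.DataFrame(rows, columns=["group", "time_to_onset_h", "duration_h"])
        table = df.groupby("group").agg(
            n=("duration_h", "size"),
            onset_q1=("time_to_onset_h", lambda x: x.quantile(0.25)),
            onset_median=("time_to_onset_h", "median"),
            onset_q3=("time_to_onset_h", lambda x: x.quantile(0.75)),
            duration_q1=("duration_h", lambda x: x.quantile(0.25)),
            duration_median=("duration_h", "median"),
            duration_q3=("duration_h", lambda x: x.quantile(0.75)),
        ).reset_index()
    else:
        table = pd.DataFrame(
            columns=["group", "n", "onset_q1", "onset_median", "onset_q3",
                     "duration_q1", "duration_median", "duration_q3"]
        )
    return summaries, excluded, table


# -- group statistics ----------------------------------------------------------


def _compact_letter_display(labels, not_different: set[frozenset]) -> dict[str, str]:
    g = nx.Graph()
    g.add_nodes_from(labels)
    for pair in not_different:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g), key=lambda c: sorted(c))
    letters = {lab: "" for lab in labels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for lab in clique:
            letters[lab] += letter
    return letters


def group_compare(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    Groups sharing a compact-letter-display letter are not significantly
    different at ``alpha``.  Requires >= 2 groups of >= 2 values; all-equal
    data (zero within-group variance with equal means) is rejected as
    degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("degenerate data: zero variance everywhere")
    f_stat, p_value = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    not_different: set[frozenset] = set()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(tukey.pvalue[i, j])
            pairwise.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p": p,
                    "significant": p < alpha,
                }
            )
            if p >= alpha:
                not_different.add(frozenset((labels[i], labels[j])))
    letters = _compact_letter_display(labels, not_different)
    df_between = len(labels) - 1
    df_within = pooled.size - len(labels)
    return {
        "F": float(f_stat),
        "p": float(p_value),
        "df": (df_between, df_within),
        "pairwise": pairwise,
        "letters": letters,
        "alpha": alpha,
    }


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format (animal_id, t_h, channel, value) table for CSV export."""
    parts = [
        pd.DataFrame(
            {
                "animal_id": tr.animal_id,
                "t_h": tr.t_h,
                "channel": tr.channel,
                "value": tr.values,
            }
        )
        for tr in traces
    ]
    return pd.concat(parts, ignore_index=True)
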