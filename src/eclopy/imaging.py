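"""Series reconstruction and stabilization of per-animal burst imagery.

The filming rig captures a burst of images each time an animal passes under
the objective; the animal's position varies slightly between burst frames.
:func:`reconstruct_series` keeps, per burst, the frame in which the fly is
most centered (intensity-weighted centroid of above-Otsu pixels nearest the
frame center).  :func:`stabilize` then removes residual jitter by integer
translation of each frame onto its predecessor, maximizing normalized
cross-correlation within a bounded shift, so that regions of interest drawn
on the first frame stay valid for the whole series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .synthetic_data import Manifest, Rect, _integer_shift

__all__ = ["AnimalSeries", "reconstruct_series", "stabilize", "load_images"]


@dataclass
class AnimalSeries:
    """One stabilized (or to-be-stabilized) frame per timepoint for an animal."""

    animal_id: str
    t_h: np.ndarray
    frames: np.ndarray  # (n, H, W)
    head_roi: Rect | None = None
    wing_roi: Rect | None = None
    shifts: np.ndarray | None = None        # (n, 2) applied (dy, dx)
    shift_at_bound: np.ndarray | None = None  # (n,) warning flags
    source_files: list | None = None        # selected burst frame per timepoint

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if len(self.t_h) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.t_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        h, w = self.frames.shape[1:]
        for name, roi in (("head_roi", self.head_roi), ("wing_roi", self.wing_roi)):
            if roi is not None:
                r0, c0, rh, rw = roi
                if r0 < 0 or c0 < 0 or r0 + rh > h or c0 + rw > w:
                    raise ValueError(f"{name} {roi} outside frame {h}x{w}")

    @property
    def cadence_h(self) -> float:
        steps = np.diff(self.t_h)
        return float(np.median(steps))

    def __len__(self) -> int:
        return len(self.t_h)


def load_images(source) -> dict[str, np.ndarray]:
    """Normalize an image source (dict of arrays, or a directory of files)
    into a filename-keyed dict of 2-D arrays."""
    if isinstance(source, dict):
        return source
    src = Path(source)
    if not src.is_dir():
        raise FileNotFoundError(f"image directory {src} not found")
    return {p.name: iio.imread(p) for p in sorted(src.iterdir())
            if p.suffix.lower() in (".png", ".tif", ".tiff")}


def _centroid_distance(frame: np.ndarray) -> float:
    img = frame.astype(float)
    try:
        thresh = threshold_otsu(img)
    except ValueError:  # constant image
        thresh = img.min() - 1.0
    mask = img > thresh
    if not mask.any():
        mask = np.ones_like(img, dtype=bool)
    weights = img * mask
    total = weights.sum()
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    cy = (rr * weights).sum() / total
    cx = (cc * weights).sum() / total
    center = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    return float(np.hypot(cy - center[0], cx - center[1]))


def reconstruct_series(
    manifest: Manifest | pd.DataFrame,
    images,
    head_roi: Rect | None = None,
    wing_roi: Rect | None = None,
) -> dict[str, AnimalSeries]:
    """Build one series per animal by selecting the most-centered burst frame.

    Per burst, the frame whose intensity-weighted centroid of above-Otsu
    pixels lies nearest the frame center is kept; ties go to the lowest
    burst index.  Returns a dict keyed by animal id.
    """
    df = manifest.frame if isinstance(manifest, Manifest) else manifest
    if isinstance(manifest, pd.DataFrame):
        Manifest(df)  # validate
    imgs = load_images(images)
    series: dict[str, AnimalSeries] = {}
    for animal, grp in df.groupby("animal_id", sort=False):
        times, frames, chosen = [], [], []
        for t, burst in grp.groupby("t_h", sort=True):
            burst = burst.sort_values("burst_index")
            if burst.empty:
                raise ValueError(f"empty burst for animal {animal} at t={t} h")
            best_name, best_d = None, np.inf
            for row in burst.itertuples():
                if row.filename not in imgs:
                    raise FileNotFoundError(
                        f"image {row.filename} (animal {animal}, t={t} h) unreadable"
                    )
                d = _centroid_distance(imgs[row.filename])
                if d < best_d - 1e-12:
                    best_name, best_d = row.filename, d
            times.append(float(t))
            frames.append(imgs[best_name])
            chosen.append(best_name)
        series[str(animal)] = AnimalSeries(
            animal_id=str(animal),
            t_h=np.array(times),
            frames=np.stack(frames),
            head_roi=head_roi,
            wing_roi=wing_roi,
            source_files=chosen,
        )
    return series


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def best_shift(
    reference: np.ndarray, frame: np.ndarray, max_shift_px: int
) -> tuple[int, int, float]:
    """Integer shift (dy, dx) maximizing NCC of ``frame`` against
    ``reference``; exhaustive scan over the bounded shift grid.  Ties break
    toward the smallest |shift|, then lexicographically."""
    ref = reference.astype(float)
    img = frame.astype(float)
    h, w = ref.shape
    best = (0, 0, -np.inf)
    for dy in range(-max_shift_px, max_shift_px + 1):
        ys = slice(max(dy, 0), min(h, h + dy))
        ys_src = slice(max(-dy, 0), min(h, h - dy))
        for dx in range(-max_shift_px, max_shift_px + 1):
            xs = slice(max(dx, 0), min(w, w + dx))
            xs_src = slice(max(-dx, 0), min(w, w - dx))
            score = _ncc(ref[ys, xs], img[ys_src, xs_src])
            key = (score, -(abs(dy) + abs(dx)), -dy, -dx)
            best_key = (best[2], -(abs(best[0]) + abs(best[1])), -best[0], -best[1])
            if key > best_key:
                best = (dy, dx, score)
    return best


def stabilize(series: AnimalSeries, max_shift_px: int = 5) -> AnimalSeries:
    """Align each frame to its (already aligned) predecessor by bounded
    integer translation; the first frame is the fixed reference.

    Cumulative applied shifts are recorded per frame; a frame whose best
    shift sits on the search bound is flagged (the true displacement may be
    larger than the bound).
    """
    if len(series) == 0:
        raise ValueError("cannot stabilize an empty series")
    n = len(series)
    out = np.empty_like(series.frames)
    out[0] = series.frames[0]
    shifts = np.zeros((n, 2), dtype=int)
    at_bound = np.zeros(n, dtype=bool)
    fill = float(np.median(series.frames[0]))
    for i in range(1, n):
        dy, dx, _ = best_shift(out[i - 1], series.frames[i], max_shift_px)
        at_bound[i] = max(abs(dy), abs(dx)) >= max_shift_px
        shifted = _integer_shift(series.frames[i].astype(float), dy, dx, fill)
        out[i] = shifted.astype(series.frames.dtype)
        shifts[i] = (dy, dx)
    return replace(
        series, frames=out, shifts=shifts, shift_at_bound=at_bound
    )
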