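"""Ground-truthed synthetic time-lapse imagery and population eclosion records.

Emulates a rotating-disk filming rig for pharate adult flies: every animal
is imaged in a burst of ``burst_size`` frames each ``cadence_h`` hours
(default: 10 images every 12 min), with small translation jitter between
burst images, additive sensor noise, and a slow illumination drift.

The appearance model follows the biology of the final day of metamorphosis
as seen through the pupal cuticle with oblique far-red illumination:

* a bright, smooth-bordered head reflection (molting fluid between pupal
  and adult cuticle) that — once resorption starts at the roughening onset
  — fragments into an increasing number of smaller patches with irregular
  borders and develops fine speckle texture;
* a wing region that darkens over several hours (darker wings give lower
  mean intensity);
* an abrupt switch to an "empty puparium" appearance at emergence: the wing
  region brightens suddenly and the head patchiness disappears.

All randomness is driven by explicit integer seeds; every rendered series
carries its ground-truth :class:`~eclopy.gating.FlySchedule` so recovery of
onset and emergence by the markers pipeline can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import gating
from .gating import FlySchedule, GatingParams
from .rhythm import EventRecord, bin_events

__all__ = [
    "SceneParams",
    "Manifest",
    "RenderResult",
    "render_series",
    "generate_event_record",
    "write_fixture",
    "fixture_gating_preset",
]

Rect = tuple[int, int, int, int]  # (row0, col0, height, width)


@dataclass(frozen=True)
class SceneParams:
    """Geometry and photometry of the rendered scene.

    Frames are 8-bit grayscale, origin top-left, row-major, 0-based pixels.
    All intensities are on the 0–255 scale.
    """

    frame_h: int = 200
    frame_w: int = 200
    background: float = 30.0
    body_center: tuple[float, float] = (99.5, 99.5)  # (row, col), frame center
    body_axes: tuple[float, float] = (72.0, 46.0)      # (row, col) semi-axes
    body_intensity: float = 120.0
    head_roi: Rect = (28, 72, 56, 56)
    wing_roi: Rect = (112, 76, 40, 48)
    head_axes: tuple[float, float] = (17.0, 19.0)
    head_intensity: float = 230.0
    blur_px: float = 1.0
    head_smooth_blur_px: float = 3.5  # soft border of the intact reflection
    head_rough_blur_px: float = 1.0   # border sharpness at completion
    max_patches: int = 8
    boundary_amp: float = 0.35      # radial boundary perturbation, fraction of radius
    speckle_amp: float = 28.0       # intensity SD of resorption texture at completion
    wing_ramp_start_h: float = 2.0  # offset from pupariation
    wing_ramp_h: float = 10.0
    wing_start_intensity: float = 170.0
    wing_end_intensity: float = 70.0
    post_wing_intensity: float = 210.0
    post_head_intensity: float = 130.0
    noise_sd: float = 1.5
    jitter_px: int = 2
    drift_amp: float = 2.0
    drift_period_h: float = 24.0
    cadence_h: float = 0.2
    burst_size: int = 10

    def __post_init__(self) -> None:
        for name, (r0, c0, h, w) in (("head_roi", self.head_roi),
                                     ("wing_roi", self.wing_roi)):
            if r0 < 0 or c0 < 0 or r0 + h > self.frame_h or c0 + w > self.frame_w:
                raise ValueError(f"{name} {self.head_roi} outside frame")
        for val in (self.background, self.body_intensity, self.head_intensity,
                    self.wing_start_intensity, self.wing_end_intensity,
                    self.post_wing_intensity, self.post_head_intensity):
            if not 0 <= val <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.cadence_h <= 0:
            raise ValueError("cadence_h must be positive")
        if self.burst_size < 1:
            raise ValueError("burst_size must be >= 1")


@dataclass
class Manifest:
    """Typed view of the per-frame index: one row per captured image."""

    frame: pd.DataFrame  # columns: animal_id, t_h, burst_index, filename

    def __post_init__(self) -> None:
        df = self.frame
        required = {"animal_id", "t_h", "burst_index", "filename"}
        if not required <= set(df.columns):
            raise ValueError(f"manifest missing columns {required - set(df.columns)}")
        if df["filename"].duplicated().any():
            raise ValueError("manifest filenames must be unique")
        for animal, grp in df.groupby("animal_id"):
            ts = grp["t_h"].drop_duplicates().to_numpy()
            if np.any(np.diff(ts) <= 0):
                raise ValueError(f"non-monotone timestamps for animal {animal}")
            sizes = grp.groupby("t_h").size().unique()
            if len(sizes) != 1:
                raise ValueError(f"incomplete bursts for animal {animal}")

    @property
    def burst_size(self) -> int:
        return int(self.frame.groupby(["animal_id", "t_h"]).size().iloc[0])


@dataclass
class RenderResult:
    manifest: Manifest
    images: dict[str, np.ndarray]
    jitter: pd.DataFrame  # animal_id, t_h, burst_index, dy, dx
    schedule: FlySchedule


# -- per-animal appearance model ---------------------------------------------


class _HeadModel:
    """Deterministic per-animal fragmentation model of the head reflection."""

    def __init__(self, scene: SceneParams, rng: np.random.Generator):
        self.scene = scene
        k_max = scene.max_patches
        # patch 0 sits at the ellipse center so the pre-onset smooth patch
        # deforms continuously rather than jumping at the onset
        centers = rng.uniform(-0.55, 0.55, size=(k_max, 2))
        centers[0] = (0.0, 0.0)
        self.centers = centers
        self.harmonics = np.array([3, 4, 5, 7])
        self.four_amp = rng.uniform(0.3, 1.0, size=(k_max, len(self.harmonics)))
        self.four_phase = rng.uniform(0, 2 * np.pi, size=(k_max, len(self.harmonics)))
        r0, c0, h, w = scene.head_roi
        rr, cc = np.mgrid[0:h, 0:w]
        cr, ccol = (h - 1) / 2.0, (w - 1) / 2.0
        ar, ac = scene.head_axes
        self.ny = (rr - cr) / ar
        self.nx = (cc - ccol) / ac
        self.speckle = rng.normal(0.0, 1.0, size=(h, w))

    def mask_and_texture(self, frac: float) -> tuple[np.ndarray, np.ndarray]:
        """Patch mask and additive texture over the head ROI.

        ``frac`` is progress through roughening, 0 at onset, 1 at emergence
        (negative before onset).  Patch count grows linearly with progress;
        boundary irregularity and speckle contrast grow as sqrt(progress),
        matching the steep initial rise of molting-fluid resorption.
        """
        scene = self.scene
        frac = float(np.clip(frac, 0.0, 1.0))
        # continuous fragmentation index; the i-th patch fades in as kappa
        # crosses i, so the count of patches at >= half fade equals
        # round(1 + (K-1) * frac) and the rendered index has no jump
        # discontinuities between frames
        kappa = 1.0 + (scene.max_patches - 1) * frac
        k = int(np.ceil(kappa - 1e-9))
        k = max(1, min(scene.max_patches, k))
        grow = np.sqrt(frac)
        # sublinear shrink: patch count grows faster than patch area falls,
        # so the specked (resorbing) area never contracts as it fragments
        radius = 0.95 / kappa**0.4
        edge = 0.06  # anti-aliased boundary width (normalized units, ~1 px)
        weight = np.zeros(self.ny.shape, dtype=float)
        for i in range(k):
            fade = float(np.clip(kappa - i, 0.0, 1.0))
            dy = self.ny - self.centers[i, 0]
            dx = self.nx - self.centers[i, 1]
            d = np.hypot(dy, dx)
            theta = np.arctan2(dy, dx)
            wobble = np.zeros_like(theta)
            for j, m in enumerate(self.harmonics):
                wobble += self.four_amp[i, j] * np.sin(m * theta + self.four_phase[i, j])
            wobble /= len(self.harmonics)
            r_eff = np.maximum(radius * (1.0 + scene.boundary_amp * grow * wobble), 0.05)
            indicator = fade * np.clip((r_eff - d) / edge + 0.5, 0.0, 1.0)
            weight = np.maximum(weight, indicator)
        # keep patches inside the original reflection footprint
        d0 = np.hypot(self.ny, self.nx)
        footprint = np.clip((1.05 - d0) / edge + 0.5, 0.0, 1.0)
        weight *= footprint
        # resorption texture switches on abruptly (a distinct starting moment
        # is what makes the onset detectable) and deepens as sqrt(progress);
        # it covers the whole head contact area — the cuticle sticks to the
        # irregular head surface wherever fluid has receded, not only under
        # the remaining bright reflections
        activation = 0.0 if frac <= 0 else 0.15 + 0.85 * grow
        texture = scene.speckle_amp * activation * self.speckle * footprint
        return weight, texture


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _integer_shift(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def _clean_frame(schedule: FlySchedule, scene: SceneParams, head: _HeadModel,
                 t_h: float) -> np.ndarray:
    frame = np.full((scene.frame_h, scene.frame_w), scene.background, dtype=float)
    body = _ellipse_mask(frame.shape, scene.body_center, scene.body_axes)
    frame[body] = scene.body_intensity

    emerged = t_h >= schedule.emergence_t_h
    r0, c0, h, w = scene.wing_roi
    if emerged:
        frame[r0 : r0 + h, c0 : c0 + w] = scene.post_wing_intensity
    else:
        ramp_t0 = schedule.pupariation_zt_h + scene.wing_ramp_start_h
        prog = np.clip((t_h - ramp_t0) / scene.wing_ramp_h, 0.0, 1.0)
        wing = scene.wing_start_intensity + prog * (
            scene.wing_end_intensity - scene.wing_start_intensity
        )
        frame[r0 : r0 + h, c0 : c0 + w] = wing

    if scene.blur_px > 0:
        frame = gaussian_filter(frame, scene.blur_px)

    # the head reflection is composited after the global blur: its border
    # softness is a developmental signal (smooth-bordered while molting
    # fluid is present, sharpening as resorption proceeds), and the
    # resorption speckle must stay at pixel scale
    r0, c0, h, w = scene.head_roi
    sub = frame[r0 : r0 + h, c0 : c0 + w]
    if emerged:
        footprint = np.hypot(head.ny, head.nx) <= 1.0
        sub[footprint] = scene.post_head_intensity
    else:
        denom = schedule.emergence_t_h - schedule.onset_t_h
        frac = (t_h - schedule.onset_t_h) / denom if denom > 0 else 0.0
        weight, texture = head.mask_and_texture(frac)
        grow = np.sqrt(np.clip(frac, 0.0, 1.0))
        sigma = (scene.head_smooth_blur_px
                 + grow * (scene.head_rough_blur_px - scene.head_smooth_blur_px))
        layer = (scene.head_intensity - sub) * weight
        if sigma > 0:
            layer = gaussian_filter(layer, sigma)
        sub += layer + texture
    return frame


def render_series(
    schedule: FlySchedule,
    scene: SceneParams,
    seed: int,
    out_dir: str | Path | None = None,
    t_start_h: float = 0.0,
) -> RenderResult:
    """Render the burst image series for one animal, t_start to emergence + 2 h.

    Returns the manifest, the images (as a filename-keyed dict of uint8
    arrays) and the per-image applied jitter; with ``out_dir`` set, frames
    are also written as PNG plus a ``manifest.csv``.  Deterministic for a
    fixed seed.
    """
    if schedule.emergence_t_h <= schedule.onset_t_h:
        raise ValueError("schedule emergence must follow onset")
    if schedule.emergence_t_h <= t_start_h:
        raise ValueError("render window ends before it starts")
    layout_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    noise_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    head = _HeadModel(scene, layout_rng)

    n_steps = int(np.floor((schedule.emergence_t_h + 2.0 - t_start_h) / scene.cadence_h))
    times = t_start_h + scene.cadence_h * np.arange(n_steps + 1)

    rows, jit_rows = [], []
    images: dict[str, np.ndarray] = {}
    for ti, t in enumerate(times):
        clean = _clean_frame(schedule, scene, head, float(t))
        drift = scene.drift_amp * np.sin(2 * np.pi * t / scene.drift_period_h)
        for b in range(scene.burst_size):
            img = clean + drift
            if scene.noise_sd > 0:
                img = img + noise_rng.normal(0, scene.noise_sd, img.shape)
            if scene.jitter_px > 0:
                dy = int(noise_rng.integers(-scene.jitter_px, scene.jitter_px + 1))
                dx = int(noise_rng.integers(-scene.jitter_px, scene.jitter_px + 1))
            else:
                dy = dx = 0
            img = _integer_shift(img, dy, dx, scene.background)
            img = np.clip(img, 0, 255).astype(np.uint8)
            fname = f"{schedule.fly_id}_t{ti:04d}_b{b:02d}.png"
            images[fname] = img
            rows.append((schedule.fly_id, float(t), b, fname))
            jit_rows.append((schedule.fly_id, float(t), b, dy, dx))

    manifest = Manifest(
        pd.DataFrame(rows, columns=["animal_id", "t_h", "burst_index", "filename"])
    )
    jitter = pd.DataFrame(
        jit_rows, columns=["animal_id", "t_h", "burst_index", "dy", "dx"]
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, img in images.items():
            iio.imwrite(out_dir / fname, img)
        manifest.frame.to_csv(out_dir / "manifest.csv", index=False)
        jitter.to_csv(out_dir / "jitter.csv", index=False)
    return RenderResult(manifest, images, jitter, schedule)


# -- population event records -------------------------------------------------


def generate_event_record(
    params: GatingParams,
    pupariation_zts=None,
    n: int = 300,
    n_days: int = 7,
    bin_h: float = 0.5,
    seed: int = 0,
) -> tuple[EventRecord, list[FlySchedule]]:
    """Simulate a binned population eclosion record over ``[0, n_days*24)`` h.

    With ``pupariation_zts=None`` (the population-assay emulation) the flies'
    pupariation times are drawn uniformly over a window sized so mean
    emergence times cover the record — pupae of every developmental age, as
    collected from developing cultures.  An explicit list of collection ZTs
    instead builds synchronized cohorts restaggered daily over ``n_days``
    (the imaging-protocol emulation).

    Returns the record together with the underlying ground-truth schedules;
    the recorded total equals the number of flies emerging inside the window.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if bin_h <= 0:
        raise ValueError("bin_h must be positive")
    t_end = 24.0 * n_days
    if n == 0:
        empty = bin_events([], bin_h, 0.0, t_end)
        return empty, []
    dev_mean = params.commit_mean_h + params.rough_mean_h
    if pupariation_zts is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**20,)))
        offsets = rng.uniform(-dev_mean, t_end - dev_mean, size=n)
        schedules = gating.simulate_cohort(params, offsets.tolist(), 1, seed)
    else:
        shift = float(np.floor(dev_mean / 24.0) * 24.0)
        offsets = [
            float(zt) + 24.0 * d - shift
            for d in range(n_days)
            for zt in pupariation_zts
        ]
        n_per_group = max(1, int(np.ceil(n / len(offsets))))
        schedules = gating.simulate_cohort(params, offsets, n_per_group, seed)
    record = bin_events(
        [s.emergence_t_h for s in schedules], bin_h, 0.0, t_end
    )
    return record, schedules


# -- fixtures ------------------------------------------------------------------


def fixture_gating_preset(split_gates: bool = False, **overrides) -> GatingParams:
    """Gating preset scaled for short image fixtures (emergence within ~1 day).

    The default places completions inside the first open gate (t in [12, 22)
    with the standard clock geometry); ``split_gates=True`` centers the
    completion distribution on the gate close so cohorts split between the
    first and second gate.  In the split preset, commitment-time variation
    dominates duration variation: selection at the gate boundary acts on
    completion time, so if duration contributed a comparable share of its
    variance the early-gate group would be enriched for short durations and
    a spurious gate effect would appear even though durations are drawn
    independently of the gate.
    """
    base = dict(commit_mean_h=7.0, commit_sd_h=0.8, rough_mean_h=13.0,
                rough_sd_h=0.7)
    if split_gates:
        base.update(commit_mean_h=9.0, commit_sd_h=2.5, rough_sd_h=0.4)
    base.update(overrides)
    return GatingParams(**base)


_FIXTURE_KINDS = (
    "images_small", "images_cohorts", "events_wt", "events_short",
    "events_arrhythmic",
)


def write_fixture(kind: str, out_dir: str | Path, seed: int = 0) -> dict:
    """Write a self-describing test fixture; regenerable in well under 2 min.

    ``images_*`` fixtures contain PNG frames, a manifest, a jitter log and
    the ground-truth schedule CSV; ``events_*`` fixtures contain a binned
    event CSV plus the ground-truth schedule CSV.  Identical seeds reproduce
    identical CSVs.
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected {_FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if kind in ("images_small", "images_cohorts"):
        if kind == "images_small":
            params = fixture_gating_preset()
            zts, n_per = [0.0], 3
            scene = SceneParams(burst_size=5)  # keeps the fixture under 50 MB
        else:
            params = fixture_gating_preset(split_gates=True)
            zts, n_per = [0.0, 2.0], 3
            scene = SceneParams(burst_size=3)
        schedules = gating.simulate_cohort(params, zts, n_per, seed)
        manifests = []
        for i, sched in enumerate(schedules):
            res = render_series(sched, scene, seed=seed + 101 * i, out_dir=out_dir)
            manifests.append(res.manifest.frame)
        pd.concat(manifests, ignore_index=True).to_csv(
            out_dir / "manifest.csv", index=False
        )
        gating.write_schedules_csv(schedules, out_dir / "ground_truth.csv")
        return {"kind": kind, "n_animals": len(schedules), "dir": str(out_dir)}

    presets = {
        "events_wt": (gating.wild_type_preset(), [6.0, 12.0, 18.0]),
        "events_short": (gating.short_period_preset(), None),
        "events_arrhythmic": (gating.arrhythmic_preset(), None),
    }
    params, zts = presets[kind]
    record, schedules = generate_event_record(
        params, pupariation_zts=zts, n=300, n_days=7, bin_h=0.5, seed=seed
    )
    from .rhythm import write_events_csv

    write_events_csv(record, out_dir / "events.csv")
    gating.write_schedules_csv(schedules, out_dir / "ground_truth.csv")
    return {"kind": kind, "n_flies": len(schedules), "total_counted": record.total,
            "dir": str(out_dir)}
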