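"""Shared fixtures: rendered ground-truthed cohorts, generated at test time."""

from dataclasses import dataclass

import numpy as np
import pytest

from eclopy import gating, imaging, markers, synthetic_data as sd


@dataclass
class RenderedAnimal:
    schedule: gating.FlySchedule
    render: sd.RenderResult
    stabilized: imaging.AnimalSeries
    rough_sd: markers.MarkerTrace
    rough_borders: markers.MarkerTrace
    wing: markers.MarkerTrace


def _render_cohort(n: int, root_seed: int) -> list[RenderedAnimal]:
    params = sd.fixture_gating_preset()
    scene = sd.SceneParams(burst_size=3)
    schedules = gating.simulate_cohort(params, [0.0], n, root_seed)
    cohort = []
    for i, sched in enumerate(schedules):
        res = sd.render_series(sched, scene, seed=root_seed + 101 * i)
        series = imaging.reconstruct_series(
            res.manifest, res.images,
            head_roi=scene.head_roi, wing_roi=scene.wing_roi,
        )[sched.fly_id]
        stab = imaging.stabilize(series, max_shift_px=5)
        cohort.append(
            RenderedAnimal(
                schedule=sched,
                render=res,
                stabilized=stab,
                rough_sd=markers.roughness_trace(stab, "sd"),
                rough_borders=markers.roughness_trace(stab, "borders"),
                wing=markers.wing_trace(stab),
            )
        )
    return cohort


@pytest.fixture(scope="session")
def rendered_cohort() -> list[RenderedAnimal]:
    """Ten animals rendered with the default rig (10-min-scale bursts of 3,
    2-px jitter, sensor noise), reconstructed, stabilized and traced."""
    return _render_cohort(10, root_seed=42)


@pytest.fixture(scope="session")
def clean_animal() -> RenderedAnimal:
    """One animal rendered without noise, jitter or illumination drift."""
    params = sd.fixture_gating_preset()
    sched = gating.simulate_cohort(params, [0.0], 1, 7)[0]
    scene = sd.SceneParams(burst_size=1, noise_sd=0.0, jitter_px=0, drift_amp=0.0)
    res = sd.render_series(sched, scene, seed=7)
    series = imaging.reconstruct_series(
        res.manifest, res.images, head_roi=scene.head_roi, wing_roi=scene.wing_roi
    )[sched.fly_id]
    return RenderedAnimal(
        schedule=sched,
        render=res,
        stabilized=series,  # nothing to stabilize: jitter-free
        rough_sd=markers.roughness_trace(series, "sd"),
        rough_borders=markers.roughness_trace(series, "borders"),
        wing=markers.wing_trace(series),
    )
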