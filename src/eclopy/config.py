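"""Flat key-value run configuration.

The config file format is deliberately minimal: one ``section.key = value``
assignment per line, ``#`` comments, blank lines ignored.  Section names
match the module whose parameters they carry (``gating``, ``scene``,
``markers``, ``rhythm``, ``run``).  Every default is echoed into the run
log so any output is reproducible from its log alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .gating import GatingParams
from .synthetic_data import SceneParams

__all__ = ["RunConfig", "parse_config", "load_config"]

_DEFAULTS = {
    "run": {"seed": 0, "out_dir": "eclopy_out"},
    "markers": {"window_h": 6.0, "k_mad": 4.0, "min_run": 5, "k_jump": 6.0,
                "algorithm": "sd", "sd_mode": "neighborhood"},
    "rhythm": {"bin_h": 0.5, "max_lag_h": 72.0, "prominence": 0.02,
               "ri_peak_index": 1, "expected_period_h": 24.0, "valley_tol_h": 4.0},
    "imaging": {"max_shift_px": 5},
}


def _coerce(value: str):
    v = value.strip()
    low = v.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(v)
    except ValueError:
        pass
    try:
        return float(v)
    except ValueError:
        pass
    if v.startswith("(") and v.endswith(")"):
        return tuple(_coerce(p) for p in v[1:-1].split(",") if p.strip())
    return v


def parse_config(text: str) -> dict:
    """Parse flat ``section.key = value`` lines into a nested dict on top of
    the documented defaults."""
    cfg = {sec: dict(vals) for sec, vals in _DEFAULTS.items()}
    cfg.setdefault("gating", {})
    cfg.setdefault("scene", {})
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line or "." not in line.split("=", 1)[0]:
            raise ValueError(f"config line {ln}: expected 'section.key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        section, name = key.split(".", 1)
        cfg.setdefault(section, {})[name] = _coerce(value)
    return cfg


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return parse_config("")
    return parse_config(Path(path).read_text())


@dataclasses.dataclass
class RunConfig:
    """Validated configuration bundle for the end-to-end pipeline."""

    seed: int
    out_dir: Path
    gating: GatingParams
    scene: SceneParams
    markers: dict
    rhythm: dict
    imaging: dict

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        run = cfg.get("run", {})
        return cls(
            seed=int(run.get("seed", 0)),
            out_dir=Path(run.get("out_dir", "eclopy_out")),
            gating=GatingParams(**cfg.get("gating", {})),
            scene=SceneParams(**cfg.get("scene", {})),
            markers=dict(cfg.get("markers", _DEFAULTS["markers"])),
            rhythm=dict(cfg.get("rhythm", _DEFAULTS["rhythm"])),
            imaging=dict(cfg.get("imaging", _DEFAULTS["imaging"])),
        )

    def echo(self) -> str:
        """Full parameter dump for the run log."""
        payload = {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "gating": dataclasses.asdict(self.gating),
            "scene": dataclasses.asdict(self.scene),
            "markers": self.markers,
            "rhythm": self.rhythm,
            "imaging": self.imaging,
        }
        return json.dumps(payload, indent=2, sort_keys=True)
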