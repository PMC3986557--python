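"""Run configuration: a validated YAML document driving the CLI.

Top-level blocks: ``screen`` (display geometry), ``simulate`` (session
generator), ``calibrate`` (method and optimiser settings), ``evaluate``
(pairing and thresholds) and a global ``seed``.  Unknown keys anywhere are
rejected so that typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .screen import ScreenParams, default_screen

__all__ = ["RunConfig", "load_config"]

_SCREEN_KEYS = {"center", "normal", "up", "width_cm", "height_cm", "width_px", "height_px"}
_SIM_KEYS = {"mobility", "sample_rate", "noise_pupil", "noise_head_pos",
             "noise_head_rot", "fixation_jitter_deg", "protocol"}
_CAL_KEYS = {"method", "subset_size", "max_evaluations", "gp_max_train", "kernel_form"}
_EVAL_KEYS = {"pairing", "reject_threshold_px", "subset_size", "gp_max_train"}
_TOP_KEYS = {"seed", "screen", "simulate", "calibrate", "evaluate"}


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block {where!r}")


@dataclass
class RunConfig:
    seed: int = 0
    screen: ScreenParams = field(default_factory=default_screen)
    simulate: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, _TOP_KEYS, "<top level>")
        screen = default_screen()
        if "screen" in d:
            _check_keys(d["screen"], _SCREEN_KEYS, "screen")
            screen = ScreenParams.from_dict({**default_screen().to_dict(), **d["screen"]})
        sim = dict(d.get("simulate", {}))
        _check_keys(sim, _SIM_KEYS, "simulate")
        cal = dict(d.get("calibrate", {}))
        _check_keys(cal, _CAL_KEYS, "calibrate")
        ev = dict(d.get("evaluate", {}))
        _check_keys(ev, _EVAL_KEYS, "evaluate")
        return cls(seed=int(d.get("seed", 0)), screen=screen,
                   simulate=sim, calibrate=cal, evaluate=ev)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig.from_dict(doc)
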