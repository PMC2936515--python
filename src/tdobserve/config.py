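"""YAML/JSON experiment configuration.

A config document has optional sections ``task``, ``engagement``,
``policy``, ``learning`` and ``experiment``; anything omitted falls back to
the package defaults.  The task may be given inline (builder keywords) or
as a reference to a full task document via ``task_file``.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .choice_policy import PolicyParams
from .engagement import EngagementParams
from .experiments import DEFAULT_ALPHA, DEFAULT_TRIALS_PER_SESSION
from .task_model import TaskSpec, build_delayed_task, build_observing_task, load_task

__all__ = ["load_config", "make_task", "make_engagement", "make_policy",
           "experiment_settings"]


def load_config(path) -> dict:
    """Read a YAML (or ``.json``) config document; empty file → defaults."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return doc


def make_task(cfg: dict) -> TaskSpec:
    section = dict(cfg.get("task", {}))
    if "task_file" in section:
        return load_task(section["task_file"])
    variant = section.pop("variant", "standard")
    builder = build_delayed_task if variant == "delayed" else build_observing_task
    if variant == "aversive":
        section.setdefault("variant_tag", "aversive")
        section.setdefault("r_large", -1.0)
        section.setdefault("r_small", -0.04)
    return builder(**section)


def make_engagement(cfg: dict) -> EngagementParams:
    return EngagementParams(**cfg.get("engagement", {}))


def make_policy(cfg: dict) -> PolicyParams:
    return PolicyParams(**cfg.get("policy", {}))


def experiment_settings(cfg: dict) -> dict:
    """Experiment-loop settings with defaults filled in."""
    section = dict(cfg.get("experiment", {}))
    learning = cfg.get("learning", {})
    section.setdefault("n_trials", DEFAULT_TRIALS_PER_SESSION)
    section.setdefault("n_sessions", 25)
    section["alpha"] = learning.get("alpha", DEFAULT_ALPHA)
    return section
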