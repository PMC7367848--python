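"""Experiment configuration: YAML round-trip with strict key validation.

An experiment file has up to four sections — ``network``, ``learning``,
``rl``, ``task``, and ``run`` — whose keys map one-to-one onto the
corresponding dataclasses.  Unknown keys are hard errors (with a
nearest-key suggestion); invariant violations are collected and reported
together.  A loaded configuration is echoed back into the output
directory so any run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .config import ConfigurationError, NetworkConfig
from .learning import LearningMode
from .rl import RLConfig
from .tasks import CueAccumulationParams, PatternRegressionParams

TASKS = ("cue_accumulation", "pattern_regression", "catch")


@dataclass
class RunSettings:
    """Run-level settings: seed, batching, duration, output."""

    seed: int = 1
    batch_size: int = 64
    n_iterations: int = 100
    out_dir: str = "runs"
    snapshot_every: int = 0  # 0 disables weight snapshots
    eval_every: int = 10
    preset: str = "default"


@dataclass
class ExperimentConfig:
    network: NetworkConfig = None
    learning: LearningMode = field(default_factory=LearningMode)
    rl: RLConfig = field(default_factory=RLConfig)
    task: str = "cue_accumulation"
    task_params: dict = field(default_factory=dict)
    run: RunSettings = field(default_factory=RunSettings)


_SECTION_TYPES = {
    "learning": LearningMode,
    "rl": RLConfig,
    "run": RunSettings,
}


def _build(cls, section: str, data: dict, problems: list):
    valid = {f.name for f in fields(cls)}
    clean = {}
    for key, value in data.items():
        if key not in valid:
            hint = difflib.get_close_matches(key, sorted(valid), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            problems.append(f"unknown key {section}.{key}{suffix}")
        else:
            clean[key] = value
    if problems:
        return None
    try:
        return cls(**clean)
    except (ConfigurationError, TypeError, ValueError) as exc:
        problems.append(f"{section}: {exc}")
        return None


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment file, resolving all defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    problems: list[str] = []
    known_sections = {"network", "learning", "rl", "task", "run"}
    for key in raw:
        if key not in known_sections:
            hint = difflib.get_close_matches(key, sorted(known_sections), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            problems.append(f"unknown section {key!r}{suffix}")

    task_section = raw.get("task", "cue_accumulation")
    if isinstance(task_section, str):
        task_name, task_params = task_section, {}
    else:
        task_name = task_section.get("name", "cue_accumulation")
        task_params = {k: v for k, v in task_section.items() if k != "name"}
    if task_name not in TASKS:
        hint = difflib.get_close_matches(task_name, TASKS, n=1)
        suffix = f"; did you mean {hint[0]!r}?" if hint else ""
        problems.append(f"unknown task {task_name!r}{suffix}")

    network = None
    if "network" in raw:
        network = _build(NetworkConfig, "network", raw["network"], problems)
    learning = _build(LearningMode, "learning", raw.get("learning", {}), problems)
    rl = _build(RLConfig, "rl", raw.get("rl", {}), problems)
    run = _build(RunSettings, "run", raw.get("run", {}), problems)
    if problems:
        raise ConfigurationError("invalid configuration:\n  " + "\n  ".join(problems))
    return ExperimentConfig(network=network, learning=learning, rl=rl,
                            task=task_name, task_params=task_params, run=run)


def dump_config(cfg: ExperimentConfig, path) -> None:
    """Echo a resolved configuration back to YAML (round-trips identically)."""
    doc = {
        "network": asdict(cfg.network) if cfg.network is not None else None,
        "learning": asdict(cfg.learning),
        "rl": asdict(cfg.rl),
        "task": {"name": cfg.task, **cfg.task_params},
        "run": asdict(cfg.run),
    }
    if doc["network"] is None:
        del doc["network"]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
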