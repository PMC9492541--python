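"""Run configuration for the command-line pipeline.

One YAML file drives every subcommand.  Shape::

    seed: 1
    outdir: runs/demo
    inputs:              # paths, relative to the config file
      tree: fixture/tree.nwk
      events: fixture/events.tsv
      annotations: fixture/annotations.tsv
      composites: fixture/composites.tsv
      ko_classes: fixture/ko_classes.tsv
    category_sets:
      ktw: [K, T, W]
    focal:
      group_root: A1       # clade whose trajectory is analysed
      other_root: B1
      group_tips: [a1, a2, a3, a4]
      related_set: ktw     # category set used for shift tables
      tip: a1              # tip for path/contribution summaries
    simulator: {}          # SimConfig overrides for `simulate`
    classifier:
      cv_folds: 5
      min_inertia: 0.9
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    base_dir: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    category_sets: dict[str, set[str]] = field(default_factory=dict)
    focal: dict = field(default_factory=dict)
    simulator: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)

    def input_path(self, key: str, stage: str) -> Path:
        if key not in self.inputs:
            raise ConfigError(f"stage {stage!r} needs input {key!r} in the config")
        path = self.inputs[key]
        if not path.exists():
            raise ConfigError(f"stage {stage!r}: input {key!r} not found at {path}")
        return path

    def output_path(self, name: str) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        return self.outdir / name


def load_config(path: str | Path, seed: int | None = None,
                outdir: str | Path | None = None) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    base = path.parent
    eff_seed = seed if seed is not None else raw.get("seed")
    if eff_seed is None:
        raise ConfigError("a seed is mandatory (config `seed:` or --seed)")
    eff_outdir = Path(outdir) if outdir is not None else base / raw.get("outdir", "out")
    inputs = {k: (base / v) for k, v in (raw.get("inputs") or {}).items()}
    category_sets = {k: set(v) for k, v in (raw.get("category_sets") or {}).items()}
    return RunConfig(
        seed=int(eff_seed),
        outdir=eff_outdir,
        base_dir=base,
        inputs=inputs,
        category_sets=category_sets,
        focal=raw.get("focal") or {},
        simulator=raw.get("simulator") or {},
        classifier=raw.get("classifier") or {},
    )
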