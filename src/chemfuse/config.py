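"""Run configuration: one serialisable document driving every subcommand.

Defaults mirror the published workflow settings: 1024-bit radius-2
fingerprints, activity thresholds 5/7, screening hit threshold 0.8,
80/20 split with 5-fold CV.  Values may be overridden by a YAML config
file and by ``CHEMFUSE_``-prefixed environment variables (dots replaced
by double underscores, e.g. ``CHEMFUSE_FEATURIZE__FP_DIM=512``).
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    paths: dict = field(default_factory=lambda: {
        "ligand_table": "ligands.csv",
        "candidate_library": "candidates.csv",
        "output_dir": "out",
        "checkpoint": "fusion_model.npz",
    })
    thresholds: dict = field(default_factory=lambda: {
        "activity_low": 5.0,
        "activity_high": 7.0,
        "hit": 0.8,
        "lipinski": {"logp": 5.0, "mw": 500.0, "hbd": 5, "hba": 10},
    })
    featurize: dict = field(default_factory=lambda: {"fp_dim": 1024, "radius": 2})
    split: dict = field(default_factory=lambda: {"test_fraction": 0.2, "n_folds": 5})
    fusion: dict = field(default_factory=lambda: {
        "hidden_dim": 128, "n_heads": 4, "dropout": 0.2, "mlp_dims": [128, 32],
        "lr": 1e-3, "max_epochs": 50, "batch_size": 64,
        "plateau_patience": 5, "early_stop_patience": 10, "val_fraction": 0.15,
        "max_pairs": 4000,
    })
    screen: dict = field(default_factory=lambda: {"target_count": 100, "n_neighbors": 15, "min_dist": 0.1})
    cluster: dict = field(default_factory=lambda: {"k_min": 2, "k_max": 6, "n_init": 20})
    synthetic: dict = field(default_factory=lambda: {"n_ligands": 2000, "n_candidates": 500, "analog_fraction": 0.25})
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RunConfig":
        cfg = cls()
        if path is not None:
            with open(path) as fh:
                overrides = yaml.safe_load(fh) or {}
            cfg._merge(overrides)
        cfg._apply_env()
        return cfg

    def _merge(self, overrides: dict) -> None:
        for key, value in overrides.items():
            if not hasattr(self, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(self, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(self, key, value)

    def _apply_env(self) -> None:
        for name, raw in os.environ.items():
            if not name.startswith("CHEMFUSE_"):
                continue
            parts = name[len("CHEMFUSE_"):].lower().split("__")
            target = self
            try:
                for p in parts[:-1]:
                    target = getattr(target, p) if not isinstance(target, dict) else target[p]
                leaf = parts[-1]
                value = yaml.safe_load(raw)
                if isinstance(target, dict):
                    target[leaf] = value
                else:
                    setattr(target, leaf, value)
            except (AttributeError, KeyError):
                raise KeyError(f"environment override {name} does not match any config key")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
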