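"""Experiment configuration: YAML manifests validated up front.

Unknown keys are rejected so a typo in a manifest fails loudly before any
computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .knn import InsertLabelMode, KNNConfig
from .strategies import Strategy, UpdateConfig

__all__ = ["ExperimentConfig", "load_config"]


@dataclass
class ExperimentConfig:
    seed: int = 0
    classifier: str = "frnn"  # frnn | knn
    k: int = 5
    window_size: int = 0
    strategy: str = "probability"  # actual_class | probability | none
    insert_label_mode: str = "predicted"  # knn only
    n_folds: int = 10
    cfs: bool = True
    # synthetic generator
    n_subjects: int = 45
    n_per_subject: int = 150
    client_subject: int = 0
    n_features: int = 12
    drift: float = 1.0
    # descriptor grid
    channels: tuple[str, ...] = ("T5", "T6", "O1", "OZ", "O2")
    pairs: tuple[tuple[str, str], ...] = (("O1", "OZ"), ("OZ", "O2"))
    block: int = 10
    # paths
    table_path: str = ""
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.classifier not in ("frnn", "knn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        Strategy(self.strategy)
        InsertLabelMode(self.insert_label_mode)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def update_config(self) -> UpdateConfig:
        return UpdateConfig(
            k=self.k, window_size=self.window_size, strategy=Strategy(self.strategy)
        )

    def knn_config(self) -> KNNConfig:
        return KNNConfig(
            k=self.k,
            window_size=self.window_size,
            insert_label_mode=InsertLabelMode(self.insert_label_mode),
        )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment manifest."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "channels" in raw:
        raw["channels"] = tuple(raw["channels"])
    if "pairs" in raw:
        raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
    return ExperimentConfig(**raw)
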