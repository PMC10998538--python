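"""Run configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class RunConfig:
    """Hyperparameters of the full prediction pipeline.

    Defaults follow the published setup where one was stated (3-mers,
    128-dimensional piRNA embedding, 2 attention heads, 5% spies, 500-tree
    spy forest, decay theta = 0.5, 30 bags x 5 averaging rounds, 5 two-step
    iterations); the remaining knobs are the package's own defaults and are
    documented in docs/methods.md.
    """

    # sequence embedding
    kmer_k: int = 3
    word_dim: int = 64           # skip-gram vector size per 3-mer
    embed_dim: int = 128         # TextCNN output (piRNA embedding) size
    n_filters: int = 128         # filters per convolution kernel size
    kernel_sizes: tuple = (1, 3, 5)
    w2v_window: int = 5
    w2v_epochs: int = 5
    w2v_negative: int = 5
    train_textcnn: bool = True   # end-to-end by default; False freezes random filters

    # similarity
    sw_match: float = 2.0
    sw_mismatch: float = -1.0
    sw_gap: float = -1.0
    theta: float = 0.5           # semantic decay on the disease DAG

    # model
    gcn_layers: int = 2
    gcn_dim: int = 64            # width of each graph-convolution layer
    n_heads: int = 2
    final_relu: bool = True      # ReLU after the last graph-convolution layer
    lr: float = 1e-3
    epochs: int = 200

    # positive-unlabelled learning
    spy_frac: float = 0.05
    rf_estimators: int = 500     # spy classifier (stated)
    bag_estimators: int = 100    # per-bag forest ("small classifiers")
    two_step_estimators: int = 100
    n_bags: int = 30
    bag_rounds: int = 5
    two_step_iters: int = 5

    # evaluation
    cv_folds: int = 5
    report_window: int = 5       # metrics averaged over the last k epochs

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.spy_frac < 1:
            raise ValueError(f"spy_frac must be in (0,1), got {self.spy_frac}")
        if self.gcn_dim % self.n_heads != 0:
            raise ValueError(
                f"n_heads ({self.n_heads}) must divide gcn_dim ({self.gcn_dim})"
            )
        for name in ("kmer_k", "word_dim", "embed_dim", "n_filters", "gcn_layers",
                     "gcn_dim", "n_heads", "rf_estimators", "bag_estimators",
                     "two_step_estimators", "n_bags", "bag_rounds",
                     "two_step_iters", "cv_folds", "epochs", "report_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.theta < 1:
            raise ValueError(f"theta must be in (0,1), got {self.theta}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "kernel_sizes" in d:
            d["kernel_sizes"] = tuple(d["kernel_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
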