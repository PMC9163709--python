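"""Pipeline configuration: one YAML file drives every stage.

All defaults of the method live here in one place so deviations are
visible in diffs: 90 s target length, 256/128 STFT, 50 principal
components, component budget max(n/500, 15), 3/5 and 5/10 triplet counts,
margin 1.0, batch of 16 triplets, 256-dimensional embedding, top-5
retrieval. A single top-level seed determines every stochastic stage;
per-stage seeds are derived from it deterministically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

_STAGE_SALT = {
    "generate": 1,
    "preprocess": 2,
    "cluster": 3,
    "triplets": 4,
    "train": 5,
    "index": 6,
    "query": 7,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    workdir: str = "pipeline"
    # generate
    n_patients: int = 5
    records_per_template: int = 10
    record_duration_s: float = 90.0
    # preprocess
    preprocess: dict = field(default_factory=dict)
    # spectrogram
    spectrogram: dict = field(default_factory=dict)
    # clustering
    clustering: dict = field(
        default_factory=lambda: {"feature_source": "spectral_power"}
    )
    # triplets
    triplets: dict = field(
        default_factory=lambda: {
            "same_cluster": {"n_pos": 3, "n_neg": 5},
            "different_cluster": {"n_pos": 5, "n_neg": 10},
        }
    )
    # training
    training: dict = field(
        default_factory=lambda: {
            "embedding_dim": 256,
            "batch_triplets": 16,
            "learning_rate": 1e-5,
            "max_epochs": 10,
            "patience": 5,
            "margin": 1.0,
        }
    )
    # search
    search: dict = field(
        default_factory=lambda: {
            "method": "feature_pca_tsne_knn",
            "backend": "random_init",
            "k": 5,
            "knn_space": "tsne_2d",
        }
    )

    def stage_seed(self, stage: str) -> int:
        if stage not in _STAGE_SALT:
            raise ParameterError(f"unknown stage {stage!r}")
        # derived deterministically from the top-level seed; kept < 2**31
        return (self.seed * 1000 + _STAGE_SALT[stage]) % (2**31)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(
                f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def write_meta(artifact_path, cfg: PipelineConfig, stage: str, **extra) -> None:
    """Sidecar provenance: config digest + stage parameters per artifact."""
    meta = {"config_digest": cfg.digest(), "stage": stage,
            "seed": cfg.stage_seed(stage), **extra}
    Path(str(artifact_path) + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1)
    )
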