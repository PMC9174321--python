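"""Checkpoint and run-manifest I/O.

Checkpoints bundle network weights with the config that produced them, so
predicting with a mismatched tile geometry or channel count fails fast.
Every pipeline run emits a manifest recording the config hash, input
checksums, per-stage timing and record counts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .mil import MILConfig, ModelHandle, build_backbone
from .segmentation import SegTrainConfig, UNet, build_unet

__all__ = ["save_mil_checkpoint", "load_mil_checkpoint", "save_unet_checkpoint",
           "load_unet_checkpoint", "RunManifest", "file_checksum"]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_mil_checkpoint(handle: ModelHandle, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": handle.config.__dict__, "history": handle.history,
            "version": __version__}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **handle.backbone.state_dict())


def load_mil_checkpoint(path) -> ModelHandle:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    config = MILConfig(**meta["config"])
    backbone = build_backbone(config.backbone_variant, seed=config.seed)
    backbone.load_state_dict(state)
    backbone.eval()
    handle = ModelHandle(backbone, config)
    handle.history = meta["history"]
    return handle


def save_unet_checkpoint(model: UNet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.config.__dict__, "version": __version__}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_unet_checkpoint(path) -> UNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_unet(SegTrainConfig(**meta["config"]))
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config_hash: str
    tool_version: str = __version__
    stages: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def start_stage(self, name: str) -> float:
        return time.perf_counter()

    def end_stage(self, name: str, t0: float, *, reused: bool = False,
                  **counts) -> None:
        self.stages[name] = {"seconds": round(time.perf_counter() - t0, 3),
                             "reused": reused, **counts}

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_checksum(path)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "tool_version": self.tool_version,
             "stages": self.stages, "inputs": self.inputs}, indent=2))
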