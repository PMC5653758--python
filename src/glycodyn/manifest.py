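"""Run provenance: config snapshot, seed, input digests, outputs, timing."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a deterministic run byte-for-byte."""

    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    status: str = "running"
    wall_time_s: float | None = None
    tool_version: str = __version__
    _t0: float = field(default_factory=time.monotonic, repr=False)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def finish(self, status: str = "ok") -> None:
        self.status = status
        self.wall_time_s = round(time.monotonic() - self._t0, 3)

    def write(self, path: str | Path) -> None:
        payload = {
            "tool_version": self.tool_version,
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "status": self.status,
            "wall_time_s": self.wall_time_s,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
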