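"""Reproducibility manifests: every CLI run records what produced its outputs."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import __version__

__all__ = ["write_manifest"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, command: str, config: dict, seeds: list[int],
                   inputs: list | None = None, outputs: list | None = None) -> Path:
    """Write a JSON manifest next to ``out_path`` and return its path.

    Records the subcommand, the full config snapshot, every RNG seed, the
    package version, SHA-256 digests of input/output files and wall-clock
    timestamps, so any output CSV can be regenerated exactly.
    """
    out_path = Path(out_path)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "package": "flagrow",
        "version": __version__,
        "inputs": {str(p): _digest(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "outputs": {str(p): _digest(Path(p)) for p in (outputs or []) if Path(p).exists()},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    mpath = out_path.with_suffix(out_path.suffix + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return mpath
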