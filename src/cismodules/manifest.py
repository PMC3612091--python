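"""Run manifests: parameters, seed, input checksums, version, timestamp."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

from . import __version__

MANIFEST_NAME = "manifest.json"


@dataclass
class RunManifest:
    command: str
    parameters: dict
    seed: int | None
    inputs: dict[str, str]
    version: str
    timestamp: str


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def build_manifest(
    command: str,
    parameters: Mapping,
    seed: int | None,
    input_paths: Iterable[str | Path],
) -> RunManifest:
    return RunManifest(
        command=command,
        parameters=dict(parameters),
        seed=seed,
        inputs={str(p): sha256_file(p) for p in input_paths},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    path = Path(out_dir) / MANIFEST_NAME
    with open(path, "w") as handle:
        json.dump(asdict(manifest), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path
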