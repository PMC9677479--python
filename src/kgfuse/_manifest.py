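"""Reproducibility manifests: parameters + content hashes of artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    params: dict,
    artifacts: list[str | Path],
) -> Path:
    """Write <stage>.manifest.json recording parameters and artifact hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "params": params,
        "artifacts": {
            str(Path(a).name): sha256_of(a) for a in artifacts if Path(a).exists()
        },
    }
    path = out_dir / f"{stage}.manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
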