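"""Run manifests: seeds, config hashes, and file digests for reproducibility."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _version() -> str:
    try:
        return version("misosip")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(out_dir: str | Path, command: str, seed: int | None,
                   config, outputs: list[str | Path]) -> Path:
    """Write ``manifest.json`` into an output directory and return its path."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": sha256_obj(config),
        "artifact_version": _version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": {
            str(Path(p).name): sha256_file(p) for p in outputs
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash the listed outputs and compare with the recorded digests."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return all(sha256_file(out_dir / name) == digest
               for name, digest in manifest["outputs"].items())
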