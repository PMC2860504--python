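"""Run manifests: JSON sidecars recording how an output was produced."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_path, command: str, parameters: dict,
                   input_paths: dict, seed=None,
                   started: str | None = None) -> Path:
    """Write ``<output>.manifest.json`` next to an output file.

    Records the command, all resolved parameters, SHA-256 digests of the
    inputs, the package version, the seed, and wall-clock timestamps.
    """
    manifest = {
        "command": command,
        "parameters": {k: v for k, v in sorted(parameters.items())},
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in sorted(input_paths.items())},
        "package_version": __version__,
        "seed": seed,
        "started": started,
        "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(str(output_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def timestamp() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
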