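"""Run manifests: enough metadata beside every output to replay the run."""

from __future__ import annotations

import datetime
import json
from pathlib import Path

from . import __version__


def write_manifest(path, command: str, argv: list[str], params: dict, seed) -> Path:
    """Write a JSON run manifest and return its path.

    Replaying the recorded ``argv`` (see the ``rerun`` subcommand) reproduces
    all outputs bit-for-bit; the timestamp is informational only.
    """
    path = Path(path)
    payload = {
        "command": command,
        "argv": list(argv),
        "params": params,
        "seed": seed,
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path) -> dict:
    data = json.loads(Path(path).read_text())
    for key in ("command", "argv"):
        if key not in data:
            raise ValueError(f"manifest {path} lacks required key {key!r}")
    return data
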