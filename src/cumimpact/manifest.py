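"""Run manifests: reproducibility metadata for every CLI invocation."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Records inputs, seeds and checksummed outputs of one pipeline run.

    Re-running a deterministic stage with identical inputs must reproduce
    identical output checksums; the manifest is the audit trail for that.
    """

    def __init__(self, command: str, seed: int | None = None):
        self.data = {
            "tool": "cumimpact",
            "version": __version__,
            "command": command,
            "seed": seed,
            "started_utc": datetime.datetime.now(
                datetime.timezone.utc).isoformat(),
            "inputs": {},
            "outputs": {},
        }

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        self.data["inputs"][str(path)] = sha256_of(path)

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.data["outputs"][str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.data["finished_utc"] = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path
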