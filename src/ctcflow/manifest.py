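"""Reproducibility bookkeeping: run manifests and atomic output writing."""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from importlib.metadata import PackageNotFoundError, version


def _code_version() -> str:
    try:
        return version("ctcflow")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, seeds, units, files."""

    config: dict
    seeds: dict
    units: dict = dc_field(default_factory=dict)
    code_version: str = dc_field(default_factory=_code_version)
    inventory: list = dc_field(default_factory=list)

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("a run manifest must record explicit seeds")

    def to_json(self) -> str:
        return json.dumps({
            "code_version": self.code_version,
            "config": self.config,
            "seeds": self.seeds,
            "units": self.units,
            "inventory": self.inventory,
        }, indent=2, sort_keys=True, default=str)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(config=data["config"], seeds=data["seeds"],
                   units=data.get("units", {}),
                   code_version=data.get("code_version", "unknown"),
                   inventory=data.get("inventory", []))


def write_outputs(writers: dict, manifest: RunManifest, outdir) -> list:
    """Write all artifacts atomically and record their checksums.

    ``writers`` maps relative file names to callables taking the target
    path. Files land in a temporary sibling directory first; only when
    every writer succeeds are they moved into ``outdir`` (so a failed
    run leaves no partial inventory). Returns the inventory, which is
    also stored on the manifest and written as ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".ctcflow-", dir=outdir))
    inventory = []
    try:
        for name, writer in writers.items():
            target = tmp / name
            target.parent.mkdir(parents=True, exist_ok=True)
            writer(target)
            inventory.append({"path": name, "sha256": sha256_file(target),
                              "bytes": target.stat().st_size})
        for name in writers:
            dest = outdir / name
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(tmp / name), dest)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    shutil.rmtree(tmp, ignore_errors=True)
    manifest.inventory = inventory
    manifest.save(outdir / "manifest.json")
    return inventory
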