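"""Layered run configuration and deterministic seed fan-out.

Every stochastic operation in a run receives an explicit seed derived from
one root seed by hashing a label path (``spawn_seed(root, "train",
"whole", "axial")``), so stages are independently reproducible: rerunning
one stage never perturbs another's random stream.

Configuration values are merged with precedence defaults < file < flags,
and each value remembers where it came from (provenance), which the CLI
records in its run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def spawn_seed(root_seed: int, *labels) -> int:
    """Derive a child seed (< 2^31) from a root seed and a label path."""
    key = json.dumps([int(root_seed)] + [str(l) for l in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Merged configuration document with per-key provenance."""

    values: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_layers(cls, defaults: dict, file_path=None, flags: dict | None = None):
        cfg = cls()
        cfg._merge(defaults, "default")
        if file_path is not None:
            loaded = yaml.safe_load(Path(file_path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {file_path} must hold a mapping")
            cfg._merge(loaded, str(file_path))
        if flags:
            cfg._merge({k: v for k, v in flags.items() if v is not None}, "flag")
        return cfg

    def _merge(self, values: dict, source: str):
        for k, v in values.items():
            self.values[k] = v
            self.provenance[k] = source

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)

    def manifest(self, extra: dict | None = None) -> dict:
        doc = {
            "config": self.values,
            "provenance": self.provenance,
        }
        if extra:
            doc.update(extra)
        doc["config_hash"] = hashlib.sha256(
            json.dumps(self.values, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return doc
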