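"""Shared helpers: named random substreams, config hashing, versioning."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from typing import Any

import numpy as np

__all__ = ["substream", "substream_seed", "config_hash", "to_jsonable"]


def substream_seed(root_seed: int, name: str) -> int:
    """Derive a deterministic child seed (< 2**31) from a root seed and name."""
    return (int(root_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Named, independent random generator derived from one root seed.

    All randomness in the package (weight init, shuffling, augmentation,
    synthetic data) flows through these substreams so that experiments
    are reproducible from a single integer.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())])
    )


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy scalars to JSON-safe values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(obj: Any) -> str:
    """Stable short hash of a configuration object (dataclass or dict)."""
    payload = json.dumps(to_jsonable(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
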