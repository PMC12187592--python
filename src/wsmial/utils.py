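"""Seeding helpers: one global seed fans out to named per-component streams."""

from __future__ import annotations

import zlib

import numpy as np


def seed_stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic, independent generator for a named component.

    The stream identity is the CRC32 of the name, so the mapping is stable
    across runs and platforms.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])
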