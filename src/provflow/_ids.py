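"""Identifier and clock providers.

Identifiers are UUIDv4 strings.  By default they come from :func:`uuid.uuid4`;
a seeded provider draws the 16 random bytes from a NumPy generator instead so
that a whole workspace (demo data, tests) can be rebuilt bit-identically from
a seed.  Timestamps default to the real clock but can likewise be replaced by
a deterministic synthetic clock.
"""

from __future__ import annotations

import datetime as _dt
import uuid

import numpy as np


class IdGen:
    """UUIDv4 factory, optionally seeded for reproducibility."""

    def __init__(self, seed: int | None = None):
        self._rng = None if seed is None else np.random.default_rng(seed)

    def __call__(self) -> str:
        if self._rng is None:
            return str(uuid.uuid4())
        raw = bytes(self._rng.bytes(16))
        return str(uuid.UUID(bytes=raw, version=4))


class Clock:
    """ISO-8601 timestamp source with explicit UTC offset.

    A seeded clock starts at a fixed epoch and advances by a fixed increment
    per call, which keeps serialized workspaces reproducible.
    """

    _EPOCH = _dt.datetime(2018, 7, 2, 8, 0, 0, tzinfo=_dt.timezone.utc)

    def __init__(self, synthetic: bool = False):
        self._synthetic = synthetic
        self._ticks = 0

    def __call__(self) -> str:
        if self._synthetic:
            t = self._EPOCH + _dt.timedelta(minutes=self._ticks)
            self._ticks += 1
            return t.isoformat()
        return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


#: module-level defaults used when no provider is passed explicitly
default_idgen = IdGen()
default_clock = Clock()
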