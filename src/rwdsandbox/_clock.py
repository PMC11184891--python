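"""Injectable clocks.

Every agent takes a ``clock`` callable returning the current POSIX timestamp
(float seconds).  Production code uses :func:`system_clock`; tests inject a
:class:`FakeClock` so expiry, scheduling and heartbeat logic are deterministic.
"""

from __future__ import annotations

import time
from datetime import datetime, timezone


def system_clock() -> float:
    return time.time()


def to_iso(ts: float) -> str:
    """ISO-8601 UTC with microseconds, the timestamp format used everywhere."""
    return datetime.fromtimestamp(ts, tz=timezone.utc).isoformat()


def from_iso(s: str) -> float:
    return datetime.fromisoformat(s).timestamp()


class FakeClock:
    """Monotone fake clock for tests."""

    def __init__(self, start: float = 1_700_000_000.0):
        self._now = float(start)

    def __call__(self) -> float:
        return self._now

    def advance(self, seconds: float) -> float:
        if seconds < 0:
            raise ValueError("clock must be monotone")
        self._now += seconds
        return self._now

    def set(self, ts: float) -> None:
        if ts < self._now:
            raise ValueError("clock must be monotone")
        self._now = ts
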