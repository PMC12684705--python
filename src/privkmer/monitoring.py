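"""Phase timing and peak-memory reporting.

Each pipeline stage (encrypt, evaluate, decrypt) is wrapped in a phase;
file reads/writes inside a phase are additionally wrapped in ``io()`` so a
phase's wall clock splits into I/O and compute. Peak RSS comes from
``resource.getrusage`` and is reported, never asserted — it is hardware-
and allocator-dependent.
"""

from __future__ import annotations

import json
import resource
import time
from contextlib import contextmanager


def peak_rss_mb() -> float:
    # ru_maxrss is KiB on Linux.
    return resource.getrusage(resource.RUSAGE_SELF).ru_maxrss / 1024.0


class PhaseTimer:
    """Accumulates wall/I-O/compute time per named phase."""

    def __init__(self):
        self.phases: dict[str, dict] = {}
        self._active: str | None = None

    @contextmanager
    def phase(self, name: str):
        entry = self.phases.setdefault(name, {"wall": 0.0, "io": 0.0})
        prev, self._active = self._active, name
        t0 = time.perf_counter()
        try:
            yield
        finally:
            entry["wall"] += time.perf_counter() - t0
            self._active = prev

    @contextmanager
    def io(self):
        name = self._active
        t0 = time.perf_counter()
        try:
            yield
        finally:
            if name is not None:
                self.phases[name]["io"] += time.perf_counter() - t0

    def report(self) -> dict:
        out = {"peak_rss_mb": round(peak_rss_mb(), 1), "phases": {}}
        for name, e in self.phases.items():
            wall, io = e["wall"], min(e["io"], e["wall"])
            compute = wall - io
            out["phases"][name] = {
                "wall_s": round(wall, 4),
                "io_s": round(io, 4),
                "compute_s": round(compute, 4),
                "io_pct": round(100.0 * io / wall, 2) if wall else 0.0,
                "compute_pct": round(100.0 * compute / wall, 2) if wall else 0.0,
            }
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=1)
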