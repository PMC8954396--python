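"""Plan long-range PCR amplicon windows that tile each contig.

Per contig the window count is the provable minimum k = ceil(len /
max_len); windows are equal-length (ceil(len/k), raised to min_len when
the equal split would fall short) and their start points are spread by
the largest-remainder rule so total overlap is minimal and distributed
as evenly as possible.  Output coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence


@dataclasses.dataclass
class AmpliconPlan:
    windows: list[tuple[str, int, int]]
    min_len: int
    max_len: int

    @property
    def total_len(self) -> int:
        return sum(e - s for _, s, e in self.windows)

    def to_bed(self) -> str:
        return "".join(f"{c}\t{s}\t{e}\n" for c, s, e in self.windows)

    def summary(self) -> dict:
        return {"n_windows": len(self.windows), "total_bp": self.total_len}


def plan_amplicons(
    contigs: Sequence[tuple[str, int]], min_len: int = 10_000, max_len: int = 12_000
) -> AmpliconPlan:
    """Tile each contig with the minimum number of [min_len, max_len] windows.

    Contigs shorter than ``min_len`` are skipped with a warning.  For each
    planned contig the windows jointly cover every position; consecutive
    windows overlap only as much as the length arithmetic forces.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if min_len < 1:
        raise ValueError("window lengths must be positive")
    windows: list[tuple[str, int, int]] = []
    for name, length in contigs:
        if length < min_len:
            warnings.warn(f"contig {name!r} ({length} bp) shorter than min_len; skipped")
            continue
        k = math.ceil(length / max_len)
        w = max(math.ceil(length / k), min_len)
        if k == 1:
            windows.append((name, 0, length))
            continue
        # largest-remainder spread of start points over [0, length - w]
        span = length - w
        for i in range(k):
            start = round(i * span / (k - 1))
            windows.append((name, start, start + w))
    return AmpliconPlan(windows=windows, min_len=min_len, max_len=max_len)
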