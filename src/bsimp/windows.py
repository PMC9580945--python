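"""Sliding windows of consecutive context cytosines.

A window is w consecutive sites from one (chrom, strand, context) stream
together with the read x site status matrix over every read contributing at
least one call inside it.  Windows slide one cytosine at a time, so
neighbouring windows share w-1 sites; they never cross a chromosome or
strand boundary, and by default may span any genomic distance between
consecutive context sites.

Rows are classified by how much of the pattern is observed: complete
(no missing cell), eligible (exactly one missing cell -- the only rows the
imputer touches) and observed-only (two or more missing).  A cell is
MISSING whether the site lies outside the read's alignment span or inside
it without a call; the method only distinguishes observed vs not.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .readcalls import ReadCall
from .sites import SiteIndex

MISSING = -1


@dataclass(slots=True)
class Window:
    chrom: str
    strand: str
    context: str
    sites: np.ndarray  # w ascending 1-based positions
    read_ids: list[str]
    matrix: np.ndarray  # (n_reads, w) int8 in {1, 0, MISSING}
    offset: int = 0  # index of sites[0] in the (chrom, strand, context) stream

    @property
    def w(self) -> int:
        return int(self.sites.size)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def start(self) -> int:
        return int(self.sites[0])

    def missing_counts(self) -> np.ndarray:
        return (self.matrix == MISSING).sum(axis=1)

    def complete_rows(self) -> list[int]:
        return [i for i, m in enumerate(self.missing_counts()) if m == 0]

    def eligible_rows(self) -> list[int]:
        return [i for i, m in enumerate(self.missing_counts()) if m == 1]

    def observed_only_rows(self) -> list[int]:
        return [i for i, m in enumerate(self.missing_counts()) if m >= 2]

    def dump(self) -> str:
        """Small text rendering of the status matrix, for logs."""
        lines = [f"{self.chrom}:{self.start} {self.strand} {self.context} w={self.w}"]
        sym = {1: "M", 0: "U", MISSING: "."}
        for rid, row in zip(self.read_ids, self.matrix):
            lines.append(f"  {rid}\t" + "".join(sym[int(v)] for v in row))
        return "\n".join(lines)


def classify_rows(window: Window) -> tuple[list[int], list[int], list[int]]:
    """Partition row indices into (complete, eligible, observed-only).

    Deterministic and order-preserving: each list keeps the window's row
    order.
    """
    return window.complete_rows(), window.eligible_rows(), window.observed_only_rows()


def build_windows(
    reads: Iterable[ReadCall],
    site_index: SiteIndex,
    w: int,
    context: str = "CG",
    max_gap: int | None = None,
) -> Iterator[Window]:
    """Yield every populated sliding window over each (chrom, strand) stream.

    Windows step one cytosine at a time; a window is materialized only when
    at least one read contributes a call inside it (a read appears as a row
    iff it has >=1 call at the window's sites, so every row has at least one
    observed entry).  Within a row, MISSING marks window sites lacking a
    call, whether inside or outside the read's span.

    ``max_gap``, when set, suppresses windows where two adjacent sites are
    more than that many bases apart on the genome.
    """
    if w < 2:
        raise ValueError(f"window size must be >= 2 cytosines, got {w}")
    by_stream: dict[tuple[str, str], list[ReadCall]] = {}
    for r in reads:
        by_stream.setdefault((r.chrom, r.strand), []).append(r)

    for chrom, strand in sorted(by_stream):
        positions = site_index.positions(chrom, strand, context)
        n = positions.size
        if n < w:
            continue
        pos_to_idx = {int(p): i for i, p in enumerate(positions)}
        # offset -> rows, preserving read input order
        members: dict[int, list[tuple[str, list[int]]]] = {}
        for r in by_stream[(chrom, strand)]:
            call_idx = sorted(pos_to_idx[p] for p in r.calls if p in pos_to_idx)
            if not call_idx:
                continue
            lo = max(0, call_idx[0] - w + 1)
            hi = min(n - w, call_idx[-1])
            for o in range(lo, hi + 1):
                # row only if the read has a call among sites [o, o+w-1]
                k = bisect_left(call_idx, o)
                if k < len(call_idx) and call_idx[k] <= o + w - 1:
                    members.setdefault(o, []).append((r.read_id, call_idx))
        calls_by_id = {r.read_id: r.calls for r in by_stream[(chrom, strand)]}
        for o in sorted(members):
            win_sites = positions[o : o + w]
            if max_gap is not None and int(np.diff(win_sites).max()) > max_gap:
                continue
            rows = members[o]
            matrix = np.full((len(rows), w), MISSING, dtype=np.int8)
            read_ids = []
            for i, (rid, _) in enumerate(rows):
                calls = calls_by_id[rid]
                for j, p in enumerate(win_sites):
                    v = calls.get(int(p))
                    if v is not None:
                        matrix[i, j] = v
                read_ids.append(rid)
            yield Window(chrom, strand, context.upper(), win_sites.copy(), read_ids, matrix, o)
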