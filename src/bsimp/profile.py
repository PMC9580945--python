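"""Genome screening: impute every sliding window and profile its patterns.

The screening output is one vector per window start: chromosome, position
of the first cytosine, strand, the copy number of every possible
methylation pattern of length w starting there, and the number of
methylated and unmethylated statuses at each of the w sites.  Pattern copy
numbers feed methylation-heterogeneity statistics downstream; site counts
give methylation levels.

Pattern encoding: patterns are indexed by their binary value with site 1 as
the most significant bit and methylated = 1, so for w=3 index 0 is UUU and
index 7 is MMM.  This fixed bit order makes outputs bit-exact across
implementations.

Imputation is strictly window-local: a read overlapping several windows may
receive different imputations in each, and every profile is self-consistent
for its own window.  For read-level export, each cell takes its imputation
from the first (leftmost) window that imputes it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .impute import UNASSIGNED, ImputedCell, impute_window
from .readcalls import ReadCall
from .sites import SiteIndex
from .windows import MISSING, Window, build_windows

logger = logging.getLogger(__name__)

LEVEL_STATS = ("max", "mean")


@dataclass(slots=True)
class PatternProfile:
    """Per-window-start output vector.

    ``pattern_counts`` has 2^w entries (see module docstring for the bit
    order); their sum is ``n_complete_after``, the number of rows complete
    after merging assigned imputations.  ``site_counts`` is a (w, 2) array
    of (n_meth, n_unmeth) per site over all rows observed-or-imputed there.
    """

    chrom: str
    start: int
    strand: str
    w: int
    pattern_counts: np.ndarray
    site_counts: np.ndarray
    n_complete_after: int
    sites: np.ndarray | None = None  # all w site positions; not serialized

    def depths(self) -> np.ndarray:
        return self.site_counts.sum(axis=1)

    def levels(self) -> np.ndarray:
        """Per-site methylation level; sites with zero depth report 0."""
        d = self.depths()
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(d > 0, self.site_counts[:, 0] / np.maximum(d, 1), 0.0)
        return lv


def pattern_name(index: int, w: int) -> str:
    """Status string for a pattern index, e.g. index 5, w=3 -> 'MUM'."""
    return "".join("M" if (index >> (w - 1 - j)) & 1 else "U" for j in range(w))


def pattern_index(statuses: Sequence[int]) -> int:
    idx = 0
    for v in statuses:
        idx = (idx << 1) | int(v)
    return idx


def profile_window(window: Window, imputed: Iterable[ImputedCell]) -> PatternProfile:
    """Tally pattern copy numbers and per-site counts after imputation.

    Rows that become complete once assigned imputations are merged each
    contribute one pattern count; UNASSIGNED cells leave their rows out of
    the pattern tally but their rows' observed statuses still count toward
    site totals.
    """
    w = window.w
    mat = window.matrix.copy()
    for cell in imputed:
        if not (0 <= cell.row < window.n_reads) or window.read_ids[cell.row] != cell.read_id:
            raise ValueError(f"imputed cell references unknown row: {cell!r}")
        if cell.assigned != UNASSIGNED:
            mat[cell.row, cell.j - 1] = cell.assigned
    pattern_counts = np.zeros(2**w, dtype=np.int64)
    n_complete = 0
    for row in mat:
        if (row != MISSING).all():
            pattern_counts[pattern_index(row)] += 1
            n_complete += 1
    site_counts = np.stack(
        [(mat == 1).sum(axis=0), (mat == 0).sum(axis=0)], axis=1
    ).astype(np.int64)
    return PatternProfile(
        chrom=window.chrom,
        start=window.start,
        strand=window.strand,
        w=w,
        pattern_counts=pattern_counts,
        site_counts=site_counts,
        n_complete_after=n_complete,
        sites=window.sites.copy(),
    )


def screen_genome(
    reads: Iterable[ReadCall],
    site_index: SiteIndex,
    w: int,
    context: str = "CG",
    min_complete: int = 2,
    min_depth: int = 0,
    min_level: float = 0.0,
    assign_mode: str = "sample",
    seed: int = 0,
    level_stat: str = "max",
    max_gap: int | None = None,
) -> Iterator[PatternProfile]:
    """Impute and profile every sliding window, applying output filters.

    A profile is emitted iff, after imputation, the window has at least
    ``min_complete`` complete patterns, every site has depth >=
    ``min_depth``, and the window-level methylation statistic (maximum
    per-site level by default, mean with ``level_stat='mean'``) is >=
    ``min_level``.  ``min_complete`` below 2 is rejected: imputation itself
    needs two complete patterns.
    """
    if min_complete < 2:
        raise ValueError("min_complete must be >= 2 (imputation needs two complete patterns)")
    if level_stat not in LEVEL_STATS:
        raise ValueError(f"level_stat must be one of {LEVEL_STATS}")
    reads = list(reads)
    read_chroms = {r.chrom for r in reads}
    known = set(site_index.chroms())
    unknown = read_chroms - known
    if unknown and not (read_chroms & known):
        raise ValueError(
            f"read chromosomes {sorted(unknown)} not present in the site index"
        )
    for window in build_windows(reads, site_index, w, context, max_gap=max_gap):
        cells = impute_window(window, assign_mode=assign_mode, rng_seed=seed)
        prof = profile_window(window, cells)
        if prof.n_complete_after < min_complete:
            continue
        depths = prof.depths()
        if (depths < min_depth).any():
            continue
        if min_level > 0:
            levels = prof.levels()[depths > 0]
            stat = 0.0 if levels.size == 0 else (
                float(levels.max()) if level_stat == "max" else float(levels.mean())
            )
            if stat < min_level:
                continue
        yield prof


def write_profiles(
    profiles: Iterable[PatternProfile],
    sink: str | Path | IO[str],
    w: int,
) -> int:
    """Write profiles as TSV; returns the number of data rows.

    Columns: chrom, start, strand, n_complete, one column per pattern
    (named by its status string, UUU..MMM in index order), then
    meth_j/unmeth_j for each site j = 1..w.  An empty stream yields a
    header-only file.
    """
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", newline="") if own else sink
    n = 0
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["chrom", "start", "strand", "n_complete"]
        header += [pattern_name(k, w) for k in range(2**w)]
        for j in range(1, w + 1):
            header += [f"meth_{j}", f"unmeth_{j}"]
        writer.writerow(header)
        for p in profiles:
            if p.w != w:
                raise ValueError(f"profile has w={p.w}, writer configured for w={w}")
            row = [p.chrom, p.start, p.strand, p.n_complete_after]
            row += [int(c) for c in p.pattern_counts]
            for j in range(w):
                row += [int(p.site_counts[j, 0]), int(p.site_counts[j, 1])]
            writer.writerow(row)
            n += 1
    finally:
        if own:
            fh.close()
    return n


def read_profiles(source: str | Path | IO[str]) -> list[PatternProfile]:
    """Re-read a profile TSV written by :func:`write_profiles` losslessly."""
    own = isinstance(source, (str, Path))
    fh = open(source, newline="") if own else source
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        n_patterns = sum(1 for h in header if set(h) <= {"M", "U"} and h)
        w = n_patterns.bit_length() - 1
        if 2**w != n_patterns:
            raise ValueError(f"malformed header: {n_patterns} pattern columns")
        out = []
        for row in reader:
            chrom, start, strand, n_complete = row[0], int(row[1]), row[2], int(row[3])
            counts = np.asarray([int(v) for v in row[4 : 4 + n_patterns]], dtype=np.int64)
            rest = [int(v) for v in row[4 + n_patterns : 4 + n_patterns + 2 * w]]
            site_counts = np.asarray(rest, dtype=np.int64).reshape(w, 2)
            out.append(PatternProfile(chrom, start, strand, w, counts, site_counts, n_complete))
        return out
    finally:
        if own:
            fh.close()


def write_bedgraph(
    profiles: Iterable[PatternProfile],
    sink: str | Path | IO[str],
) -> int:
    """Export per-site methylation levels as bedGraph (0-based half-open).

    A site covered by several overlapping windows is written once, from the
    first (leftmost) window reporting it.
    """
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    seen: set[tuple[str, str, int]] = set()
    n = 0
    try:
        for p in profiles:
            if p.sites is None:
                raise ValueError("bedGraph export needs profiles carrying site positions")
            levels = p.levels()
            depths = p.depths()
            for j in range(p.w):
                pos = int(p.sites[j])
                key = (p.chrom, p.strand, pos)
                if key in seen or depths[j] == 0:
                    continue
                seen.add(key)
                fh.write(f"{p.chrom}\t{pos - 1}\t{pos}\t{levels[j]:.6g}\n")
                n += 1
    finally:
        if own:
            fh.close()
    return n


def impute_read_level(
    reads: Iterable[ReadCall],
    site_index: SiteIndex,
    w: int,
    context: str = "CG",
    assign_mode: str = "sample",
    seed: int = 0,
) -> list[ReadCall]:
    """Read-level export: merge each cell's first (leftmost) imputation.

    Returns new ReadCalls whose call maps contain the original observed
    calls plus, for each (read, site) cell imputed in at least one window,
    the assigned status from the leftmost window that imputed it.  Observed
    calls are never overwritten; UNASSIGNED cells add nothing.
    """
    reads = list(reads)
    filled: dict[tuple[str, str, str], dict[int, int]] = {}
    for window in build_windows(reads, site_index, w, context):
        for cell in impute_window(window, assign_mode=assign_mode, rng_seed=seed):
            if cell.assigned == UNASSIGNED:
                continue
            per_read = filled.setdefault((window.chrom, window.strand, cell.read_id), {})
            per_read.setdefault(cell.site_position, cell.assigned)
    out = []
    for r in reads:
        calls = dict(r.calls)
        for pos, status in filled.get((r.chrom, r.strand, r.read_id), {}).items():
            calls.setdefault(pos, status)
        out.append(ReadCall(r.read_id, r.chrom, r.strand, dict(sorted(calls.items())), r.span))
    return out
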