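"""Per-read methylation calls.

The unit of information for pattern analysis is not the per-site
methylation level but the ordered vector of binary statuses one sequencing
read reports at consecutive context cytosines: each read stands for one
molecule, hence one cell, so read identity must be preserved.  This module
parses such calls from Bismark-style SAM/BAM (the XM per-base call string)
or from a plain per-call TSV, and restricts them to indexed context sites.

A "missing" status is never stored: it is representable only by the absence
of a position from a read's call map.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .sites import SiteIndex, _normalize_context

logger = logging.getLogger(__name__)

TSV_COLUMNS = ("read_id", "chrom", "strand", "position", "status")

# Bismark per-base call letters: lowercase = unmethylated, uppercase = methylated.
_BISMARK_CODE = {
    "z": ("CG", 0),
    "Z": ("CG", 1),
    "x": ("CHG", 0),
    "X": ("CHG", 1),
    "h": ("CHH", 0),
    "H": ("CHH", 1),
}


@dataclass(slots=True)
class ReadCall:
    """One read's (or fragment's) methylation statuses at context sites.

    ``calls`` maps 1-based site position to status (1 methylated,
    0 unmethylated); ``span`` is the closed interval of forward-strand
    coordinates covered by the alignment (for TSV input, by the calls).
    ``strand`` is the strand whose context-site stream this read reports on.
    """

    read_id: str
    chrom: str
    strand: str
    calls: dict[int, int] = field(default_factory=dict)
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        for pos, status in self.calls.items():
            if status not in (0, 1):
                raise ValueError(f"call status must be 0/1, got {status!r} at {pos}")
        if self.calls:
            lo, hi = min(self.calls), max(self.calls)
            if self.span == (0, 0):
                self.span = (lo, hi)
            else:  # span must contain every call position
                self.span = (min(self.span[0], lo), max(self.span[1], hi))


def parse_tsv_calls(source: str | Path | IO[str]) -> list[ReadCall]:
    """Parse the per-call TSV dialect into ReadCalls.

    The file must carry the header ``read_id chrom strand position status``
    (tab-separated).  Rows are grouped by (read_id, chrom, strand) in order
    of first appearance, independent of row order; a duplicate
    (read_id, chrom, strand, position) row is an error, as is any malformed
    row (reported with its line number).
    """
    own = isinstance(source, (str, Path))
    fh = open(source, newline="") if own else source
    try:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty TSV: missing header") from None
        if tuple(h.strip() for h in header[: len(TSV_COLUMNS)]) != TSV_COLUMNS:
            raise ValueError(
                f"bad TSV header {header!r}; expected columns {list(TSV_COLUMNS)}"
            )
        grouped: dict[tuple[str, str, str], dict[int, int]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 5:
                raise ValueError(f"line {lineno}: expected 5 fields, got {len(row)}")
            read_id, chrom, strand, pos_s, status_s = (v.strip() for v in row[:5])
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: strand must be + or -, got {strand!r}")
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"line {lineno}: bad position {pos_s!r}") from None
            if pos < 1:
                raise ValueError(f"line {lineno}: position must be >= 1, got {pos}")
            if status_s not in ("0", "1"):
                raise ValueError(f"line {lineno}: status must be 0 or 1, got {status_s!r}")
            key = (read_id, chrom, strand)
            calls = grouped.setdefault(key, {})
            if pos in calls:
                raise ValueError(
                    f"line {lineno}: duplicate call for read {read_id!r} at position {pos}"
                )
            calls[pos] = int(status_s)
    finally:
        if own:
            fh.close()
    out = []
    for (read_id, chrom, strand), calls in grouped.items():
        ordered = dict(sorted(calls.items()))
        out.append(
            ReadCall(read_id, chrom, strand, ordered, (min(ordered), max(ordered)))
        )
    return out


def write_tsv_calls(reads: Iterable[ReadCall], sink: str | Path | IO[str]) -> int:
    """Write ReadCalls in the TSV dialect; returns the number of call rows."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", newline="") if own else sink
    n = 0
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for r in reads:
            for pos in sorted(r.calls):
                writer.writerow([r.read_id, r.chrom, r.strand, pos, r.calls[pos]])
                n += 1
    finally:
        if own:
            fh.close()
    return n


def _bismark_strand(aln) -> str:
    """Strand whose cytosines the read reports on.

    Bismark encodes the bisulfite conversion strand in the XG tag (CT =
    original top, GA = original bottom); fall back to alignment strand.
    """
    try:
        xg = aln.get_tag("XG")
        return "+" if xg == "CT" else "-"
    except KeyError:
        return "-" if aln.is_reverse else "+"


def parse_sam_calls(
    source: str | Path,
    site_index: SiteIndex,
    context: str = "CG",
    tag: str = "XM",
    on_missing_tag: str = "skip",
    forward_only: bool = False,
) -> list[ReadCall]:
    """Extract per-read calls from a SAM/BAM with Bismark-style call strings.

    One ReadCall is produced per fragment: paired mates sharing a query name
    are merged, and where mates overlap with conflicting calls the call from
    the higher-base-quality mate wins (ties drop the position).  Secondary,
    supplementary and unmapped records are skipped; calls at positions not
    present in ``site_index`` (or of another context) are dropped with a
    logged tally.

    Parameters
    ----------
    on_missing_tag
        "skip" (default) logs and skips records lacking the call tag;
        "abort" raises instead.
    forward_only
        Keep only fragments reporting on the + strand (mirrors analyses
        that restrict to the original top strand).
    """
    import pysam

    wanted = _normalize_context(context)
    if on_missing_tag not in ("skip", "abort"):
        raise ValueError("on_missing_tag must be 'skip' or 'abort'")

    # fragment key -> position -> (status, quality, conflicted)
    frags: dict[tuple[str, str, str], dict[int, tuple[int, int, bool]]] = {}
    spans: dict[tuple[str, str, str], tuple[int, int]] = {}
    n_dropped_offsite = 0
    n_skipped_records = 0

    with pysam.AlignmentFile(str(source), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            try:
                xm = aln.get_tag(tag)
            except KeyError:
                if on_missing_tag == "abort":
                    raise ValueError(
                        f"record {aln.query_name!r} lacks methylation-call tag {tag!r}"
                    ) from None
                n_skipped_records += 1
                continue
            if aln.query_length and len(xm) != aln.query_length:
                logger.warning(
                    "record %s: call string length %d != read length %d; skipped",
                    aln.query_name, len(xm), aln.query_length,
                )
                n_skipped_records += 1
                continue
            strand = _bismark_strand(aln)
            if forward_only and strand != "+":
                continue
            chrom = aln.reference_name
            quals = aln.query_qualities
            key = (aln.query_name, chrom, strand)
            calls = frags.setdefault(key, {})
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                code = _BISMARK_CODE.get(xm[qpos])
                if code is None:
                    continue
                ctx, status = code
                pos = rpos + 1
                if ctx not in wanted or site_index.context_at(chrom, strand, pos) != ctx:
                    n_dropped_offsite += 1
                    continue
                q = int(quals[qpos]) if quals is not None else 0
                prev = calls.get(pos)
                if prev is None:
                    calls[pos] = (status, q, False)
                else:
                    pstatus, pq, _ = prev
                    if pstatus == status:
                        calls[pos] = (status, max(q, pq), False)
                    elif q > pq:
                        calls[pos] = (status, q, False)
                    elif q < pq:
                        calls[pos] = (pstatus, pq, False)
                    else:  # conflicting mates at equal quality: drop the site
                        calls[pos] = (pstatus, pq, True)
            lo, hi = aln.reference_start + 1, aln.reference_end or aln.reference_start + 1
            if key in spans:
                plo, phi = spans[key]
                spans[key] = (min(plo, lo), max(phi, hi))
            else:
                spans[key] = (lo, hi)

    if n_dropped_offsite or n_skipped_records:
        logger.info(
            "parse_sam_calls: dropped %d off-index/off-context calls, skipped %d records",
            n_dropped_offsite, n_skipped_records,
        )
    out = []
    for (read_id, chrom, strand), calls in frags.items():
        kept = {pos: sc[0] for pos, sc in sorted(calls.items()) if not sc[2]}
        if not kept:
            continue
        out.append(ReadCall(read_id, chrom, strand, kept, spans[(read_id, chrom, strand)]))
    return out
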