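"""Context-cytosine indexing over a reference genome.

Bisulfite and EM-seq report methylation per cytosine, and every cytosine
belongs to one of three sequence contexts -- CG, CHG or CHH, with H any of
A, C or T -- determined by the two bases that follow it 5'->3' on its own
strand.  Different DNA methyltransferase pathways act on different contexts,
so sites are never mixed across contexts.  This module scans a reference
FASTA and emits the ordered backbone of context sites, on both strands,
that all downstream window construction is built on.

Coordinates are 1-based and always refer to the cytosine's own base; a
minus-strand site is reported at the forward-strand G coordinate (the
Bismark/CGmap convention).  Soft-masked (lowercase) bases are treated as
their uppercase equivalents; any base outside ACGT makes the trinucleotide
undefined and the site is skipped, as are cytosines within 2 bp of a
chromosome end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np

CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True, slots=True)
class ContextSite:
    """One context cytosine on one strand of the reference.

    ``position`` is 1-based; for ``strand == '-'`` it is the forward-strand
    coordinate of the G that pairs with the cytosine.  ``trinucleotide`` is
    read 5'->3' on the site's own strand and always starts with C.
    """

    chrom: str
    position: int
    strand: str
    context: str
    trinucleotide: str


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(trinucleotide: str) -> str | None:
    """Classify a 5'->3' trinucleotide starting at a cytosine.

    Returns "CG", "CHG" or "CHH", or None when the trinucleotide does not
    start with C or contains a base outside ACGT (N, IUPAC ambiguity codes).
    """
    t = trinucleotide.upper()
    if len(t) != 3 or any(b not in "ACGT" for b in t):
        return None
    if t[0] != "C":
        return None
    if t[1] == "G":
        return "CG"
    if t[2] == "G":
        return "CHG"
    return "CHH"


def _normalize_context(context: str) -> frozenset[str]:
    c = context.upper()
    if c == "ALL":
        return frozenset(CONTEXTS)
    if c in CONTEXTS:
        return frozenset([c])
    raise ValueError(
        f"unknown context {context!r}; expected one of CG, CHG, CHH, all"
    )


def _iter_sequences(
    fasta: str | Path | Mapping[str, str],
    chroms: Sequence[str] | None,
) -> Iterator[tuple[str, str]]:
    if isinstance(fasta, Mapping):
        for name, seq in fasta.items():
            if chroms is None or name in chroms:
                yield name, str(seq)
        return
    path = os.fspath(fasta)
    if not os.path.exists(path):
        raise FileNotFoundError(f"reference FASTA not found: {path}")
    import pyfaidx

    fa = pyfaidx.Fasta(path, as_raw=True, rebuild=False)
    for name in fa.keys():
        if chroms is None or name in chroms:
            yield name, str(fa[name][:])


def index_context_sites(
    fasta: str | Path | Mapping[str, str],
    context: str = "CG",
    chroms: Sequence[str] | None = None,
) -> Iterator[ContextSite]:
    """Yield every context cytosine of the requested class, both strands.

    Parameters
    ----------
    fasta
        Path to a (plain or bgzipped) FASTA, or a mapping of chromosome
        name to sequence string.
    context
        "CG", "CHG", "CHH" or "all".  With "all" the union is emitted and
        each site carries its true context label.
    chroms
        Optional subset of chromosome names to index.

    Sites are emitted in ascending forward-strand coordinate per
    chromosome with the two strands interleaved, so within each
    (chrom, strand, context) stream positions strictly increase.
    """
    wanted = _normalize_context(context)
    for name, raw in _iter_sequences(fasta, chroms):
        seq = raw.upper()
        n = len(seq)
        for i in range(n):  # 0-based scan
            base = seq[i]
            if base == "C" and i + 2 < n:
                tri = seq[i : i + 3]
                ctx = classify_context(tri)
                if ctx is not None and ctx in wanted:
                    yield ContextSite(name, i + 1, "+", ctx, tri)
            elif base == "G" and i >= 2:
                tri = revcomp(seq[i - 2 : i + 1])
                ctx = classify_context(tri)
                if ctx is not None and ctx in wanted:
                    yield ContextSite(name, i + 1, "-", ctx, tri)


class SiteIndex:
    """Random-access index over a stream of :class:`ContextSite`.

    Holds, per (chrom, strand, context), the sorted array of site positions,
    plus a per-(chrom, strand) position -> context lookup used when
    restricting read calls to indexed sites.
    """

    def __init__(self, sites: Iterable[ContextSite]):
        streams: dict[tuple[str, str, str], list[int]] = {}
        lookup: dict[tuple[str, str], dict[int, str]] = {}
        for s in sites:
            streams.setdefault((s.chrom, s.strand, s.context), []).append(s.position)
            lookup.setdefault((s.chrom, s.strand), {})[s.position] = s.context
        self._streams = {
            key: np.asarray(pos, dtype=np.int64) for key, pos in streams.items()
        }
        for key, arr in self._streams.items():
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"site positions not strictly increasing in {key}")
        self._lookup = lookup

    @classmethod
    def from_fasta(
        cls,
        fasta: str | Path | Mapping[str, str],
        context: str = "CG",
        chroms: Sequence[str] | None = None,
    ) -> "SiteIndex":
        return cls(index_context_sites(fasta, context, chroms))

    def streams(self, context: str | None = None) -> list[tuple[str, str, str]]:
        keys = sorted(self._streams)
        if context is None:
            return keys
        c = context.upper()
        return [k for k in keys if c == "ALL" or k[2] == c]

    def positions(self, chrom: str, strand: str, context: str) -> np.ndarray:
        return self._streams.get((chrom, strand, context), np.empty(0, dtype=np.int64))

    def n_sites(self, chrom: str, strand: str, context: str) -> int:
        return int(self.positions(chrom, strand, context).size)

    def context_at(self, chrom: str, strand: str, position: int) -> str | None:
        return self._lookup.get((chrom, strand), {}).get(position)

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._lookup})


def write_sites_bed(sites: Iterable[ContextSite], sink: str | Path | IO[str]) -> int:
    """Dump sites as BED-like rows (0-based half-open): chrom start end context strand.

    Returns the number of rows written.
    """
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    n = 0
    try:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position - 1}\t{s.position}\t{s.context}\t{s.strand}\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n
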