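"""Synthetic epiallele-mixture methylomes with read-boundary missingness.

Bulk bisulfite data mixes molecules from many cells, and cells within a
population tend to share a small number of local methylation patterns
(epialleles).  The generator realizes exactly that: a region of evenly
spaced context cytosines, K binary epiallele patterns with mixture weights,
and reads of fixed length whose starts are uniform over the region, so
reads at window boundaries observe only part of a pattern -- the
missingness shape that makes imputation necessary in real WGBS/RRBS data.

Per-call noise is a single i.i.d. flip probability epsilon, standing in for
bisulfite conversion failure and sequencing error together.  Every
simulated call is recorded in a truth table (epiallele, pre-noise status,
flip indicator), so any downstream evaluation can score against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .readcalls import ReadCall

_MOTIF = {"CG": "CG", "CHG": "CAG", "CHH": "CAA"}
_PAD = 10  # A/T padding on each end of the synthetic chromosome


@dataclass(slots=True)
class EpialleleModel:
    """Mixture of K epiallele patterns over a region of context sites.

    ``patterns`` is a (K, n_sites) 0/1 array; ``weights`` sum to 1.
    ``epsilon`` is the per-site-call flip probability (< 0.5); reads of
    ``read_length`` bases are drawn to an expected per-site depth of
    ``mean_depth``, over sites ``spacing`` bases apart.
    """

    patterns: np.ndarray
    weights: np.ndarray
    epsilon: float = 0.0
    read_length: int = 100
    mean_depth: float = 18.0
    spacing: int = 25
    context: str = "CG"
    chrom: str = "sim1"
    start_mode: str = "uniform"  # "uniform" (WGBS-like) or "fixed" (RRBS-like)

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=np.int8))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.patterns.ndim != 2 or not np.isin(self.patterns, (0, 1)).all():
            raise ValueError("patterns must be a (K, n_sites) 0/1 array")
        if self.weights.shape != (self.patterns.shape[0],):
            raise ValueError("need one weight per epiallele pattern")
        if (self.weights < 0).any() or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must lie in [0, 0.5)")
        if self.context not in _MOTIF:
            raise ValueError(f"context must be one of {sorted(_MOTIF)}")
        if self.start_mode not in ("uniform", "fixed"):
            raise ValueError("start_mode must be 'uniform' or 'fixed'")

    @property
    def n_sites(self) -> int:
        return int(self.patterns.shape[1])

    def site_positions(self) -> np.ndarray:
        return _planned_positions(self.n_sites, self.spacing)

    def region_length(self) -> int:
        return int(self.site_positions()[-1]) + 2 + _PAD


def _planned_positions(n_sites: int, spacing: int) -> np.ndarray:
    """1-based forward-strand positions of the planned context cytosines."""
    return np.arange(n_sites, dtype=np.int64) * spacing + _PAD + 1


def simulate_reference(
    n_sites: int,
    spacing: int,
    context: str = "CG",
    chrom: str = "sim1",
    seed: int = 0,
) -> tuple[dict[str, str], np.ndarray]:
    """Build a synthetic chromosome with context sites at planned positions.

    The background is random A/T so the only cytosines (on either strand)
    are those of the embedded context motifs; the forward-strand sites land
    exactly at the planned, evenly spaced positions.  Returns the sequence
    mapping and the planned 1-based positions.
    """
    motif = _MOTIF.get(context)
    if motif is None:
        raise ValueError(f"context must be one of {sorted(_MOTIF)}")
    if spacing < len(motif) + 1:
        raise ValueError(f"spacing {spacing} too small to embed {context} motifs")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    positions = _planned_positions(n_sites, spacing)
    length = int(positions[-1]) + 2 + _PAD
    rng = np.random.default_rng(seed)
    arr = rng.choice(np.array(list("AT")), size=length)
    for p in positions:
        arr[p - 1 : p - 1 + len(motif)] = list(motif)
    return {chrom: "".join(arr)}, positions


def simulate_reads(
    model: EpialleleModel,
    seed: int = 0,
    n_reads: int | None = None,
) -> tuple[list[ReadCall], pd.DataFrame]:
    """Draw reads from the epiallele mixture with boundary missingness.

    Each read: epiallele ~ weights, start uniform over the region (or at a
    random site for RRBS-like fixed starts), observed status = epiallele bit
    at each covered site flipped independently with probability epsilon.
    Reads covering no site are dropped (they carry no methylation
    information).  Returns the reads plus a truth table with one row per
    call: read_id, epiallele, position, true_status, flipped, observed.
    """
    rng = np.random.default_rng(seed)
    positions = model.site_positions()
    length = model.region_length()
    if n_reads is None:
        n_reads = max(1, round(model.mean_depth * length / model.read_length))
    reads: list[ReadCall] = []
    truth_rows = []
    k_choices = rng.choice(model.patterns.shape[0], size=n_reads, p=model.weights)
    for i in range(n_reads):
        k = int(k_choices[i])
        if model.start_mode == "uniform":
            start = int(rng.integers(1, max(2, length - model.read_length + 2)))
        else:
            start = int(positions[rng.integers(len(positions))])
        end = start + model.read_length - 1
        inside = np.flatnonzero((positions >= start) & (positions <= end))
        if inside.size == 0:
            continue
        calls: dict[int, int] = {}
        rid = f"r{i:06d}"
        for j in inside:
            true_bit = int(model.patterns[k, j])
            flipped = bool(rng.random() < model.epsilon)
            observed = true_bit ^ flipped
            pos = int(positions[j])
            calls[pos] = observed
            truth_rows.append((rid, k, pos, true_bit, flipped, observed))
        reads.append(ReadCall(rid, model.chrom, "+", calls, (start, end)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "epiallele", "position", "true_status", "flipped", "observed"],
    )
    return reads, truth


def downsample_reads(
    reads: Sequence[ReadCall],
    ratio: float,
    seed: int = 0,
) -> list[ReadCall]:
    """Keep each read independently with probability ``ratio`` (seeded)."""
    if not (0 < ratio <= 1):
        raise ValueError(f"downsampling ratio must be in (0, 1], got {ratio}")
    if ratio == 1:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < ratio
    return [r for r, k in zip(reads, keep) if k]


def write_fasta(sequences: dict[str, str], sink: str | Path | IO[str], width: int = 60) -> None:
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    try:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    finally:
        if own:
            fh.close()
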