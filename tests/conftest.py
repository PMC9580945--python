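from __future__ import annotations

import numpy as np
import pytest

from bsimp import ContextSite, ReadCall, SiteIndex, build_windows, simulate_reference


def make_read(rid: str, calls: dict[int, int], chrom: str = "sim1", strand: str = "+") -> ReadCall:
    return ReadCall(rid, chrom, strand, dict(calls))


def index_from_positions(
    positions, chrom: str = "sim1", strand: str = "+", context: str = "CG"
) -> SiteIndex:
    """Site index over given coordinates, bypassing any reference sequence."""
    return SiteIndex(
        ContextSite(chrom, int(p), strand, context, "CGT") for p in positions
    )


@pytest.fixture(scope="session")
def three_cg_reference():
    """A synthetic chromosome with exactly 3 forward-strand CG sites."""
    seqs, positions = simulate_reference(3, 10, "CG")
    return seqs, [int(p) for p in positions]


@pytest.fixture(scope="session")
def worked_example(three_cg_reference):
    """The w=3 illustration window: 4 complete patterns and 5 eligible reads.

    Complete patterns UMU, MMU, MMM, UUU; among the eligible reads, e1's
    subpattern matches exactly one complete pattern (unmethylated at the
    missing site, so p=0) and e4's subpattern (methylated, unmethylated at
    sites 2-3) matches two complete patterns split one methylated / one
    unmethylated at the missing first site, so p=0.5.
    """
    seqs, (p1, p2, p3) = three_cg_reference
    idx = SiteIndex.from_fasta(seqs, "CG")
    reads = [
        make_read("c1", {p1: 0, p2: 1, p3: 0}),
        make_read("c2", {p1: 1, p2: 1, p3: 0}),
        make_read("c3", {p1: 1, p2: 1, p3: 1}),
        make_read("c4", {p1: 0, p2: 0, p3: 0}),
        make_read("e1", {p1: 0, p2: 1}),
        make_read("e2", {p1: 1, p3: 1}),
        make_read("e3", {p2: 0, p3: 0}),
        make_read("e4", {p2: 1, p3: 0}),
        make_read("e5", {p1: 1, p2: 1}),
    ]
    windows = list(build_windows(reads, idx, 3))
    assert len(windows) == 1
    return idx, reads, windows[0]


def random_window_inputs(rng: np.random.Generator, w: int, n_reads: int):
    """Random read calls over w + a few extra sites, for oracle comparisons."""
    n_sites = w + int(rng.integers(0, 3))
    positions = [10 * (k + 1) for k in range(n_sites)]
    reads = []
    for i in range(n_reads):
        lo = int(rng.integers(0, n_sites))
        hi = int(rng.integers(lo, n_sites))
        calls = {}
        for k in range(lo, hi + 1):
            if rng.random() < 0.8:
                calls[positions[k]] = int(rng.integers(0, 2))
        if calls:
            reads.append(make_read(f"r{i}", calls))
    return positions, reads
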