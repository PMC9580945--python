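"""Pattern profiling, genome screening filters and TSV round-trips."""

import io

import numpy as np
import pytest

from bsimp import (
    MISSING,
    build_windows,
    impute_window,
    pattern_index,
    pattern_name,
    profile_window,
    read_profiles,
    screen_genome,
    write_profiles,
)
from bsimp.impute import ImputedCell
from bsimp.profile import impute_read_level, write_bedgraph
from conftest import index_from_positions, make_read
from test_impute import window_from_matrix


def test_pattern_encoding_site1_is_most_significant():
    assert pattern_index([1, 0, 1]) == 5
    assert pattern_name(5, 3) == "MUM"
    assert [pattern_name(k, 2) for k in range(4)] == ["UU", "UM", "MU", "MM"]


def test_direct_tally_w2():
    win = window_from_matrix([[1, 1], [1, 1], [0, 0]])
    prof = profile_window(win, [])
    assert prof.pattern_counts.tolist() == [1, 0, 0, 2]
    assert prof.n_complete_after == 3


def test_worked_example_threshold_profile(worked_example):
    """The p=0 read joins its completed pattern; the tied read stays out."""
    _, _, win = worked_example
    cells = impute_window(win, assign_mode="threshold")
    prof = profile_window(win, cells)
    # completed rows: 4 complete + e1 (UMU), e2 (MMM), e3 (UUU); e4/e5 tied out
    assert prof.n_complete_after == 7
    assert prof.pattern_counts.sum() == 7
    assert prof.pattern_counts[pattern_index([0, 1, 0])] == 2  # c1 + completed e1
    # tied reads still contribute their observed statuses to site counts
    assert prof.site_counts[1].tolist() == [7, 2]


def test_unknown_row_reference_rejected(worked_example):
    _, _, win = worked_example
    bogus = ImputedCell("ghost", 0, int(win.sites[0]), 1, 0.5, "conditional", 1)
    with pytest.raises(ValueError, match="unknown row"):
        profile_window(win, [bogus])


@pytest.mark.parametrize("seed", [0, 1])
def test_pattern_sum_equals_recounted_complete_rows(seed):
    rng = np.random.default_rng(seed)
    mat = rng.choice([0, 1, MISSING], size=(15, 3), p=[0.4, 0.4, 0.2])
    mat = mat[(mat != MISSING).any(axis=1)]
    win = window_from_matrix(mat)
    cells = impute_window(win, assign_mode="sample", rng_seed=seed)
    prof = profile_window(win, cells)
    merged = win.matrix.copy()
    for c in cells:
        if c.assigned != -1:
            merged[c.row, c.j - 1] = c.assigned
    recount = sum(1 for row in merged if (row != MISSING).all())
    assert int(prof.pattern_counts.sum()) == prof.n_complete_after == recount
    # site counts tally observed plus assigned statuses exactly
    assert (prof.site_counts[:, 0] == (merged == 1).sum(axis=0)).all()
    assert (prof.site_counts[:, 1] == (merged == 0).sum(axis=0)).all()


class TestScreenGenome:
    def setup_method(self):
        self.positions = [10 * (k + 1) for k in range(6)]
        self.idx = index_from_positions(self.positions)

    def reads_epialleles(self, n=12):
        reads = []
        for i in range(n):
            bits = [1, 1, 1, 1, 1, 1] if i % 2 == 0 else [0, 0, 0, 0, 0, 0]
            reads.append(make_read(f"r{i}", dict(zip(self.positions, bits))))
        return reads

    def test_min_level_zero_is_vacuous(self):
        reads = self.reads_epialleles()
        base = list(screen_genome(reads, self.idx, 3, min_complete=2, min_level=0.0))
        assert len(base) == len(self.positions) - 2

    def test_min_complete_two_drops_single_pattern_windows(self):
        reads = [make_read("only", dict(zip(self.positions, [1] * 6)))]
        assert list(screen_genome(reads, self.idx, 3, min_complete=2)) == []

    def test_min_complete_below_two_rejected(self):
        with pytest.raises(ValueError, match="min_complete"):
            list(screen_genome([], self.idx, 3, min_complete=1))

    def test_emitted_set_matches_independent_refilter(self):
        reads = self.reads_epialleles(9)
        got = {
            p.start
            for p in screen_genome(reads, self.idx, 3, min_complete=4,
                                   min_depth=4, min_level=0.5, seed=1)
        }
        expected = set()
        for win in build_windows(reads, self.idx, 3):
            prof = profile_window(win, impute_window(win, "sample", 1))
            depths = prof.depths()
            levels = prof.levels()[depths > 0]
            if (
                prof.n_complete_after >= 4
                and (depths >= 4).all()
                and levels.size
                and levels.max() >= 0.5
            ):
                expected.add(prof.start)
        assert got == expected

    def test_level_filter_blocks_unmethylated_windows(self):
        reads = [make_read(f"r{i}", dict(zip(self.positions, [0] * 6))) for i in range(5)]
        assert list(screen_genome(reads, self.idx, 3, min_level=0.2)) == []

    def test_unknown_chromosome_is_input_error(self):
        reads = [make_read("r", {10: 1, 20: 1}, chrom="chrZ")]
        with pytest.raises(ValueError, match="chromosomes"):
            list(screen_genome(reads, self.idx, 2))

    def test_coverage_monotone_under_imputation(self):
        """Windows passing min_complete after imputation superset those before."""
        rng = np.random.default_rng(5)
        reads = []
        for i in range(40):
            lo = int(rng.integers(0, 4))
            n_cov = int(rng.integers(2, 4))
            bits = [int(rng.integers(0, 2))] * 6
            calls = {self.positions[k]: bits[k] for k in range(lo, min(6, lo + n_cov))}
            reads.append(make_read(f"r{i}", calls))
        passing_before = set()
        passing_after = set()
        for win in build_windows(reads, self.idx, 3):
            if len(win.complete_rows()) >= 3:
                passing_before.add(win.start)
            prof = profile_window(win, impute_window(win, "sample", 0))
            if prof.n_complete_after >= 3:
                passing_after.add(win.start)
        assert passing_before <= passing_after


class TestProfileTsv:
    def test_empty_stream_writes_header_only(self):
        buf = io.StringIO()
        assert write_profiles([], buf, 3) == 0
        lines = buf.getvalue().strip().split("\n")
        assert len(lines) == 1
        cols = lines[0].split("\t")
        assert len(cols) == 4 + 8 + 6  # keys + 2^3 patterns + 3x(meth,unmeth)
        assert cols[4] == "UUU" and cols[11] == "MMM"

    def test_roundtrip_random_profiles(self, worked_example):
        _, _, win = worked_example
        prof = profile_window(win, impute_window(win, "threshold"))
        buf = io.StringIO()
        write_profiles([prof], buf, 3)
        buf.seek(0)
        (back,) = read_profiles(buf)
        assert back.chrom == prof.chrom and back.start == prof.start
        assert back.strand == prof.strand and back.w == prof.w
        assert (back.pattern_counts == prof.pattern_counts).all()
        assert (back.site_counts == prof.site_counts).all()
        assert back.n_complete_after == prof.n_complete_after


def test_bedgraph_deduplicates_overlapping_windows():
    positions = [10, 20, 30, 40]
    idx = index_from_positions(positions)
    reads = [make_read(f"r{i}", dict(zip(positions, [1, 1, 0, 0]))) for i in range(3)]
    profiles = list(screen_genome(reads, idx, 3, min_complete=2))
    buf = io.StringIO()
    n = write_bedgraph(profiles, buf)
    assert n == 4  # each site once despite w-1 overlap
    rows = [line.split("\t") for line in buf.getvalue().strip().split("\n")]
    assert [r[1] for r in rows] == ["9", "19", "29", "39"]
    assert [float(r[3]) for r in rows] == [1.0, 1.0, 0.0, 0.0]


def test_read_level_export_uses_leftmost_window():
    positions = [10, 20, 30, 40]
    idx = index_from_positions(positions)
    reads = [
        make_read("c1", {10: 1, 20: 1, 30: 1, 40: 1}),
        make_read("c2", {10: 1, 20: 1, 30: 1, 40: 1}),
        make_read("c3", {10: 0, 20: 0, 30: 0, 40: 0}),
        make_read("e", {20: 1, 40: 1}),  # missing 30, imputable in two windows
    ]
    aug = {r.read_id: r for r in impute_read_level(reads, idx, 3, assign_mode="threshold")}
    assert aug["e"].calls[30] == 1  # matches the all-methylated epiallele
    # observed calls never overwritten
    for r in reads:
        for pos, v in r.calls.items():
            assert aug[r.read_id].calls[pos] == v
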