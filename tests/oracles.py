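"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration over python lists, sharing
no code path with the package implementation it checks.
"""

from __future__ import annotations

MISSING = -1


def oracle_classify_context(seq: str, i: int, strand: str) -> str | None:
    """Direct per-position context classifier (0-based i, forward coords)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    s = seq.upper()
    if strand == "+":
        if i + 2 >= len(s) or s[i] != "C":
            return None
        tri = s[i : i + 3]
    else:
        if i < 2 or s[i] != "G":
            return None
        tri = "".join(comp.get(b, "N") for b in reversed(s[i - 2 : i + 1]))
    if any(b not in "ACGT" for b in tri):
        return None
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def oracle_conditional_prob(matrix: list[list[int]], row: int) -> tuple[float, str]:
    """Brute-force imputed probability for an eligible row.

    Tabulates every complete pattern, groups by subpattern at the observed
    indices, and returns the conditional frequency of methylation at the
    missing index; falls back to the column mean over all observed rows.
    """
    values = matrix[row]
    miss = [j for j, v in enumerate(values) if v == MISSING]
    assert len(miss) == 1
    j = miss[0]
    obs = [k for k in range(len(values)) if k != j]
    complete = [r for r in matrix if MISSING not in r]
    matching = [r for r in complete if all(r[k] == values[k] for k in obs)]
    if matching:
        return sum(r[j] for r in matching) / len(matching), "conditional"
    col = [r[j] for r in matrix if r[j] != MISSING]
    return sum(col) / len(col), "column_mean"


def oracle_column_mean(matrix: list[list[int]], j: int) -> float:
    col = [r[j] for r in matrix if r[j] != MISSING]
    return sum(col) / len(col)


def oracle_windows(calls_by_read, positions: list[int], w: int):
    """Re-derive every populated window from raw calls.

    ``calls_by_read``: list of (read_id, {position: status}).  Returns a
    dict offset -> list of (read_id, row values) where a read is a row iff
    it has at least one call among the window's w sites.
    """
    out = {}
    for o in range(0, len(positions) - w + 1):
        win_sites = positions[o : o + w]
        rows = []
        for rid, calls in calls_by_read:
            row = [calls.get(p, MISSING) for p in win_sites]
            if any(v != MISSING for v in row):
                rows.append((rid, row))
        if rows:
            out[o] = rows
    return out
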