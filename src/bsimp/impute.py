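"""Probabilistic recovery of a single missing methylation status per read.

Cells in a population tend to share local methylation patterns, and nearby
cytosines are strongly correlated, so the statuses a read does show within
a small window carry information about the one it is missing.  For an
eligible row (exactly one missing cell, at site index j) the imputed
probability of methylation is the conditional frequency among the window's
complete patterns whose statuses at the w-1 observed sites equal the row's
subpattern:

    p(m_ij = 1) = #{complete rows matching the subpattern, methylated at j}
                  / #{complete rows matching the subpattern}

By the law of total probability the sum over all subpatterns collapses to
this single term, because the row's subpattern is fully observed.  When no
complete pattern matches the subpattern, the probability falls back to the
column mean: the methylation level at j over all reads observed there
(including observed-only rows).  Only windows with at least two complete
patterns are imputed at all.

The conditioning set is the window's original complete rows, frozen before
any imputation: imputed rows never feed other imputations in the same
window, which removes any dependence on the order rows are visited.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
import numpy as np

from .windows import MISSING, Window

UNASSIGNED = -1

ASSIGN_MODES = ("sample", "threshold", "none")


@dataclass(slots=True)
class ImputedCell:
    """A filled missing cell.

    ``j`` is the 1-based site index within the window; ``row`` the row index
    in the window the cell belongs to.  ``method`` records whether the
    probability came from the conditional rule or the column-mean fallback.
    ``assigned`` is 1/0 once a hard status has been drawn or thresholded,
    else UNASSIGNED.
    """

    read_id: str
    row: int
    site_position: int
    j: int
    p_meth: float
    method: str
    assigned: int = UNASSIGNED


def column_mean(window: Window, j: int) -> float:
    """Methylation level at 1-based window site index j.

    The fraction of methylated statuses among ALL rows observed at j --
    complete, eligible and observed-only alike.
    """
    col = window.matrix[:, j - 1]
    observed = col != MISSING
    if not observed.any():
        raise ValueError(f"no read observed at window site {j}; column mean undefined")
    return float(col[observed].mean())


def conditional_prob(window: Window, row: int) -> ImputedCell:
    """Impute the probability for an eligible row's single missing cell.

    Requires >=2 complete rows in the window and exactly one MISSING entry
    in the row (both are contract violations otherwise; callers gate via
    :func:`impute_window`).  Observed entries are never altered.
    """
    values = window.matrix[row]
    miss = np.flatnonzero(values == MISSING)
    if miss.size != 1:
        raise ValueError(
            f"row {row} has {miss.size} missing cells; eligible rows have exactly 1"
        )
    complete_idx = window.complete_rows()
    if len(complete_idx) < 2:
        raise ValueError("window has fewer than 2 complete patterns; not imputable")
    jj = int(miss[0])  # 0-based
    obs = np.flatnonzero(values != MISSING)
    complete = window.matrix[complete_idx]
    match = np.all(complete[:, obs] == values[obs], axis=1)
    if match.any():
        p = float(complete[match, jj].mean())
        method = "conditional"
    else:
        p = column_mean(window, jj + 1)
        method = "column_mean"
    return ImputedCell(
        read_id=window.read_ids[row],
        row=row,
        site_position=int(window.sites[jj]),
        j=jj + 1,
        p_meth=p,
        method=method,
    )


def cell_seed(seed: int, chrom: str, strand: str, start: int, read_id: str, j: int) -> int:
    """Deterministic 31-bit substream seed for one imputed cell.

    Keyed by coordinates rather than call order so results do not depend on
    read iteration order.
    """
    key = f"{seed}|{chrom}|{strand}|{start}|{read_id}|{j}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


def impute_window(
    window: Window,
    assign_mode: str = "sample",
    rng_seed: int = 0,
) -> list[ImputedCell]:
    """Impute every eligible row of a window, if the window qualifies.

    Returns an empty list when the window has fewer than two complete
    patterns.  Otherwise one :class:`ImputedCell` per eligible row, in row
    order, with probabilities computed from the original complete-row set.

    Assignment modes:

    - ``sample``: draw Bernoulli(p_meth) from a per-cell substream derived
      from (rng_seed, chrom, strand, window start, read_id, j) -- the
      default, reproducible and unbiased;
    - ``threshold``: 1 if p_meth > 0.5, 0 if p_meth < 0.5, UNASSIGNED at
      exactly 0.5 (ties left unimputed to avoid directional bias);
    - ``none``: probabilities only, everything UNASSIGNED.
    """
    if assign_mode not in ASSIGN_MODES:
        raise ValueError(f"assign_mode must be one of {ASSIGN_MODES}, got {assign_mode!r}")
    if len(window.complete_rows()) < 2:
        return []
    out = []
    for row in window.eligible_rows():
        cell = conditional_prob(window, row)
        if assign_mode == "sample":
            sub = np.random.default_rng(
                cell_seed(rng_seed, window.chrom, window.strand, window.start,
                          cell.read_id, cell.j)
            )
            cell.assigned = int(sub.random() < cell.p_meth)
        elif assign_mode == "threshold":
            if cell.p_meth > 0.5:
                cell.assigned = 1
            elif cell.p_meth < 0.5:
                cell.assigned = 0
        out.append(cell)
    return out
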