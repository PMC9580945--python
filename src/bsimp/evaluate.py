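"""Desk-scale evaluation harnesses for the imputer.

Three designs, all runnable on simulated data with no external downloads:

- mask-and-impute accuracy: hide observed statuses in windows of complete
  patterns, recover them with the conditional imputer and with the
  column-mean baseline, and score against the hidden truth;
- coverage before/after imputation across sequencing depths: the fraction
  of window starts with enough complete patterns for heterogeneity
  analysis, and the fraction of sites with enough depth for level
  analysis;
- methylation-level bias: how far per-site levels move, after downsampling
  and after imputation, from the full-depth levels treated as truth.

Accuracy uses threshold-mode predictions with ties scored as half credit,
which removes sampling variance from the headline metric; it aggregates
per window first and then averages across windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .impute import impute_window
from .profile import impute_read_level, profile_window
from .readcalls import ReadCall
from .simulate import downsample_reads
from .sites import SiteIndex
from .windows import MISSING, Window, build_windows

logger = logging.getLogger(__name__)

METHODS = ("bsimp", "column_mean", "oracle")


@dataclass(slots=True)
class MaskingExperiment:
    """Result of a mask-and-impute run.

    ``accuracy`` maps method name to the mean over windows of the fraction
    of masked cells recovered correctly (ties at p = 0.5 earn half credit).
    """

    n_windows: int
    n_skipped: int
    k_per_window: int
    n_masked: int
    accuracy: dict[str, float]
    per_window: pd.DataFrame


def _threshold_credit(p: float, truth: int) -> float:
    if p > 0.5:
        return float(truth == 1)
    if p < 0.5:
        return float(truth == 0)
    return 0.5


def _subpattern_supported(masked: np.ndarray, row: int) -> bool:
    """Does any unmasked complete row match the masked row's subpattern?"""
    values = masked[row]
    obs = values != MISSING
    for k in range(masked.shape[0]):
        if k == row:
            continue
        other = masked[k]
        if (other != MISSING).all() and (other[obs] == values[obs]).all():
            return True
    return False


def mask_and_score(
    windows: Iterable[Window],
    k_masks_per_window: int = 2,
    methods: Sequence[str] = ("bsimp", "column_mean"),
    seed: int = 0,
    require_subpattern_support: bool = False,
) -> MaskingExperiment:
    """Hide k observed statuses per window and score their recovery.

    Only the complete rows of each window are used, so the hidden truth is
    known; masks respect imputation eligibility (at most one per read per
    window) and at least two rows are left untouched so the conditional
    rule always has a conditioning set.  Windows too small for that are
    skipped with a log message.

    Methods: ``bsimp`` (conditional rule with column-mean fallback),
    ``column_mean`` (the baseline: the site's methylation level over
    unmasked cells as the probability for every masked cell), ``oracle``
    (predicts the truth -- harness self-test).

    ``require_subpattern_support`` additionally skips windows where a
    proposed mask would leave a masked read's subpattern unrepresented
    among the remaining complete patterns.  Exactness statements about the
    conditional rule presuppose that the conditioning information exists;
    this switch restricts the experiment to that premise regime (it also
    removes the column-mean fallback from the scored cells, so leave it off
    when benchmarking the baseline).
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    rng = np.random.default_rng(seed)
    rows_out = []
    n_windows = n_skipped = n_masked = 0
    for win in windows:
        complete = win.complete_rows()
        if len(complete) < k_masks_per_window + 2:
            n_skipped += 1
            logger.debug("window %s:%d too small for %d masks; skipped",
                         win.chrom, win.start, k_masks_per_window)
            continue
        sub = win.matrix[complete].copy()
        read_ids = [win.read_ids[i] for i in complete]
        masked_rows = rng.choice(len(complete), size=k_masks_per_window, replace=False)
        masks = [(int(r), int(rng.integers(win.w))) for r in masked_rows]
        truth = {(r, j): int(sub[r, j]) for r, j in masks}
        masked = sub.copy()
        for r, j in masks:
            masked[r, j] = MISSING
        if require_subpattern_support and not all(
            _subpattern_supported(masked, r) for r, _ in masks
        ):
            n_skipped += 1
            logger.debug("window %s:%d: masked subpattern unsupported; skipped",
                         win.chrom, win.start)
            continue
        mwin = Window(win.chrom, win.strand, win.context, win.sites, read_ids,
                      masked, win.offset)
        credits: dict[str, list[float]] = {m: [] for m in methods}
        cells = {c.row: c for c in impute_window(mwin, assign_mode="none")}
        for r, j in masks:
            t = truth[(r, j)]
            for m in methods:
                if m == "bsimp":
                    p = cells[r].p_meth
                elif m == "column_mean":
                    col = masked[:, j]
                    obs = col != MISSING
                    p = float(col[obs].mean()) if obs.any() else 0.5
                else:  # oracle
                    p = float(t)
                credits[m].append(_threshold_credit(p, t))
        n_windows += 1
        n_masked += len(masks)
        for m in methods:
            rows_out.append(
                (win.chrom, win.start, win.strand, m, float(np.mean(credits[m])))
            )
    per_window = pd.DataFrame(
        rows_out, columns=["chrom", "start", "strand", "method", "accuracy"]
    )
    accuracy = {
        m: float(per_window.loc[per_window["method"] == m, "accuracy"].mean())
        if n_windows
        else float("nan")
        for m in methods
    }
    return MaskingExperiment(
        n_windows=n_windows,
        n_skipped=n_skipped,
        k_per_window=k_masks_per_window,
        n_masked=n_masked,
        accuracy=accuracy,
        per_window=per_window,
    )


def _site_depths(reads: Iterable[ReadCall]) -> dict[tuple[str, str, int], int]:
    depths: dict[tuple[str, str, int], int] = {}
    for r in reads:
        for pos in r.calls:
            key = (r.chrom, r.strand, pos)
            depths[key] = depths.get(key, 0) + 1
    return depths


def methylation_levels(reads: Iterable[ReadCall]) -> dict[tuple[str, str, int], float]:
    """Per-site methylation level (fraction methylated) from raw calls."""
    meth: dict[tuple[str, str, int], int] = {}
    total: dict[tuple[str, str, int], int] = {}
    for r in reads:
        for pos, status in r.calls.items():
            key = (r.chrom, r.strand, pos)
            total[key] = total.get(key, 0) + 1
            meth[key] = meth.get(key, 0) + status
    return {k: meth[k] / total[k] for k in total}


def coverage_scan(
    reads: Sequence[ReadCall],
    site_index: SiteIndex,
    w: int = 3,
    ratios: Sequence[float] = (0.28, 0.44, 0.56, 0.83, 1.0),
    min_complete: int = 8,
    min_depth: int = 8,
    context: str = "CG",
    assign_mode: str = "sample",
    seed: int = 0,
) -> pd.DataFrame:
    """Window and site coverage before/after imputation across depths.

    For each downsampling ratio: window coverage is the fraction of window
    starts (over all offsets of the streams the reads report on) holding at
    least ``min_complete`` complete patterns, before imputation and after;
    site coverage is the fraction of sites with depth >= ``min_depth``,
    likewise before and after.  Returns a tidy frame with one row per
    ratio.
    """
    for r in ratios:
        if not (0 < r <= 1):
            raise ValueError(f"ratios must lie in (0, 1], got {r}")
    streams = sorted({(r.chrom, r.strand) for r in reads})
    n_offsets = sum(
        max(0, site_index.n_sites(c, s, context) - w + 1) for c, s in streams
    )
    n_sites_total = sum(site_index.n_sites(c, s, context) for c, s in streams)
    rows = []
    for t, ratio in enumerate(ratios):
        sub_seed = (seed * 1009 + t) & 0x7FFFFFFF
        ds = downsample_reads(reads, ratio, seed=sub_seed)
        before = after = 0
        for win in build_windows(ds, site_index, w, context):
            if len(win.complete_rows()) >= min_complete:
                before += 1
            cells = impute_window(win, assign_mode=assign_mode, rng_seed=sub_seed)
            if profile_window(win, cells).n_complete_after >= min_complete:
                after += 1
        depths_before = _site_depths(ds)
        aug = impute_read_level(ds, site_index, w, context, assign_mode, sub_seed)
        depths_after = _site_depths(aug)
        rows.append(
            {
                "ratio": ratio,
                "n_reads": len(ds),
                "windows_before": before / n_offsets if n_offsets else 0.0,
                "windows_after": after / n_offsets if n_offsets else 0.0,
                "sites_before": sum(d >= min_depth for d in depths_before.values())
                / n_sites_total if n_sites_total else 0.0,
                "sites_after": sum(d >= min_depth for d in depths_after.values())
                / n_sites_total if n_sites_total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def level_bias(
    reference_reads: Sequence[ReadCall],
    reduced_reads: Sequence[ReadCall],
    site_index: SiteIndex,
    w: int = 3,
    context: str = "CG",
    methods: Sequence[str] = ("no_imputation", "bsimp"),
    assign_mode: str = "sample",
    seed: int = 0,
) -> pd.DataFrame:
    """Mean absolute per-site methylation-level difference vs full depth.

    The reference levels come from ``reference_reads`` (the full-depth
    library, treated as truth); each method recomputes levels from
    ``reduced_reads``, either raw (``no_imputation``) or after read-level
    imputation (``bsimp``).  Only sites covered in the reference and in
    every compared arm contribute.  Raises when the common site set is
    empty.
    """
    ref_levels = methylation_levels(reference_reads)
    arms: dict[str, Mapping[tuple[str, str, int], float]] = {}
    for m in methods:
        if m == "no_imputation":
            arms[m] = methylation_levels(reduced_reads)
        elif m == "bsimp":
            aug = impute_read_level(reduced_reads, site_index, w, context, assign_mode, seed)
            arms[m] = methylation_levels(aug)
        else:
            raise ValueError(f"unknown method {m!r}")
    common = set(ref_levels)
    for levels in arms.values():
        common &= set(levels)
    if not common:
        raise ValueError("no site covered by the reference and every compared arm")
    rows = []
    for m, levels in arms.items():
        diffs = [abs(levels[k] - ref_levels[k]) for k in common]
        rows.append({"method": m, "mad": float(np.mean(diffs)), "n_sites": len(common)})
    return pd.DataFrame(rows)
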