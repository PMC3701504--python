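"""Windowed coverage profiling, gap detection and region segmentation.

A misassembled ("hybrid") scaffold joins sequence from two genomic
locations; when reads come from a single dissected chromosome arm, the
foreign segment shows as a long run with essentially no uniquely-mapping
reads.  This module bins unique-hit start positions into fixed windows,
reports maximal low-density runs longer than a minimum span (default
100 kb) as gap calls, and segments chromosome-scale sequences into
alternating read-dense / read-sparse regions.

Defaults: 10 kb windows; sparse cutoff 1.0 hits/kb (the empirical off-arm
ceiling); minimum gap 100 kb; minimum region 500 kb with a two-window
smoothing tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .align import UniqueHitTable

DEFAULT_WINDOW_BP = 10_000
DEFAULT_SPARSE_CUTOFF = 1.0     # hits/kb; off-arm scaffolds sit below this
DEFAULT_MIN_GAP_BP = 100_000
DEFAULT_MIN_REGION_BP = 500_000
DEFAULT_MAX_DISCORDANT = 2


@dataclass
class CoverageProfile:
    """Non-overlapping window densities for one scaffold.  The last window
    may be short; its density is normalised by its true length."""

    scaffold: str
    length_bp: int
    window_bp: int
    counts: np.ndarray     # hits per window
    densities: np.ndarray  # hits/kb per window

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def window_bounds(self, i: int) -> tuple[int, int]:
        return i * self.window_bp, min((i + 1) * self.window_bp, self.length_bp)

    def total_hits(self) -> int:
        return int(self.counts.sum())


GAP_COLUMNS = ["scaffold", "start0", "end0", "span_bp",
               "mean_density_inside", "terminal"]
SEGMENT_COLUMNS = ["scaffold", "start0", "end0", "state", "mean_density"]


def window_profile(hits: UniqueHitTable | pd.DataFrame, scaffold: str,
                   length_bp: int, window_bp: int = DEFAULT_WINDOW_BP,
                   ) -> CoverageProfile:
    """Assign each unique hit to the window containing its start."""
    if window_bp < 1000:
        raise ValueError("window_bp must be >= 1000")
    table = hits.hits if isinstance(hits, UniqueHitTable) else hits
    sel = table.loc[table["scaffold"] == scaffold, "pos0"]
    n_win = max(1, -(-length_bp // window_bp))
    if len(sel) and (sel.max() >= length_bp or sel.min() < 0):
        raise ValueError(f"hit outside scaffold bounds on {scaffold}")
    counts = np.bincount((sel.to_numpy() // window_bp).astype(np.int64),
                         minlength=n_win).astype(np.int64)
    win_len = np.full(n_win, window_bp, dtype=np.int64)
    win_len[-1] = length_bp - (n_win - 1) * window_bp
    densities = counts / (win_len / 1000.0)
    return CoverageProfile(scaffold, length_bp, window_bp, counts, densities)


def detect_gaps(profile: CoverageProfile,
                sparse_cutoff: float = DEFAULT_SPARSE_CUTOFF,
                min_gap_bp: int = DEFAULT_MIN_GAP_BP) -> pd.DataFrame:
    """Maximal runs of consecutive windows below ``sparse_cutoff`` spanning
    at least ``min_gap_bp``.  Gaps touching a scaffold end are flagged
    ``terminal`` (possible laser-path taper or truncated assembly) but are
    still reported."""
    below = profile.densities < sparse_cutoff
    rows = []
    i = 0
    n = profile.n_windows
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        start = i * profile.window_bp
        end = min(j * profile.window_bp, profile.length_bp)
        span = end - start
        if span >= min_gap_bp:
            hits_inside = int(profile.counts[i:j].sum())
            rows.append({
                "scaffold": profile.scaffold,
                "start0": start,
                "end0": end,
                "span_bp": span,
                "mean_density_inside": hits_inside / (span / 1000.0),
                "terminal": i == 0 or j == n,
            })
        i = j
    frame = pd.DataFrame(rows, columns=GAP_COLUMNS)
    if frame.empty:
        frame = frame.astype({"scaffold": object, "start0": np.int64,
                              "end0": np.int64, "span_bp": np.int64,
                              "mean_density_inside": float,
                              "terminal": bool})
    return frame


def _smooth_labels(labels: np.ndarray, max_discordant: int) -> np.ndarray:
    """Absorb contrary runs of length <= max_discordant that are flanked on
    both sides by the opposite state; iterate to a fixed point."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _rle(labels)
        for idx in range(1, len(runs) - 1):
            s, e, val = runs[idx]
            if (e - s <= max_discordant
                    and runs[idx - 1][2] == runs[idx + 1][2] != val):
                labels[s:e] = runs[idx - 1][2]
                changed = True
                break
    return labels


def _rle(labels: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((i, j, int(labels[i])))
        i = j
    return runs


def segment_regions(profile: CoverageProfile, dense_cutoff: float,
                    min_region_bp: int = DEFAULT_MIN_REGION_BP,
                    max_discordant: int = DEFAULT_MAX_DISCORDANT,
                    ) -> pd.DataFrame:
    """Partition a scaffold into alternating dense/sparse regions.

    Windows are labelled dense iff density >= dense_cutoff; contrary runs
    of up to ``max_discordant`` windows inside a longer run are absorbed;
    remaining runs shorter than ``min_region_bp`` are merged into a
    neighbour (the longer neighbour wins, the left one on a tie).  The
    result tiles [0, length) with adjacent segments differing in state.
    """
    labels = (profile.densities >= dense_cutoff).astype(np.int64)
    labels = _smooth_labels(labels, max_discordant)
    runs = _rle(labels)

    def run_bp(run: tuple[int, int, int]) -> int:
        s, e, _ = run
        return (min(e * profile.window_bp, profile.length_bp)
                - s * profile.window_bp)

    # merge short runs, shortest first (leftmost on equal span)
    while len(runs) > 1:
        spans = [run_bp(r) for r in runs]
        short = [i for i, bp in enumerate(spans) if bp < min_region_bp]
        if not short:
            break
        i = min(short, key=lambda idx: (spans[idx], idx))
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            target = i - 1 if spans[i - 1] >= spans[i + 1] else i + 1
        s, e, _ = runs[i]
        runs[i] = (s, e, runs[target][2])
        # coalesce equal-state neighbours
        merged: list[tuple[int, int, int]] = []
        for run in runs:
            if merged and merged[-1][2] == run[2]:
                merged[-1] = (merged[-1][0], run[1], run[2])
            else:
                merged.append(run)
        runs = merged

    rows = []
    for s, e, val in runs:
        start = s * profile.window_bp
        end = min(e * profile.window_bp, profile.length_bp)
        hits_in = int(profile.counts[s:e].sum())
        rows.append({
            "scaffold": profile.scaffold,
            "start0": start,
            "end0": end,
            "state": "dense" if val else "sparse",
            "mean_density": hits_in / ((end - start) / 1000.0),
        })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def flag_hybrids(calls: pd.DataFrame, gaps: pd.DataFrame) -> pd.DataFrame:
    """Hybrid-candidate report: scaffolds that are above the on-arm
    threshold AND contain at least one non-terminal coverage gap.  Returns
    one row per flagged gap (for probe design) plus the flagged fraction of
    above-threshold scaffolds in the attribute ``.attrs['fraction_flagged']``.
    """
    above = set(calls.loc[calls["above_threshold"], "scaffold"])
    if len(gaps):
        internal = gaps[~gaps["terminal"] & gaps["scaffold"].isin(above)]
    else:
        internal = gaps
    flagged = sorted(set(internal["scaffold"])) if len(internal) else []
    report = internal.copy() if len(internal) else pd.DataFrame(
        columns=GAP_COLUMNS)
    report.attrs["n_above_threshold"] = len(above)
    report.attrs["n_flagged"] = len(flagged)
    report.attrs["fraction_flagged"] = (len(flagged) / len(above)
                                        if above else 0.0)
    return report


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_bedgraph(profiles: Iterable[CoverageProfile],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            for i in range(p.n_windows):
                s, e = p.window_bounds(i)
                fh.write(f"{p.scaffold}\t{s}\t{e}\t{p.densities[i]:.4f}\n")


def write_bed(frame: pd.DataFrame, path: str | Path, name_col: str,
              density_col: str) -> None:
    """BED with name = state/flag and score = mean density x10, truncated."""
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            score = int(getattr(row, density_col) * 10)
            fh.write(f"{row.scaffold}\t{row.start0}\t{row.end0}"
                     f"\t{getattr(row, name_col)}\t{score}\n")
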