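"""Read-depth, spanning-read, and repeat-content evidence in fixed windows
around scaffold termini and lifted junctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .breakpoint_stats import BreakpointSpec
from .formats_io import (
    AlignmentRecord,
    DepthWindowTable,
    REPEAT_CLASSES,
    RepeatAnnotation,
    ScaffoldSet,
    cigar_reference_length,
)

__all__ = [
    "TerminalWindowDepth",
    "RepeatWindowProfile",
    "CoverageFold",
    "RepeatComparison",
    "terminal_window_depth",
    "detect_spanning_reads",
    "coverage_fold",
    "junction_depth_track",
    "window_masked_fraction",
    "compare_junction_repeats",
]


# ---------------------------------------------------------------------------
# terminal-window depth from alignments


@dataclass
class TerminalWindowDepth:
    scaffold: str
    terminus: str            # 'start' or 'end'
    window: int
    bin_size: int
    bins: np.ndarray         # per-bin mean depth, in scaffold orientation
    window_start: int        # scaffold coordinate of the first bin


def terminal_window_depth(
    alignments: Iterable[AlignmentRecord],
    scaffolds: ScaffoldSet,
    scaffold: str,
    terminus: str,
    window: int = 200_000,
    bin_size: int = 1000,
    mq_min: int = 10,
) -> TerminalWindowDepth:
    """Mean read depth per bin over a terminal window, at MAPQ >= ``mq_min``.

    Depth counts reference-consuming CIGAR operations (M/=/X/D/N);
    duplicate-flagged and sub-threshold alignments contribute nothing.
    """
    if terminus not in ("start", "end"):
        raise ValueError("terminus must be 'start' or 'end'")
    L = scaffolds.length(scaffold)
    span = min(window, L)
    if L < bin_size:
        warnings.warn(f"scaffold {scaffold} shorter than one bin; single partial bin")
    w_start = 0 if terminus == "start" else L - span
    cover = np.zeros(span + 1, dtype=np.int64)  # difference array
    for a in alignments:
        if a.target != scaffold or a.is_duplicate or a.mapq < mq_min:
            continue
        s = a.target_start
        e = s + cigar_reference_length(a.cigar)
        s, e = max(s, w_start), min(e, w_start + span)
        if e > s:
            cover[s - w_start] += 1
            cover[e - w_start] -= 1
    per_base = np.cumsum(cover[:-1])
    n_bins = -(-span // bin_size)
    bins = np.array([per_base[i * bin_size:(i + 1) * bin_size].mean()
                     for i in range(n_bins)])
    return TerminalWindowDepth(scaffold, terminus, window, bin_size, bins, w_start)


# ---------------------------------------------------------------------------
# spanning reads


def _terminus_pos(scaffolds: ScaffoldSet, scaffold: str, terminus: str) -> int:
    return 0 if terminus == "start" else scaffolds.length(scaffold)


def detect_spanning_reads(
    alignments: Iterable[AlignmentRecord],
    bp: BreakpointSpec,
    scaffolds: ScaffoldSet,
    flank: int = 10_000,
) -> int:
    """Count distinct query names with split alignments crossing the junction.

    A query counts once when it has one alignment within ``flank`` of the
    left scaffold's junction-abutting terminus and another (primary or
    supplementary) within ``flank`` of the right scaffold's terminus.
    """
    left_term, right_term = bp.orientation
    targets = {
        bp.left_scaffold: _terminus_pos(scaffolds, bp.left_scaffold, left_term),
        bp.right_scaffold: _terminus_pos(scaffolds, bp.right_scaffold, right_term),
    }
    hits: dict[str, set[str]] = {}
    for a in alignments:
        if a.is_duplicate or a.target not in targets:
            continue
        s = a.target_start
        e = s + cigar_reference_length(a.cigar)
        t = targets[a.target]
        if s - flank <= t <= e + flank:
            hits.setdefault(a.query, set()).add(a.target)
    return sum(1 for sides in hits.values() if len(sides) == 2)


# ---------------------------------------------------------------------------
# coverage fold


@dataclass
class CoverageFold:
    fold: float
    low_mappability: bool
    infinite: bool = False


def junction_depth_track(depth1kb: DepthWindowTable, scaffold: str,
                         junction: int, flank: int = 200_000) -> np.ndarray:
    """Per-1 kb depth bins centered on a junction, spanning ±``flank``."""
    sub = depth1kb.for_scaffold(scaffold)
    lo, hi = junction - flank, junction + flank
    sel = sub[(sub["start"] >= lo) & (sub["start"] < hi)]
    return sel["depth"].to_numpy(dtype=float)


def coverage_fold(track: np.ndarray, core: int = 50_000, flank: int = 200_000,
                  junction_exclude: int = 100_000, bin_size: int = 1000,
                  fold_threshold: float = 2.0) -> CoverageFold:
    """Fold drop of junction-core depth relative to the flanks.

    ``track`` is a junction-centered depth array spanning 2*``flank``. The
    core is the central ``core`` bp. The flank is the outer annulus beyond
    ``junction_exclude`` of the junction (default: the outer 100 kb on each
    side of a ±200 kb track), so a repeat island extending past the core
    does not contaminate the flank estimate; set ``junction_exclude=0`` to
    use everything outside the core. F = median(flank) / median(core); a
    fold of at least ``fold_threshold`` flags the junction as
    low-mappability (a zero core median flags it as infinite).
    """
    track = np.asarray(track, dtype=float)
    n = len(track)
    n_core = max(1, core // bin_size)
    if n_core >= n:
        raise ValueError("core region must be strictly inside the track")
    lo = (n - n_core) // 2
    core_bins = track[lo:lo + n_core]
    n_excl = max(n_core, 2 * (junction_exclude // bin_size))
    elo = (n - n_excl) // 2
    flank_bins = np.concatenate([track[:elo], track[elo + n_excl:]])
    if not len(flank_bins):
        raise ValueError("no flank bins outside the excluded junction zone")
    core_med = float(np.median(core_bins))
    flank_med = float(np.median(flank_bins))
    if core_med == 0:
        return CoverageFold(np.inf, True, infinite=True)
    f = flank_med / core_med
    return CoverageFold(f, f >= fold_threshold)


# ---------------------------------------------------------------------------
# repeat windows


@dataclass
class RepeatWindowProfile:
    """Masked fraction per collapsed repeat class within one window."""

    window_id: str
    scaffold: str
    start: int
    end: int
    class_fractions: dict[str, float]
    total_fraction: float

    @property
    def f_unknown(self) -> float:
        return self.class_fractions.get("unknown", 0.0)


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def window_masked_fraction(annotation: RepeatAnnotation,
                           window: tuple[str, int, int],
                           window_id: Optional[str] = None) -> RepeatWindowProfile:
    """Per-class and total masked fractions of one window.

    Intervals are clipped to the window and merged within each class before
    summing (no double counting); the total fraction comes from the merged
    union across all classes.
    """
    scaffold, start, end = window
    if end <= start:
        raise ValueError("window length must be > 0")
    span = end - start
    sub = annotation.for_scaffold(scaffold)
    sub = sub[(sub["end"] > start) & (sub["start"] < end)]
    clipped = [(max(int(s), start), min(int(e), end), c)
               for s, e, c in zip(sub["start"], sub["end"], sub["class8"])]
    fractions = {}
    for cls in REPEAT_CLASSES:
        fractions[cls] = _merged_length([(s, e) for s, e, c in clipped if c == cls]) / span
    total = _merged_length([(s, e) for s, e, _ in clipped]) / span
    return RepeatWindowProfile(window_id or f"{scaffold}:{start}-{end}",
                               scaffold, start, end, fractions, total)


@dataclass
class RepeatComparison:
    """Junction-vs-control repeat content summary."""

    junction_mean_total: float
    control_mean_total: float
    junction_mean_unknown: float
    control_mean_unknown: float
    repeat_enriched: bool
    junction_profiles: list[RepeatWindowProfile] = field(default_factory=list)
    control_profiles: list[RepeatWindowProfile] = field(default_factory=list)

    @property
    def diff_total(self) -> float:
        return self.junction_mean_total - self.control_mean_total

    @property
    def diff_unknown(self) -> float:
        return self.junction_mean_unknown - self.control_mean_unknown


def compare_junction_repeats(junction_profiles: Sequence[RepeatWindowProfile],
                             control_profiles: Sequence[RepeatWindowProfile]
                             ) -> RepeatComparison:
    """Mean masked fractions (total and unknown-class) at junctions vs controls."""
    if not junction_profiles or not control_profiles:
        raise ValueError("need at least one profile per side")
    jt = float(np.mean([p.total_fraction for p in junction_profiles]))
    ct = float(np.mean([p.total_fraction for p in control_profiles]))
    ju = float(np.mean([p.f_unknown for p in junction_profiles]))
    cu = float(np.mean([p.f_unknown for p in control_profiles]))
    return RepeatComparison(jt, ct, ju, cu, jt > ct,
                            list(junction_profiles), list(control_profiles))
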