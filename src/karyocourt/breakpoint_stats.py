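"""Breakpoint detection from whole-genome alignments and the trans-contact
rate tests against the genome-wide background.

A "breakpoint" is a place where one assembly represents as two scaffolds
what the other represents as one. Candidates are found from PAF alignment
blocks by a partner-coverage rule; each candidate's trans contact rate is
then compared against the empirical distribution of all scaffold-pair
rates in its own assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .formats_io import PafBlock, ScaffoldSet

__all__ = [
    "BreakpointSpec",
    "BreakpointTestResult",
    "IntraComparison",
    "detect_breakpoints",
    "select_control",
    "empirical_pvalue",
    "joint_rank_test",
    "compare_intra",
    "annotate_outgroup_collinearity",
]


@dataclass
class BreakpointSpec:
    """Two scaffolds in one assembly hypothesized to be one chromosome.

    ``orientation`` records which terminus of each split scaffold abuts the
    junction, as ('start'|'end', 'start'|'end') for (left, right).
    """

    id: str
    split_assembly: str
    left_scaffold: str
    right_scaffold: str
    joined_assembly: str
    joined_scaffold: str
    junction_position: int
    orientation: tuple[str, str] = ("end", "start")
    collinear_in_outgroup: Optional[bool] = None

    def __post_init__(self):
        if self.left_scaffold == self.right_scaffold:
            raise ValueError("left and right scaffolds must differ")


@dataclass
class BreakpointTestResult:
    breakpoint_id: str
    observed_rate: float
    background_n: int
    empirical_p: float
    control_rate: Optional[float] = None
    intra_comparison: Optional["IntraComparison"] = None


@dataclass
class IntraComparison:
    """How a trans rate sits against the within-scaffold rate distribution."""

    fraction_above: float  # fraction of intra rates exceeding r_obs
    below_intra: bool      # r_obs < median intra rate


# ---------------------------------------------------------------------------
# detection


def _partner_spans(blocks: Iterable[PafBlock], by: str):
    """Group blocks by the 'joined' side and aggregate per-partner coverage.

    ``by='target'``: joined scaffold is the PAF target, partners are queries.
    Returns {joined: {partner: [blocks]}}.
    """
    grouped: dict[str, dict[str, list[PafBlock]]] = {}
    for b in blocks:
        joined = b.target if by == "target" else b.query
        partner = b.query if by == "target" else b.target
        grouped.setdefault(joined, {}).setdefault(partner, []).append(b)
    return grouped


def _joined_span(b: PafBlock, by: str) -> tuple[int, int]:
    return (b.t_start, b.t_end) if by == "target" else (b.q_start, b.q_end)


def _partner_span(b: PafBlock, by: str) -> tuple[int, int]:
    return (b.q_start, b.q_end) if by == "target" else (b.t_start, b.t_end)


def _terminus(partner_blocks: list[PafBlock], side: str, by: str,
              partner_len: int) -> str:
    """Which terminus of the partner abuts the junction.

    ``side`` is 'left' (partner occupies the left span on the joined
    scaffold) or 'right'. With '+' strand the left partner abuts with
    whichever of its own ends sits at the junction-facing edge of its
    alignment; '-' strand flips it.
    """
    if side == "left":
        blk = max(partner_blocks, key=lambda b: _joined_span(b, by)[1])
    else:
        blk = min(partner_blocks, key=lambda b: _joined_span(b, by)[0])
    ps, pe = _partner_span(blk, by)
    plus = blk.strand == "+"
    if side == "left":
        near_end = pe if plus else ps
    else:
        near_end = ps if plus else pe
    return "end" if near_end > partner_len - near_end else "start"


def _detect_one_direction(
    blocks: list[PafBlock],
    joined_set: ScaffoldSet,
    split_set: ScaffoldSet,
    by: str,
    min_cov_frac: float,
    partner_floor: float,
) -> list[dict]:
    found = []
    for joined, partners in _partner_spans(blocks, by).items():
        if joined not in joined_set:
            continue
        cov = {p: sum(_joined_span(b, by)[1] - _joined_span(b, by)[0] for b in bl)
               for p, bl in partners.items()}
        total = sum(cov.values())
        if total == 0:
            warnings.warn(f"scaffold {joined} has zero aligned bases; skipped")
            continue
        qualifying = [p for p, c in cov.items() if c >= partner_floor * total]
        if len(qualifying) <= 1:
            continue  # 1-to-1 (or dominated) match: no breakpoint
        if len(qualifying) > 2:
            warnings.warn(f"scaffold {joined}: {len(qualifying)}-way partner set; "
                          "reported as complex and excluded from testing")
            continue
        if sum(cov[p] for p in qualifying) < min_cov_frac * total:
            continue
        # order the two partners by their span on the joined scaffold
        spans = {p: (min(_joined_span(b, by)[0] for b in partners[p]),
                     max(_joined_span(b, by)[1] for b in partners[p]))
                 for p in qualifying}
        left, right = sorted(qualifying, key=lambda p: spans[p][0])
        junction = (spans[left][1] + spans[right][0]) // 2
        found.append(dict(
            joined=joined, left=left, right=right, junction=int(junction),
            orientation=(
                _terminus(partners[left], "left", by, split_set.length(left)),
                _terminus(partners[right], "right", by, split_set.length(right)),
            ),
        ))
    found.sort(key=lambda d: joined_set.order(d["joined"]))
    return found


def detect_breakpoints(
    paf_blocks: Sequence[PafBlock],
    set_a: ScaffoldSet,
    set_b: ScaffoldSet,
    min_cov_frac: float = 0.5,
    partner_floor: float = 0.2,
) -> list[BreakpointSpec]:
    """Find 2-way split/join discrepancies between two assemblies.

    ``paf_blocks`` align assembly A (queries) against assembly B (targets).
    A scaffold whose aligned bases are covered by exactly two partner
    scaffolds (each >= ``partner_floor`` of its aligned bases, jointly >=
    ``min_cov_frac``) is a joined scaffold; the two partners are the split
    side. Detection runs in both directions; 3+-way partner sets are
    complex and excluded (with a warning).
    """
    specs = []
    n = 0
    # splits in A (joined scaffold lives in B)
    for d in _detect_one_direction(list(paf_blocks), set_b, set_a, "target",
                                   min_cov_frac, partner_floor):
        n += 1
        specs.append(BreakpointSpec(
            f"BP{n}", set_a.assembly_id, d["left"], d["right"],
            set_b.assembly_id, d["joined"], d["junction"], d["orientation"]))
    # splits in B (joined scaffold lives in A)
    for d in _detect_one_direction(list(paf_blocks), set_a, set_b, "query",
                                   min_cov_frac, partner_floor):
        n += 1
        specs.append(BreakpointSpec(
            f"BP{n}", set_b.assembly_id, d["left"], d["right"],
            set_a.assembly_id, d["joined"], d["junction"], d["orientation"]))
    return specs


def annotate_outgroup_collinearity(
    breakpoints: Sequence[BreakpointSpec],
    outgroup_blocks: Sequence[PafBlock],
    split_assembly_id: str,
    majority_frac: float = 0.5,
) -> None:
    """Annotate breakpoints with outgroup collinearity, in place.

    ``outgroup_blocks`` align the split assembly (queries) against an
    outgroup assembly (targets). A breakpoint is collinear when both split
    scaffolds map by majority (>= ``majority_frac`` of aligned bases) to
    the same outgroup scaffold.
    """
    cov: dict[str, dict[str, int]] = {}
    for b in outgroup_blocks:
        cov.setdefault(b.query, {})[b.target] = (
            cov.get(b.query, {}).get(b.target, 0) + (b.q_end - b.q_start))

    def majority(scaffold: str) -> Optional[str]:
        c = cov.get(scaffold)
        if not c:
            return None
        total = sum(c.values())
        best = max(c, key=c.get)
        return best if c[best] >= majority_frac * total else None

    for bp in breakpoints:
        if bp.split_assembly != split_assembly_id:
            continue
        ml, mr = majority(bp.left_scaffold), majority(bp.right_scaffold)
        bp.collinear_in_outgroup = (ml is not None and ml == mr)


# ---------------------------------------------------------------------------
# controls and statistics


def select_control(bp: BreakpointSpec, opposing: ScaffoldSet,
                   involved: set[str]) -> str:
    """Nearest-length uninvolved scaffold from the joined scaffold's assembly.

    Ties break toward the smaller order index.
    """
    L0 = opposing.length(bp.joined_scaffold)
    candidates = [s for s in opposing
                  if s.name not in involved and s.name != bp.joined_scaffold]
    if not candidates:
        raise ValueError("no uninvolved scaffold available as control")
    return min(candidates, key=lambda s: (abs(s.length - L0), s.order_index)).name


def empirical_pvalue(r_obs: float, background: Sequence[float],
                     floor: int = 20) -> float:
    """Fraction of genome-wide scaffold-pair rates >= the observed rate.

    When the breakpoint pair itself is part of the background (the
    default convention), p is bounded below by 1/n and never zero.
    """
    bg = np.asarray(background, dtype=float)
    if len(bg) < floor:
        raise ValueError(
            f"background of {len(bg)} scaffold-pair rates is below the floor of "
            f"{floor}; use an assembly with more scaffolds")
    return float((bg >= r_obs).sum() / len(bg))


def joint_rank_test(breakpoint_rates: Sequence[float],
                    background: Sequence[float]) -> tuple[float, float]:
    """One-tailed (greater) Wilcoxon rank-sum of breakpoint rates vs background.

    Uses the exact null distribution when there are no ties and
    n*m <= 10^4; otherwise midranks with tie correction and a normal
    approximation with continuity correction. Returns (U for the
    breakpoint sample, one-tailed p).
    """
    x = np.asarray(breakpoint_rates, dtype=float)
    y = np.asarray(background, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (no_ties and len(x) * len(y) <= 10_000) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_intra(r_obs: float, intra_rates: Sequence[float]) -> IntraComparison:
    """Place a trans rate against the within-scaffold rate distribution."""
    rates = np.asarray(list(intra_rates), dtype=float)
    fraction = float((rates > r_obs).mean()) if len(rates) else 0.0
    below = bool(len(rates)) and r_obs < float(np.median(rates))
    return IntraComparison(fraction, below)
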