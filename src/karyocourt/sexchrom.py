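"""Coverage-based sex-chromosome identification and qPCR ΔCq sex calling.

In a ZZ/Z0 system the female carries a single Z, so the Z shows ~half
depth in a female sample. Windowed depth is normalized to the median of
the first chromosome; each chromosome's windows are then tested against
all remaining chromosomes with a one-sided rank-sum (alternative "less"),
p-values are Benjamini-Hochberg adjusted, and a chromosome is called only
when its median normalized depth has dropped by at least 10%.

The qPCR classifier uses ΔCq = mean(A_Cq) − mean(S_Cq) with positive
values diagnostic of males (ZZ) and negative of females (Z0). That sign
convention is the reverse of the naive copy-number expectation for a ZZ
male; it is applied as stated and the raw ΔCq is surfaced for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .formats_io import DepthWindowTable

__all__ = ["SexCallResult", "QpcrResult", "normalize_depth",
           "call_sex_chromosomes", "classify_sex_qpcr"]


@dataclass
class SexCallResult:
    chromosome: str
    median_normalized_depth: float
    decrease: float           # 1 - median normalized depth
    p_value: float
    q_value: float
    called: bool
    n_windows: int


@dataclass
class QpcrResult:
    a_cq: np.ndarray
    s_cq: np.ndarray
    delta_cq: float
    call: str  # male | female | indeterminate


def normalize_depth(windows: DepthWindowTable,
                    reference_chrom: Optional[str] = None) -> DepthWindowTable:
    """Divide all window depths by the reference chromosome's median depth.

    The reference defaults to the first chromosome in table order.
    """
    table = windows.table
    if reference_chrom is None:
        if not len(table):
            raise ValueError("empty depth table")
        reference_chrom = table["scaffold"].iloc[0]
    ref = table.loc[table["scaffold"] == reference_chrom, "depth"]
    if not len(ref):
        raise ValueError(f"reference chromosome {reference_chrom!r} has no windows")
    med = float(ref.median())
    if med == 0:
        raise ValueError(f"reference chromosome {reference_chrom!r} has zero median depth")
    return windows.scaled(1.0 / med)


def _rank_sum_less(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (less) rank-sum p; exact for tiny tie-free samples else midranks."""
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (no_ties and len(x) * len(y) <= 10_000) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="less", method=method,
                                    use_continuity=True).pvalue)


def call_sex_chromosomes(normalized: DepthWindowTable, alpha: float = 0.05,
                         min_decrease: float = 0.10,
                         min_windows: int = 5) -> list[SexCallResult]:
    """Test each chromosome's normalized windows against all the others.

    A chromosome is called as a putative sex chromosome when its BH-adjusted
    one-sided (less) rank-sum q-value is below ``alpha`` AND its median
    normalized depth shows at least ``min_decrease`` decrease.
    """
    table = normalized.table
    chroms = list(dict.fromkeys(table["scaffold"]))
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes")
    depths = {c: table.loc[table["scaffold"] == c, "depth"].to_numpy(dtype=float)
              for c in chroms}
    tested = []
    for c in chroms:
        if len(depths[c]) < min_windows:
            warnings.warn(f"chromosome {c} has {len(depths[c])} < {min_windows} "
                          "windows; excluded from testing")
            continue
        tested.append(c)
    pvals = []
    for c in tested:
        rest = np.concatenate([depths[o] for o in tested if o != c])
        pvals.append(_rank_sum_less(depths[c], rest))
    qvals = stats.false_discovery_control(pvals, method="bh") if pvals else []
    results = []
    for c, p, q in zip(tested, pvals, qvals):
        m = float(np.median(depths[c]))
        dec = 1.0 - m
        results.append(SexCallResult(
            c, m, dec, p, float(q),
            called=bool(q < alpha and dec >= min_decrease),
            n_windows=len(depths[c]),
        ))
    return results


def classify_sex_qpcr(a_reps: Sequence[float], s_reps: Sequence[float],
                      epsilon: float = 0.0) -> QpcrResult:
    """Classify sex from qPCR Cq replicates via the sign of ΔCq.

    ΔCq = mean(A_Cq) − mean(S_Cq); ΔCq > ε → male (ZZ), ΔCq < −ε →
    female (Z0), otherwise indeterminate (dead zone of width 2ε).
    """
    a = np.asarray(a_reps, dtype=float)
    s = np.asarray(s_reps, dtype=float)
    if len(a) == 0 or len(s) == 0:
        raise ValueError("need at least one replicate per assay")
    if not (np.isfinite(a).all() and np.isfinite(s).all()):
        raise ValueError("non-finite Cq value")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    delta = float(a.mean() - s.mean())
    if delta > epsilon:
        call = "male"
    elif delta < -epsilon:
        call = "female"
    else:
        call = "indeterminate"
    return QpcrResult(a, s, delta, call)
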