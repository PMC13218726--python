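"""Per-scaffold-pair trans contact counts, length-normalized rates, and
binned trans density tracks.

Rates follow the pairs-per-Mb^2 convention: for scaffolds i < j with
lengths L_i, L_j (bp) and T_ij trans pairs, r_ij = T_ij / ((L_i/1e6) *
(L_j/1e6)). Zero-count scaffold pairs get rate 0 and are part of the
genome-wide background distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .formats_io import PairRecord, ScaffoldSet, pairs_to_frame

__all__ = ["ContactRateTable", "TransDensityTrack", "count_contacts", "bin_trans_density"]

PairsInput = Union[pd.DataFrame, Iterable[PairRecord]]

MB = 1e6


def _as_frame(pairs: PairsInput) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    return pairs_to_frame(pairs)


def _codes(df: pd.DataFrame, scaffolds: ScaffoldSet) -> tuple[np.ndarray, np.ndarray]:
    order = {s.name: s.order_index for s in scaffolds}
    c1 = df["scaffold1"].map(order)
    c2 = df["scaffold2"].map(order)
    if c1.isna().any() or c2.isna().any():
        bad = df.loc[c1.isna() | c2.isna(), ["scaffold1", "scaffold2"]].iloc[0]
        raise ValueError(
            f"pair references scaffold absent from set {scaffolds.assembly_id!r}: "
            f"{bad['scaffold1']!r}/{bad['scaffold2']!r}"
        )
    return c1.to_numpy(dtype=np.int64), c2.to_numpy(dtype=np.int64)


@dataclass
class ContactRateTable:
    """Trans counts/rates over all scaffold pairs plus intra-scaffold counts."""

    scaffolds: ScaffoldSet
    trans_counts: dict[tuple[str, str], int]  # all i<j pairs, zeros included
    intra_counts: dict[str, int]              # intra pairs with separation > min_intra_sep
    n_short_intra: int                        # intra pairs at separation <= min_intra_sep
    min_intra_sep: int

    @property
    def n_total(self) -> int:
        return sum(self.trans_counts.values()) + sum(self.intra_counts.values()) + self.n_short_intra

    def rate(self, i: str, j: str) -> float:
        key = self._key(i, j)
        L = self.scaffolds
        return self.trans_counts[key] / ((L.length(key[0]) / MB) * (L.length(key[1]) / MB))

    def _key(self, i: str, j: str) -> tuple[str, str]:
        if self.scaffolds.order(i) > self.scaffolds.order(j):
            i, j = j, i
        return (i, j)

    @property
    def trans_rates(self) -> dict[tuple[str, str], float]:
        return {k: self.rate(*k) for k in self.trans_counts}

    def background_rates(self, exclude: Optional[set[tuple[str, str]]] = None) -> np.ndarray:
        """All genome-wide scaffold-pair rates (optionally excluding given pairs)."""
        excl = {self._key(*p) for p in exclude} if exclude else set()
        return np.array([self.rate(*k) for k in self.trans_counts if k not in excl])

    def intra_rates(self) -> dict[str, float]:
        """Within-scaffold rates I_i / (L_i/Mb)^2."""
        return {
            name: self.intra_counts[name] / ((self.scaffolds.length(name) / MB) ** 2)
            for name in self.scaffolds.names
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), t in self.trans_counts.items():
            rows.append((i, j, self.scaffolds.length(i), self.scaffolds.length(j),
                         t, self.rate(i, j)))
        return pd.DataFrame(rows, columns=[
            "scaffold_i", "scaffold_j", "L_i", "L_j", "T_ij", "rate_pairs_per_Mb2"])


def count_contacts(pairs: PairsInput, scaffolds: ScaffoldSet,
                   min_intra_sep: int = 1000) -> ContactRateTable:
    """Single-pass tally of trans and intra-scaffold pair counts.

    Every trans pair increments exactly one T_ij; intra pairs increment I_i
    only when their separation strictly exceeds ``min_intra_sep`` (shorter
    ones are tallied separately so the totals are conserved). Rates cover
    all scaffold pairs, including zero-count ones.
    """
    df = _as_frame(pairs)
    names = scaffolds.names
    trans_counts: dict[tuple[str, str], int] = {
        (names[i], names[j]): 0 for i in range(len(names)) for j in range(i + 1, len(names))
    }
    intra_counts = {n: 0 for n in names}
    n_short = 0
    if len(df):
        c1, c2 = _codes(df, scaffolds)
        pos1 = df["pos1"].to_numpy(dtype=np.int64)
        pos2 = df["pos2"].to_numpy(dtype=np.int64)
        lo = np.minimum(c1, c2)
        hi = np.maximum(c1, c2)
        trans = lo != hi
        key = lo * len(names) + hi
        uniq, cnt = np.unique(key[trans], return_counts=True)
        for k, n in zip(uniq, cnt):
            trans_counts[(names[k // len(names)], names[k % len(names)])] = int(n)
        intra = ~trans
        sep = np.abs(pos2[intra] - pos1[intra])
        far = sep > min_intra_sep
        n_short = int((~far).sum())
        iu, icnt = np.unique(c1[intra][far], return_counts=True)
        for k, n in zip(iu, icnt):
            intra_counts[names[k]] = int(n)
    return ContactRateTable(scaffolds, trans_counts, intra_counts, n_short, min_intra_sep)


@dataclass
class TransDensityTrack:
    """Counts of trans pair ends per fixed-size bin along each scaffold."""

    scaffolds: ScaffoldSet
    bin_size: int
    bins: dict[str, np.ndarray]

    def total_mass(self) -> int:
        return int(sum(b.sum() for b in self.bins.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.bins.items():
            L = self.scaffolds.length(name)
            for i, c in enumerate(arr):
                rows.append((name, i * self.bin_size, min((i + 1) * self.bin_size, L), int(c)))
        return pd.DataFrame(rows, columns=["scaffold", "start", "end", "trans_ends"])


def bin_trans_density(pairs: PairsInput, scaffolds: ScaffoldSet,
                      bin_size: int = 500_000) -> TransDensityTrack:
    """Histogram trans pair ends into fixed bins along each scaffold.

    Each trans pair contributes one count at each of its two ends, so the
    total track mass is twice the trans pair count. The final partial bin
    is retained.
    """
    df = _as_frame(pairs)
    names = scaffolds.names
    n_bins = {n: -(-scaffolds.length(n) // bin_size) for n in names}
    bins = {n: np.zeros(n_bins[n], dtype=np.int64) for n in names}
    if len(df):
        c1, c2 = _codes(df, scaffolds)
        trans = c1 != c2
        for col_c, col_p in ((c1, "pos1"), (c2, "pos2")):
            pos = df[col_p].to_numpy(dtype=np.int64)[trans]
            codes = col_c[trans]
            for ci in np.unique(codes):
                name = names[ci]
                idx = pos[codes == ci] // bin_size
                np.add.at(bins[name], idx, 1)
    return TransDensityTrack(scaffolds, bin_size, bins)
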