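"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based, half-open; conversions to and from
other conventions (RepeatMasker ``.out`` is 1-based inclusive) happen only
at the format boundary.  The pairs dialect used here is the tab-separated
4DN layout (``readID chrom1 pos1 chrom2 pos2 strand1 strand2 pair_type``,
``#``-prefixed headers) with positions interpreted as 0-based.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scaffold",
    "ScaffoldSet",
    "PairRecord",
    "PafBlock",
    "AlignmentRecord",
    "RepeatAnnotation",
    "DepthWindowTable",
    "REPEAT_CLASSES",
    "collapse_repeat_class",
    "read_fai",
    "write_fai",
    "read_pairs",
    "write_pairs",
    "pairs_to_frame",
    "frame_to_pairs",
    "read_paf",
    "read_repeat_annotation",
    "write_repeat_bed",
    "read_depth_bed",
    "write_depth_bed",
    "read_sam_alignments",
    "read_alignment_tsv",
    "read_qpcr_table",
    "cigar_reference_length",
]


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


# ---------------------------------------------------------------------------
# scaffold sets


class Scaffold(NamedTuple):
    name: str
    length: int
    order_index: int


class ScaffoldSet:
    """An ordered collection of named sequences with lengths.

    The order index defines the canonical sort used for pair records
    (upper-triangle convention) and identifies the "first chromosome"
    used as the depth-normalization reference.
    """

    def __init__(self, assembly_id: str, entries: Sequence[tuple[str, int]]):
        self.assembly_id = assembly_id
        self._entries: dict[str, Scaffold] = {}
        for i, (name, length) in enumerate(entries):
            if name in self._entries:
                raise ValueError(f"duplicate scaffold name {name!r}")
            if length < 1:
                raise ValueError(f"scaffold {name!r} has length {length} < 1")
            self._entries[name] = Scaffold(name, int(length), i)

    @classmethod
    def from_fai(cls, path: str | Path, assembly_id: Optional[str] = None) -> "ScaffoldSet":
        return read_fai(path, assembly_id=assembly_id)

    # -- container protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self._entries.values())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ScaffoldSet({self.assembly_id!r}, n={len(self)})"

    # -- accessors -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self], dtype=np.int64)

    def length(self, name: str) -> int:
        return self._entries[name].length

    def order(self, name: str) -> int:
        return self._entries[name].order_index

    def total_length(self) -> int:
        return int(self.lengths.sum())

    def to_fai(self, path: str | Path) -> None:
        write_fai(self, path)


def read_fai(path: str | Path, assembly_id: Optional[str] = None) -> ScaffoldSet:
    """Read a ``.fai``-style length table (name, length in the first two columns)."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
            try:
                entries.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
    return ScaffoldSet(assembly_id or Path(path).stem, entries)


def write_fai(scaffolds: ScaffoldSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in scaffolds:
            fh.write(f"{s.name}\t{s.length}\n")


# ---------------------------------------------------------------------------
# Hi-C pairs


class PairRecord(NamedTuple):
    """One Hi-C contact, canonically ordered (end 1 <= end 2)."""

    read_id: str
    scaffold1: str
    pos1: int
    scaffold2: str
    pos2: int
    strand1: str
    strand2: str
    pair_type: str


def _canonical(rec: PairRecord, scaffolds: Optional[ScaffoldSet]) -> PairRecord:
    if scaffolds is not None:
        k1 = (scaffolds.order(rec.scaffold1), rec.pos1)
        k2 = (scaffolds.order(rec.scaffold2), rec.pos2)
    else:
        k1 = (rec.scaffold1, rec.pos1)
        k2 = (rec.scaffold2, rec.pos2)
    if k1 <= k2:
        return rec
    return PairRecord(rec.read_id, rec.scaffold2, rec.pos2, rec.scaffold1, rec.pos1,
                      rec.strand2, rec.strand1, rec.pair_type)


def read_pairs(
    path: str | Path,
    scaffolds: Optional[ScaffoldSet] = None,
    keep_pair_types: Optional[set[str]] = None,
) -> Iterator[PairRecord]:
    """Stream pair records, keeping only the requested pair types (default ``{"UU"}``).

    When a :class:`ScaffoldSet` is supplied, scaffold membership and position
    bounds (``0 <= pos < L``) are enforced and canonical ordering follows the
    set's order index; otherwise ordering is lexicographic.
    """
    keep = keep_pair_types if keep_pair_types is not None else {"UU"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected >=7 columns, got {len(fields)}")
            read_id, s1, p1, s2, p2, st1, st2 = fields[:7]
            pair_type = fields[7] if len(fields) >= 8 else "UU"
            try:
                pos1, pos2 = int(p1), int(p2)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            if pair_type not in keep:
                continue
            if scaffolds is not None:
                for s, p in ((s1, pos1), (s2, pos2)):
                    if s not in scaffolds:
                        raise FormatError(f"{path}:{lineno}: unknown scaffold {s!r}")
                    if not (0 <= p < scaffolds.length(s)):
                        raise FormatError(
                            f"{path}:{lineno}: position {p} outside [0, {scaffolds.length(s)}) on {s}"
                        )
            yield _canonical(PairRecord(read_id, s1, pos1, s2, pos2, st1, st2, pair_type), scaffolds)


PAIRS_COLUMNS = ["read_id", "scaffold1", "pos1", "scaffold2", "pos2", "strand1", "strand2", "pair_type"]


def write_pairs(
    records: Iterable[PairRecord] | pd.DataFrame,
    path: str | Path,
    scaffolds: Optional[ScaffoldSet] = None,
) -> None:
    """Write records in the pairs dialect, sorted upper-triangle when a set is given."""
    df = records if isinstance(records, pd.DataFrame) else pairs_to_frame(records)
    df = df.copy()
    if scaffolds is not None:
        order = {s.name: s.order_index for s in scaffolds}
        df["_o1"] = df["scaffold1"].map(order)
        df["_o2"] = df["scaffold2"].map(order)
        df = df.sort_values(["_o1", "pos1", "_o2", "pos2"], kind="stable").drop(columns=["_o1", "_o2"])
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        if scaffolds is not None:
            for s in scaffolds:
                fh.write(f"#chromsize: {s.name} {s.length}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2 pair_type\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=PAIRS_COLUMNS)


def pairs_to_frame(records: Iterable[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(list(records), columns=PAIRS_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> Iterator[PairRecord]:
    for row in df.itertuples(index=False):
        yield PairRecord(row.read_id, row.scaffold1, int(row.pos1), row.scaffold2,
                         int(row.pos2), row.strand1, row.strand2, row.pair_type)


# ---------------------------------------------------------------------------
# PAF whole-genome alignment blocks


class PafBlock(NamedTuple):
    query: str
    q_len: int
    q_start: int
    q_end: int
    strand: str
    target: str
    t_len: int
    t_start: int
    t_end: int
    matches: int
    block_len: int
    mapq: int


def read_paf(path: str | Path, min_block: int = 10_000) -> list[PafBlock]:
    """Read a 12+-column PAF, dropping blocks shorter than ``min_block``."""
    blocks: list[PafBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >=12 columns, got {len(f)}")
            try:
                blk = PafBlock(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]), int(f[9]), int(f[10]), int(f[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate field") from exc
            if blk.block_len >= min_block:
                blocks.append(blk)
    return blocks


def write_paf(blocks: Iterable[PafBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write("\t".join(str(x) for x in b) + "\n")


# ---------------------------------------------------------------------------
# repeat annotations

REPEAT_CLASSES = ("SINE", "LINE", "DNA", "LTR", "simple", "low_complexity", "unknown", "other")

_CLASS8_RULES = [
    (re.compile(r"^SINE", re.I), "SINE"),
    (re.compile(r"^LINE", re.I), "LINE"),
    (re.compile(r"^(DNA|RC)", re.I), "DNA"),
    (re.compile(r"^LTR", re.I), "LTR"),
    (re.compile(r"^Simple_repeat", re.I), "simple"),
    (re.compile(r"^Low_complexity", re.I), "low_complexity"),
    (re.compile(r"^Unknown", re.I), "unknown"),
]


def collapse_repeat_class(raw: str) -> str:
    """Collapse a RepeatMasker class/family string into one of eight classes.

    SINE, LINE, DNA transposons (incl. rolling-circle), LTR elements, simple
    repeats, low-complexity, unknown; everything else (satellites, small
    RNAs, retroposons, ...) falls through to "other".
    """
    for pat, label in _CLASS8_RULES:
        if pat.match(raw):
            return label
    return "other"


@dataclass
class RepeatAnnotation:
    """Repeat intervals with raw and collapsed (eight-way) classes.

    Backed by a DataFrame with columns scaffold, start, end, raw_class,
    class8; coordinates 0-based half-open.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["scaffold", "start", "end", "raw_class", "class8"]))

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not (t["start"] < t["end"]).all():
            bad = t[~(t["start"] < t["end"])].iloc[0]
            raise FormatError(f"repeat interval with start >= end on {bad['scaffold']}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def intervals(self) -> list[tuple[str, int, int, str, str]]:
        return list(self.table.itertuples(index=False, name=None))

    def total_bases(self) -> int:
        """Sum of interval spans (overlaps counted multiply)."""
        return int((self.table["end"] - self.table["start"]).sum())

    def for_scaffold(self, name: str) -> pd.DataFrame:
        return self.table[self.table["scaffold"] == name]


def read_repeat_annotation(path: str | Path, dialect: str = "rmout") -> RepeatAnnotation:
    """Parse repeat annotations from RepeatMasker ``.out`` or BED4.

    ``.out`` coordinates are 1-based inclusive and converted to 0-based
    half-open; BED is passed through. The class string (``.out`` column 11,
    BED column 4) is collapsed to the eight-way scheme.
    """
    rows = []
    if dialect == "rmout":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if lineno <= 3 or not line.strip():
                    continue  # 3 header lines
                f = line.split()
                if len(f) < 11:
                    raise FormatError(f"{path}:{lineno}: expected >=11 fields, got {len(f)}")
                try:
                    begin, end = int(f[5]), int(f[6])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
                rows.append((f[4], begin - 1, end, f[10], collapse_repeat_class(f[10])))
    elif dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise FormatError(f"{path}:{lineno}: BED4 needs >=4 columns")
                rows.append((f[0], int(f[1]), int(f[2]), f[3], collapse_repeat_class(f[3])))
    else:
        raise ValueError(f"unknown repeat dialect {dialect!r} (expected 'rmout' or 'bed')")
    table = pd.DataFrame(rows, columns=["scaffold", "start", "end", "raw_class", "class8"])
    return RepeatAnnotation(table)


def write_repeat_bed(annotation: RepeatAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\traw_class\tclass8\n")
        annotation.table.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# depth windows


@dataclass
class DepthWindowTable:
    """Per-window mean read depth (mosdepth-style regions)."""

    table: pd.DataFrame  # scaffold, start, end, depth
    window_size: int

    def __post_init__(self) -> None:
        if len(self.table) and (self.table["depth"] < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.table)

    def for_scaffold(self, name: str) -> pd.DataFrame:
        return self.table[self.table["scaffold"] == name]

    def depths(self, name: str) -> np.ndarray:
        return self.for_scaffold(name)["depth"].to_numpy(dtype=float)

    def scaled(self, factor: float) -> "DepthWindowTable":
        t = self.table.copy()
        t["depth"] = t["depth"] * factor
        return DepthWindowTable(t, self.window_size)


def read_depth_bed(path: str | Path, window_size: Optional[int] = None) -> DepthWindowTable:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: regions BED needs 4 columns")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    table = pd.DataFrame(rows, columns=["scaffold", "start", "end", "depth"])
    if window_size is None:
        window_size = int((table["end"] - table["start"]).max()) if len(table) else 0
    return DepthWindowTable(table, window_size)


def write_depth_bed(depth: DepthWindowTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\tdepth\n")
        depth.table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# alignments (SAM text or 7-column TSV)


class AlignmentRecord(NamedTuple):
    query: str
    target: str
    target_start: int  # 0-based
    mapq: int
    cigar: str
    is_supplementary: bool
    is_duplicate: bool


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def cigar_reference_length(cigar: str) -> int:
    """Reference span consumed by a CIGAR string (M/=/X/D/N operations)."""
    if cigar in ("*", ""):
        return 0
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_CONSUMING)


def read_sam_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read SAM text via pysam into lightweight alignment records (unmapped dropped)."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            records.append(AlignmentRecord(
                aln.query_name, aln.reference_name, aln.reference_start,
                aln.mapping_quality, aln.cigarstring or "*",
                aln.is_supplementary, aln.is_duplicate,
            ))
    return records


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Read the 7-column tabular alignment dialect.

    Columns: query, target, target_start (0-based), mapq, cigar,
    is_supplementary (0/1), is_duplicate (0/1).
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(f)}")
            records.append(AlignmentRecord(
                f[0], f[1], int(f[2]), int(f[3]), f[4], bool(int(f[5])), bool(int(f[6]))
            ))
    return records


def drop_duplicates(alignments: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    return [a for a in alignments if not a.is_duplicate]


# ---------------------------------------------------------------------------
# qPCR tables


def read_qpcr_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a qPCR Cq replicate TSV with columns ``assay`` and ``cq``.

    Assay labels starting with ``A``/``auto`` are the autosomal locus,
    ``S``/``sex`` the sex-chromosomal locus. Returns (A_Cq, S_Cq) arrays.
    """
    df = pd.read_csv(path, sep="\t", comment=None)
    cols = {c.lower(): c for c in df.columns}
    if "assay" not in cols or "cq" not in cols:
        raise FormatError(f"{path}: expected columns 'assay' and 'cq', got {list(df.columns)}")
    assay = df[cols["assay"]].astype(str).str.lower()
    cq = df[cols["cq"]].astype(float)
    a = cq[assay.str.startswith("a")].to_numpy()
    s = cq[assay.str.startswith("s")].to_numpy()
    if len(a) == 0 or len(s) == 0:
        raise FormatError(f"{path}: need at least one replicate per assay")
    return a, s
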