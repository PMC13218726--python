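"""Seeded simulator for karyotype-adjudication inputs.

Generates a "true" genome of K chromosomes with a repeat-density landscape,
derives assemblies from it by splitting chromosomes at repeat-rich
junctions, and emits the data the downstream stages consume: Hi-C pairs
under a power-law distance-decay contact model with a uniform trans
background and mappability loss, Poisson read-depth tracks (with a
half-depth Z chromosome for Z0 females), and qPCR Cq replicates.

The simulator works on a 1 kb lattice: chromosome lengths are multiples of
1 kb and split positions are rounded to 1 kb, so depth bins lift exactly
between the true genome and any derived assembly.

Contact model
-------------
With probability ``1 - beta`` a pair is cis: a chromosome is chosen
proportional to length, the first end uniformly, and the separation ``s``
from ``P(s) ∝ s^(-alpha)`` truncated to ``[s_min, L]`` (pairs falling off
the chromosome are resampled). With probability ``beta`` the pair is
trans: both ends uniform over the genome on distinct chromosomes. Each
end is then independently lost with probability ``gamma * density(bin)``;
a lost end discards the whole pair (mimicking unmapped-mate filtering),
and ``n_pairs`` counts *emitted* pairs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    DepthWindowTable,
    PafBlock,
    RepeatAnnotation,
    ScaffoldSet,
    write_depth_bed,
    write_fai,
    write_paf,
    write_pairs,
    write_repeat_bed,
)

BIN = 1000  # simulator lattice (bp)

# representative RepeatMasker class strings per collapsed class
_RAW_CLASS = {
    "SINE": "SINE/tRNA",
    "LINE": "LINE/L2",
    "DNA": "DNA/hAT",
    "LTR": "LTR/Gypsy",
    "simple": "Simple_repeat",
    "low_complexity": "Low_complexity",
    "unknown": "Unknown",
    "other": "Satellite",
}
_BASE_CLASS_P = {
    "unknown": 0.45, "LINE": 0.12, "DNA": 0.09, "LTR": 0.08,
    "simple": 0.09, "low_complexity": 0.06, "other": 0.10, "SINE": 0.01,
}
_JUNCTION_CLASS_P = {
    "unknown": 0.95, "LINE": 0.01, "DNA": 0.01, "LTR": 0.01,
    "simple": 0.005, "low_complexity": 0.005, "other": 0.005, "SINE": 0.005,
}

# rng substream tags
_TAG_GENOME, _TAG_PAIRS, _TAG_DEPTH, _TAG_QPCR = 0, 1, 2, 3


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), tag])


SplitSpec = tuple  # (chrom, pos) or (chrom, pos, junction_mean)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults are desk-scale: K=8 chromosomes of 3-10 Mb, 5x10^5 emitted
    Hi-C pairs with decay exponent 1.0 and 10% trans background, 23x mean
    depth (a typical HiFi coverage for a large genome), baseline masked
    fraction 0.67 rising to 0.72 at planted junctions (repeat landscapes
    of ~67% genome-wide with enriched junctions), and a mild
    mappability-loss coefficient.
    """

    n_chrom: int = 8
    chrom_lengths: Optional[tuple[int, ...]] = None
    alpha: float = 1.0
    beta: float = 0.1
    s_min: int = 1000
    n_pairs: int = 500_000
    depth_lambda: float = 23.0
    gamma: float = 0.3
    repeat_base_mean: float = 0.67
    repeat_junction_mean: float = 0.72
    repeat_concentration: float = 50.0
    junction_halfwidth: int = 100_000
    sex: str = "ZZ"
    z_chrom: Optional[str] = None
    seed: int = 0
    planned_splits: tuple[SplitSpec, ...] = ()

    def __post_init__(self):
        if self.n_chrom < 2:
            raise ValueError("need K >= 2 chromosomes")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        for name in ("repeat_base_mean", "repeat_junction_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sex not in ("ZZ", "Z0"):
            raise ValueError("sex must be 'ZZ' or 'Z0'")
        lengths = self.resolved_lengths()
        if len(lengths) != self.n_chrom:
            raise ValueError("chrom_lengths must have n_chrom entries")
        if min(lengths) < 10 * self.s_min:
            raise ValueError("all chromosome lengths must be >= 10 * s_min")
        object.__setattr__(self, "chrom_lengths", lengths)
        # quantize planned split positions to the 1 kb lattice
        splits = tuple(
            (s[0], BIN * int(round(s[1] / BIN)), *s[2:]) for s in self.planned_splits
        )
        object.__setattr__(self, "planned_splits", splits)

    def resolved_lengths(self) -> tuple[int, ...]:
        if self.chrom_lengths is not None:
            lengths = tuple(BIN * int(round(L / BIN)) for L in self.chrom_lengths)
        else:
            lengths = tuple(
                BIN * int(round(x / BIN))
                for x in np.linspace(3e6, 10e6, self.n_chrom)
            )
        return lengths

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


def desk_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default desk-scale conditions (K=8, 3-10 Mb chromosomes)."""
    return SimulationConfig(seed=seed, **overrides)


def karyotype_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A K=46 preset with scaled-down chromosome sizes (2-6 Mb)."""
    kw = dict(
        n_chrom=46,
        chrom_lengths=tuple(int(x) for x in np.linspace(2e6, 6e6, 46)),
        n_pairs=2_000_000,
    )
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# true genome


@dataclass
class Genome:
    """The simulated truth: chromosomes, repeat landscape, and config."""

    chromosomes: ScaffoldSet
    density: dict[str, np.ndarray]  # per-1kb masked fraction
    repeats: RepeatAnnotation       # true coordinates
    config: SimulationConfig

    def chrom_length(self, name: str) -> int:
        return self.chromosomes.length(name)


def _draw_masked_fraction(rng: np.random.Generator, mean: float, nu: float, n: int) -> np.ndarray:
    if mean <= 0.0:
        return np.zeros(n)
    if mean >= 1.0:
        return np.ones(n)
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=n)


def simulate_genome(config: SimulationConfig) -> Genome:
    """Draw the true genome: repeat density per 1 kb bin and its annotation.

    Bins within ``junction_halfwidth`` of each planned split are drawn
    around ``repeat_junction_mean`` (or a per-split override), the rest
    around ``repeat_base_mean``. Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, _TAG_GENOME)
    names = config.chrom_names()
    lengths = dict(zip(names, config.chrom_lengths))
    splits_by_chrom: dict[str, list[tuple[int, float]]] = {}
    for s in config.planned_splits:
        chrom, pos = s[0], int(s[1])
        jmean = float(s[2]) if len(s) > 2 else config.repeat_junction_mean
        if chrom not in lengths:
            raise ValueError(f"planned split on unknown chromosome {chrom!r}")
        if pos < config.s_min or pos > lengths[chrom] - config.s_min:
            raise ValueError(
                f"split at {chrom}:{pos} within s_min={config.s_min} of a chromosome end"
            )
        splits_by_chrom.setdefault(chrom, []).append((pos, jmean))

    density: dict[str, np.ndarray] = {}
    repeat_rows: list[pd.DataFrame] = []
    class_labels = list(_BASE_CLASS_P)
    p_base = np.array([_BASE_CLASS_P[c] for c in class_labels])
    p_junc = np.array([_JUNCTION_CLASS_P[c] for c in class_labels])
    for chrom in names:
        n_bins = lengths[chrom] // BIN
        dens = _draw_masked_fraction(rng, config.repeat_base_mean,
                                     config.repeat_concentration, n_bins)
        is_junction = np.zeros(n_bins, dtype=bool)
        for pos, jmean in splits_by_chrom.get(chrom, []):
            lo = max(0, (pos - config.junction_halfwidth) // BIN)
            hi = min(n_bins, -(-(pos + config.junction_halfwidth) // BIN))
            dens[lo:hi] = _draw_masked_fraction(rng, jmean,
                                                config.repeat_concentration, hi - lo)
            is_junction[lo:hi] = True
        density[chrom] = dens

        masked = np.rint(dens * BIN).astype(np.int64)
        cls_idx = np.where(
            is_junction,
            rng.choice(len(class_labels), size=n_bins, p=p_junc),
            rng.choice(len(class_labels), size=n_bins, p=p_base),
        )
        keep = masked > 0
        starts = np.arange(n_bins, dtype=np.int64)[keep] * BIN
        cls = np.array(class_labels, dtype=object)[cls_idx[keep]]
        repeat_rows.append(pd.DataFrame({
            "scaffold": chrom,
            "start": starts,
            "end": starts + masked[keep],
            "raw_class": [_RAW_CLASS[c] for c in cls],
            "class8": cls,
        }))

    repeats = RepeatAnnotation(pd.concat(repeat_rows, ignore_index=True))
    chromset = ScaffoldSet("truth", [(c, lengths[c]) for c in names])
    return Genome(chromset, density, repeats, config)


# ---------------------------------------------------------------------------
# assembly derivation and liftover


@dataclass
class AssemblyDerivation:
    """Mapping between true chromosomes and the scaffolds derived from them."""

    assembly_id: str
    split_plan: tuple[tuple[str, int], ...]
    # chrom -> ordered list of (start, end, scaffold_name); strand always '+'
    segments: dict[str, list[tuple[int, int, str]]]

    @property
    def liftover(self) -> dict[str, tuple[str, int, int, str]]:
        out = {}
        for chrom, segs in self.segments.items():
            for start, end, name in segs:
                out[name] = (chrom, start, end, "+")
        return out

    def to_assembly(self, chrom: str, pos: int) -> tuple[str, int]:
        for start, end, name in self.segments[chrom]:
            if start <= pos < end:
                return name, pos - start
        raise ValueError(f"position {chrom}:{pos} outside chromosome")

    def to_genome(self, scaffold: str, pos: int) -> tuple[str, int]:
        chrom, start, end, _ = self.liftover[scaffold]
        if not (0 <= pos < end - start):
            raise ValueError(f"position {pos} outside scaffold {scaffold}")
        return chrom, start + pos

    def lift_positions(self, chrom_idx: np.ndarray, pos: np.ndarray,
                       chrom_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized truth -> assembly lift; returns (scaffold order codes, positions).

        Scaffold codes index ``self.scaffold_names()``.
        """
        scaf_names = self.scaffold_names()
        scaf_code = {n: i for i, n in enumerate(scaf_names)}
        out_code = np.empty(len(pos), dtype=np.int64)
        out_pos = np.empty(len(pos), dtype=np.int64)
        for ci, chrom in enumerate(chrom_names):
            mask = chrom_idx == ci
            if not mask.any():
                continue
            segs = self.segments[chrom]
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            codes = np.array([scaf_code[n] for _, _, n in segs], dtype=np.int64)
            idx = np.searchsorted(starts, pos[mask], side="right") - 1
            out_code[mask] = codes[idx]
            out_pos[mask] = pos[mask] - starts[idx]
        return out_code, out_pos

    def scaffold_names(self) -> list[str]:
        names = []
        for segs in self.segments.values():
            names.extend(n for _, _, n in segs)
        return names


def derive_assembly(
    genome: Genome,
    split_plan: Sequence[tuple[str, int]],
    assembly_id: str = "asm",
) -> tuple[ScaffoldSet, AssemblyDerivation]:
    """Split chromosomes at the given positions, yielding K + |splits| scaffolds.

    Two splits on the same chromosome must be at least two junction windows
    apart so that their junction neighborhoods do not overlap.
    """
    cfg = genome.config
    min_sep = 2 * cfg.junction_halfwidth
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in split_plan:
        pos = BIN * int(round(pos / BIN))
        L = genome.chrom_length(chrom)
        if not (0 < pos < L):
            raise ValueError(f"split at {chrom}:{pos} not strictly inside the chromosome")
        by_chrom.setdefault(chrom, []).append(pos)
    segments: dict[str, list[tuple[int, int, str]]] = {}
    entries: list[tuple[str, int]] = []
    counter = 0
    for chrom in genome.chromosomes.names:
        cuts = sorted(by_chrom.get(chrom, []))
        for a, b in zip(cuts, cuts[1:]):
            if b - a < min_sep:
                raise ValueError(
                    f"splits at {chrom}:{a} and {chrom}:{b} closer than {min_sep} bp"
                )
        bounds = [0] + cuts + [genome.chrom_length(chrom)]
        segs = []
        for start, end in zip(bounds, bounds[1:]):
            counter += 1
            name = f"{assembly_id}_s{counter}"
            segs.append((start, end, name))
            entries.append((name, end - start))
        segments[chrom] = segs
    deriv = AssemblyDerivation(
        assembly_id,
        tuple((c, p) for c, ps in sorted(by_chrom.items()) for p in sorted(ps)),
        segments,
    )
    return ScaffoldSet(assembly_id, entries), deriv


def make_alignment_paf(deriv_a: AssemblyDerivation, deriv_b: AssemblyDerivation,
                       genome: Genome) -> list[PafBlock]:
    """Exact whole-genome alignment of two derivations of the same genome.

    Emits one PAF block per overlap between an A-scaffold segment and a
    B-scaffold segment on the true genome (all strands '+', MAPQ 60).
    """
    blocks = []
    lift_a, lift_b = deriv_a.liftover, deriv_b.liftover
    len_a = {n: e - s for n, (_, s, e, _) in lift_a.items()}
    len_b = {n: e - s for n, (_, s, e, _) in lift_b.items()}
    for chrom in genome.chromosomes.names:
        for sa, ea, qname in deriv_a.segments[chrom]:
            for sb, eb, tname in deriv_b.segments[chrom]:
                lo, hi = max(sa, sb), min(ea, eb)
                if hi <= lo:
                    continue
                n = hi - lo
                blocks.append(PafBlock(
                    qname, len_a[qname], lo - sa, hi - sa, "+",
                    tname, len_b[tname], lo - sb, hi - sb, n, n, 60,
                ))
    return blocks


# ---------------------------------------------------------------------------
# Hi-C pairs


@dataclass
class TruePairs:
    """Emitted Hi-C pairs in true-genome coordinates."""

    chrom1: np.ndarray  # chromosome indices
    pos1: np.ndarray
    chrom2: np.ndarray
    pos2: np.ndarray
    is_trans: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.pos1)

    def trans_fraction(self) -> float:
        return float(self.is_trans.mean())


_MAX_ROUNDS = 100


def simulate_true_pairs(genome: Genome, config: Optional[SimulationConfig] = None,
                        rng: Optional[np.random.Generator] = None) -> TruePairs:
    """Sample ``n_pairs`` emitted pairs in true coordinates (see module docstring)."""
    cfg = config or genome.config
    if rng is None:
        rng = _rng(cfg.seed, _TAG_PAIRS)
    names = genome.chromosomes.names
    L = genome.chromosomes.lengths.astype(np.float64)
    pL = L / L.sum()
    dens = [genome.density[c] for c in names]
    alpha, beta, s_min = cfg.alpha, cfg.beta, float(cfg.s_min)

    def sample_cis(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """k valid cis pairs; off-chromosome second ends are resampled."""
        c = np.empty(k, dtype=np.int64)
        a = np.empty(k, dtype=np.int64)
        b = np.empty(k, dtype=np.int64)
        need = np.arange(k)
        for _ in range(_MAX_ROUNDS):
            if not len(need):
                return c, a, b
            m = len(need)
            ci = rng.choice(len(L), size=m, p=pL)
            pi = np.floor(rng.random(m) * L[ci]).astype(np.int64)
            u = rng.random(m)
            Lc = L[ci]
            if abs(alpha - 1.0) < 1e-12:
                s = s_min * (Lc / s_min) ** u
            else:
                e = 1.0 - alpha
                s = (s_min ** e + u * (Lc ** e - s_min ** e)) ** (1.0 / e)
            sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
            q = pi + np.floor(sign * s).astype(np.int64)
            good = (q >= 0) & (q < Lc.astype(np.int64))
            idx = need[good]
            c[idx], a[idx], b[idx] = ci[good], pi[good], q[good]
            need = need[~good]
        raise RuntimeError("cis sampling exceeded the resample cap")

    def sample_trans(k: int) -> tuple[np.ndarray, ...]:
        """k valid trans pairs; same-chromosome draws are resampled."""
        c1 = np.empty(k, dtype=np.int64)
        p1 = np.empty(k, dtype=np.int64)
        c2 = np.empty(k, dtype=np.int64)
        p2 = np.empty(k, dtype=np.int64)
        need = np.arange(k)
        for _ in range(_MAX_ROUNDS):
            if not len(need):
                return c1, p1, c2, p2
            m = len(need)
            ca = rng.choice(len(L), size=m, p=pL)
            cb = rng.choice(len(L), size=m, p=pL)
            good = ca != cb
            idx = need[good]
            c1[idx], c2[idx] = ca[good], cb[good]
            p1[idx] = np.floor(rng.random(m)[good] * L[ca[good]]).astype(np.int64)
            p2[idx] = np.floor(rng.random(m)[good] * L[cb[good]]).astype(np.int64)
            need = need[~good]
        raise RuntimeError("trans sampling exceeded the resample cap")

    got: list[tuple[np.ndarray, ...]] = []
    n_got = 0
    for _ in range(_MAX_ROUNDS):
        if n_got >= cfg.n_pairs:
            break
        m = max(10_000, int(1.5 * (cfg.n_pairs - n_got)))
        is_trans = rng.random(m) < beta
        c1 = np.empty(m, dtype=np.int64)
        p1 = np.empty(m, dtype=np.int64)
        c2 = np.empty(m, dtype=np.int64)
        p2 = np.empty(m, dtype=np.int64)
        ok = np.ones(m, dtype=bool)

        cis = ~is_trans
        if cis.any():
            cc, pa, pb = sample_cis(int(cis.sum()))
            c1[cis], p1[cis], c2[cis], p2[cis] = cc, pa, cc, pb
        if is_trans.any():
            ta, tp1, tb, tp2 = sample_trans(int(is_trans.sum()))
            c1[is_trans], p1[is_trans] = ta, tp1
            c2[is_trans], p2[is_trans] = tb, tp2

        # mappability loss, per end; a lost end discards the whole pair
        if cfg.gamma > 0:
            d1 = np.empty(m)
            d2 = np.empty(m)
            for ci in range(len(L)):
                mask1 = c1 == ci
                if mask1.any():
                    d1[mask1] = dens[ci][np.minimum(p1[mask1] // BIN, len(dens[ci]) - 1)]
                mask2 = c2 == ci
                if mask2.any():
                    d2[mask2] = dens[ci][np.minimum(p2[mask2] // BIN, len(dens[ci]) - 1)]
            ok &= rng.random(m) >= cfg.gamma * d1
            ok &= rng.random(m) >= cfg.gamma * d2

        got.append((c1[ok], p1[ok], c2[ok], p2[ok], is_trans[ok]))
        n_got += int(ok.sum())
    else:
        raise RuntimeError(
            "pair sampling did not converge; mappability loss too severe "
            "(is gamma * density ~ 1 genome-wide?)"
        )

    cat = [np.concatenate([g[i] for g in got])[: cfg.n_pairs] for i in range(5)]
    return TruePairs(*cat)


def lift_pairs(true_pairs: TruePairs, derivation: AssemblyDerivation,
               genome: Genome, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Lift true pairs to assembly coordinates as a canonical pairs frame."""
    cfg = genome.config
    if rng is None:
        rng = _rng(cfg.seed, _TAG_PAIRS + 10)
    names = genome.chromosomes.names
    code1, q1 = derivation.lift_positions(true_pairs.chrom1, true_pairs.pos1, names)
    code2, q2 = derivation.lift_positions(true_pairs.chrom2, true_pairs.pos2, names)
    # canonical upper-triangle order: (scaffold order, position)
    swap = (code1 > code2) | ((code1 == code2) & (q1 > q2))
    a_code = np.where(swap, code2, code1)
    a_pos = np.where(swap, q2, q1)
    b_code = np.where(swap, code1, code2)
    b_pos = np.where(swap, q1, q2)
    scaf_names = np.array(derivation.scaffold_names(), dtype=object)
    n = len(a_pos)
    strands = np.array(["+", "-"], dtype=object)
    return pd.DataFrame({
        "read_id": [f"sim{i}" for i in range(n)],
        "scaffold1": scaf_names[a_code],
        "pos1": a_pos,
        "scaffold2": scaf_names[b_code],
        "pos2": b_pos,
        "strand1": strands[rng.integers(0, 2, size=n)],
        "strand2": strands[rng.integers(0, 2, size=n)],
        "pair_type": "UU",
    })


def simulate_hic_pairs(genome: Genome, derivation: AssemblyDerivation,
                       config: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Sample pairs and lift them to the derived assembly (canonical pairs frame)."""
    cfg = config or genome.config
    return lift_pairs(simulate_true_pairs(genome, cfg), derivation, genome)


# ---------------------------------------------------------------------------
# depth


def _true_depth_1kb(genome: Genome, cfg: SimulationConfig) -> dict[str, np.ndarray]:
    rng = _rng(cfg.seed, _TAG_DEPTH)
    z = cfg.z_chrom or genome.chromosomes.names[-1]
    out = {}
    for chrom in genome.chromosomes.names:
        lam = cfg.depth_lambda * (1.0 - cfg.gamma * genome.density[chrom])
        if cfg.sex == "Z0" and chrom == z:
            lam = lam * 0.5
        out[chrom] = rng.poisson(np.maximum(lam, 0.0)).astype(float)
    return out


def simulate_depth(genome: Genome, derivation: AssemblyDerivation,
                   config: Optional[SimulationConfig] = None,
                   coarse_window: int = 500_000) -> tuple[DepthWindowTable, DepthWindowTable]:
    """Poisson depth per 1 kb bin, lifted to assembly coordinates.

    Returns the 1 kb table and a coarse table (default 500 kb) whose window
    depth is the mean of its constituent 1 kb bins. The underlying
    true-genome draw depends only on the config seed, so the two assemblies
    derived from one genome see consistent depth.
    """
    cfg = config or genome.config
    truth = _true_depth_1kb(genome, cfg)
    rows_fine, rows_coarse = [], []
    per_coarse = coarse_window // BIN
    for chrom in genome.chromosomes.names:
        for start, end, name in derivation.segments[chrom]:
            d = truth[chrom][start // BIN: end // BIN]
            n = len(d)
            starts = np.arange(n, dtype=np.int64) * BIN
            rows_fine.append(pd.DataFrame({
                "scaffold": name, "start": starts,
                "end": np.minimum(starts + BIN, end - start), "depth": d,
            }))
            n_coarse = -(-n // per_coarse)
            cs = np.arange(n_coarse, dtype=np.int64) * coarse_window
            means = [float(d[i * per_coarse:(i + 1) * per_coarse].mean()) for i in range(n_coarse)]
            rows_coarse.append(pd.DataFrame({
                "scaffold": name, "start": cs,
                "end": np.minimum(cs + coarse_window, end - start), "depth": means,
            }))
    fine = DepthWindowTable(pd.concat(rows_fine, ignore_index=True), BIN)
    coarse = DepthWindowTable(pd.concat(rows_coarse, ignore_index=True), coarse_window)
    return fine, coarse


# ---------------------------------------------------------------------------
# repeat annotation liftover


def lift_annotation(repeats: RepeatAnnotation, derivation: AssemblyDerivation) -> RepeatAnnotation:
    """Lift a true-coordinate repeat annotation onto derived scaffolds."""
    parts = []
    for chrom, segs in derivation.segments.items():
        sub = repeats.table[repeats.table["scaffold"] == chrom]
        if not len(sub):
            continue
        for start, end, name in segs:
            clip = sub[(sub["end"] > start) & (sub["start"] < end)].copy()
            if not len(clip):
                continue
            clip["start"] = clip["start"].clip(lower=start) - start
            clip["end"] = clip["end"].clip(upper=end) - start
            clip["scaffold"] = name
            parts.append(clip)
    if not parts:
        return RepeatAnnotation()
    return RepeatAnnotation(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(sex: str, seed: int, noise_sd: float = 0.1, n_replicates: int = 4,
                  base_cq: float = 20.0, delta_magnitude: float = 1.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Cq replicates for the autosomal (A) and sex-locus (S) assays.

    Follows the qPCR sex-genotyping sign convention: expected ΔCq = A_Cq − S_Cq is
    +``delta_magnitude`` cycles for males (ZZ) and −``delta_magnitude``
    for females (Z0). Note this is the *reverse* of the naive copy-number
    expectation (a ZZ male has the autosomal copy number at the sex locus);
    the convention is taken as stated and surfaced as-is.
    """
    sex_norm = {"male": "male", "zz": "male", "female": "female", "z0": "female"}.get(sex.lower())
    if sex_norm is None:
        raise ValueError(f"sex must be male/ZZ or female/Z0, got {sex!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, _TAG_QPCR)
    delta = delta_magnitude if sex_norm == "male" else -delta_magnitude
    a = base_cq + rng.normal(0.0, noise_sd, n_replicates) if noise_sd else np.full(n_replicates, base_cq)
    s_mean = base_cq - delta
    s = s_mean + rng.normal(0.0, noise_sd, n_replicates) if noise_sd else np.full(n_replicates, s_mean)
    return a, s


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class Study:
    """Everything the adjudication pipeline consumes, for one simulated study."""

    config: SimulationConfig
    genome: Genome
    set_a: ScaffoldSet
    set_b: ScaffoldSet
    deriv_a: AssemblyDerivation
    deriv_b: AssemblyDerivation
    true_pairs: TruePairs
    pairs_a: pd.DataFrame
    pairs_b: pd.DataFrame
    depth1kb: dict[str, DepthWindowTable]
    depth500: dict[str, DepthWindowTable]
    repeats: dict[str, RepeatAnnotation]
    paf: list[PafBlock]  # A queries vs B targets


def simulate_study(
    config: SimulationConfig,
    splits_a: Sequence[tuple[str, int]],
    splits_b: Sequence[tuple[str, int]],
    assembly_ids: tuple[str, str] = ("A", "B"),
) -> Study:
    """Simulate one genome and two derived assemblies with their full data.

    If ``config.planned_splits`` is empty, the union of the two split plans
    becomes the planned (repeat-rich) junction set, so both assemblies'
    junctions sit in elevated repeat landscape.
    """
    if not config.planned_splits:
        union = tuple(dict.fromkeys([*(tuple(s) for s in splits_a),
                                     *(tuple(s) for s in splits_b)]))
        config = replace(config, planned_splits=union)
    genome = simulate_genome(config)
    set_a, deriv_a = derive_assembly(genome, [(c, p) for c, p, *_ in splits_a], assembly_ids[0])
    set_b, deriv_b = derive_assembly(genome, [(c, p) for c, p, *_ in splits_b], assembly_ids[1])
    tp = simulate_true_pairs(genome, config)
    pairs_a = lift_pairs(tp, deriv_a, genome)
    pairs_b = lift_pairs(tp, deriv_b, genome)
    fine_a, coarse_a = simulate_depth(genome, deriv_a, config)
    fine_b, coarse_b = simulate_depth(genome, deriv_b, config)
    ida, idb = assembly_ids
    return Study(
        config, genome, set_a, set_b, deriv_a, deriv_b, tp, pairs_a, pairs_b,
        depth1kb={ida: fine_a, idb: fine_b},
        depth500={ida: coarse_a, idb: coarse_b},
        repeats={ida: lift_annotation(genome.repeats, deriv_a),
                 idb: lift_annotation(genome.repeats, deriv_b)},
        paf=make_alignment_paf(deriv_a, deriv_b, genome),
    )


def discordance_study(seed: int = 0, scale: str = "desk", **overrides) -> Study:
    """The canonical discordant-assemblies scenario: one split in A, three in B.

    One of B's junctions is an extreme (~99.9% masked) repeat island and the
    mappability-loss coefficient is 0.8, so that junction loses most of its
    Hi-C signal and roughly five-fold of its read depth - the configuration
    that exercises the coverage/repeat rescue during adjudication. ``scale``
    is "desk" (K=8) or "karyotype" (K=46 -> 47 vs 49 scaffolds).
    """
    make = desk_scale_config if scale == "desk" else karyotype_scale_config
    cfg = make(seed, gamma=0.8, **overrides)
    names = cfg.chrom_names()
    L = dict(zip(names, cfg.chrom_lengths))

    def mid(c):
        return BIN * (L[c] // (2 * BIN))

    splits_a = [(names[0], mid(names[0]))]
    splits_b = [(names[1], mid(names[1])), (names[2], mid(names[2])),
                (names[3], mid(names[3]), 0.999)]
    return simulate_study(cfg, splits_a, splits_b)


def write_study(study: Study, outdir: str | Path) -> None:
    """Write every simulated artifact as text files plus a provenance JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ida, idb = study.set_a.assembly_id, study.set_b.assembly_id
    for sid, sset, pairs in ((ida, study.set_a, study.pairs_a),
                             (idb, study.set_b, study.pairs_b)):
        write_fai(sset, out / f"{sid}.fai")
        write_pairs(pairs, out / f"{sid}.pairs", sset)
        write_repeat_bed(study.repeats[sid], out / f"{sid}.repeats.bed")
        write_depth_bed(study.depth1kb[sid], out / f"{sid}.depth.1kb.bed")
        write_depth_bed(study.depth500[sid], out / f"{sid}.depth.500kb.bed")
    write_paf(study.paf, out / f"{ida}_vs_{idb}.paf")
    cfg = dataclasses.asdict(study.config)
    cfg["planned_splits"] = [list(s) for s in cfg["planned_splits"]]
    with open(out / "provenance.json", "w") as fh:
        json.dump({"config": cfg,
                   "splits_a": [list(s) for s in study.deriv_a.split_plan],
                   "splits_b": [list(s) for s in study.deriv_b.split_plan]},
                  fh, indent=2, default=str)
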