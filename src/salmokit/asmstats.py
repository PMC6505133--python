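"""Assembly summary statistics (Nx/Lx, GC, known-base fraction) and
stage-over-stage percent changes.

The Nx statistic uses the inclusive convention: N50 is the length of the
shortest sequence in the smallest set of longest sequences whose summed
length reaches at least 50% of the assembly total; L50 is the size of that
set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class AssemblyStats:
    """Length statistics of one assembly stage."""

    n_sequences: int
    total: int
    mean: float
    sd: float
    min: int
    max: int
    n50: int
    l50: int
    n90: int
    l90: int
    gc_percent: float | None = None
    known_fraction: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _nx_lx(sorted_desc: np.ndarray, total: int, x: float) -> tuple[int, int]:
    cum = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(cum, x / 100.0 * total))
    return int(sorted_desc[idx]), idx + 1


def contig_stats(lengths: Iterable[int]) -> AssemblyStats:
    """Compute N50/L50/N90/L90 and length summaries from sequence lengths.

    Parameters
    ----------
    lengths : iterable of positive int
        One entry per scaffold/contig.

    Raises
    ------
    ValueError
        On empty input or non-positive lengths.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("contig_stats requires at least one sequence length")
    if np.any(arr <= 0):
        raise ValueError("sequence lengths must be positive")
    desc = np.sort(arr)[::-1]
    total = int(arr.sum())
    n50, l50 = _nx_lx(desc, total, 50)
    n90, l90 = _nx_lx(desc, total, 90)
    return AssemblyStats(
        n_sequences=int(arr.size),
        total=total,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        min=int(arr.min()),
        max=int(arr.max()),
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
    )


_GC = frozenset("GCgcSs")
_KNOWN = frozenset("ACGTacgt")


def gc_and_known(sequences: Iterable[str]) -> tuple[float, float]:
    """GC percent over known (non-N) bases and the known-base fraction.

    Returns ``(gc_percent, known_fraction)``. Raises ValueError when the
    total sequence length is zero; GC over zero known bases is nan.
    """
    total = known = gc = 0
    for seq in sequences:
        total += len(seq)
        for base in seq:
            if base in _KNOWN:
                known += 1
                if base in _GC:
                    gc += 1
    if total == 0:
        raise ValueError("gc_and_known: no sequence data")
    gc_percent = 100.0 * gc / known if known else float("nan")
    return gc_percent, known / total


def percent_change(before: float, after: float) -> int:
    """Signed percent change, rounded half-away-from-zero to an integer.

    Raises ValueError when ``before`` is zero (change undefined).
    """
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    pct = 100.0 * (after - before) / before
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def stage_comparison(before: AssemblyStats, after: AssemblyStats) -> dict[str, int]:
    """Percent changes of the headline statistics between two stages."""
    out = {}
    for key in ("n50", "l50", "n90", "l90", "n_sequences", "total", "mean", "min", "max"):
        b, a = getattr(before, key), getattr(after, key)
        out[key] = percent_change(b, a)
    return out


def stats_from_fasta(path) -> AssemblyStats:
    """Full statistics (lengths, GC, known fraction) from a FASTA file."""
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    stats = contig_stats([len(s) for s in seqs])
    stats.gc_percent, stats.known_fraction = gc_and_known(seqs)
    return stats
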