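"""Duplicated-karyotype simulator.

An ancestral teleost-like genome of acrocentric chromosomes is duplicated
(copies A and B of each ancestral chromosome, emulating a whole-genome
duplication) and two lineages then diverge:

* the grayling-like lineage receives the configured inversions and
  fissions and no fusions (its chromosome number stays near the doubled
  ancestral count);
* the salmon-like lineage receives the configured fusions (chromosome
  number shrinks, as after repeated Robertsonian fusions).

Chromosomes are represented as ordered segment lists over ancestral
coordinates rather than literal sequence; ``render_fasta`` materialises
sequence for I/O tests. Every rearrangement is logged so downstream stages
can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class Segment:
    """Half-open ancestral interval [start, end) on one duplicated copy."""

    anc_chrom: int  # ancestral chromosome index (0-based)
    copy: str  # "A" or "B"
    start: int
    end: int
    strand: int = 1  # +1 / -1

    def __len__(self) -> int:
        return self.end - self.start

    def reversed(self) -> "Segment":
        return replace(self, strand=-self.strand)


@dataclass
class DerivedChromosome:
    name: str
    segments: list[Segment]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.segments)

    def locate_ancestral(self, anc_chrom: int, copy: str, pos: int) -> int | None:
        """Chromosome coordinate (0-based) of an ancestral position, or None."""
        offset = 0
        for seg in self.segments:
            if seg.anc_chrom == anc_chrom and seg.copy == copy and seg.start <= pos < seg.end:
                if seg.strand == 1:
                    return offset + (pos - seg.start)
                return offset + (seg.end - 1 - pos)
            offset += len(seg)
        return None

    def ancestral_at(self, pos: int) -> tuple[int, str, int]:
        """Ancestral (chrom, copy, position) underlying chromosome coordinate."""
        offset = 0
        for seg in self.segments:
            if offset <= pos < offset + len(seg):
                d = pos - offset
                anc = seg.start + d if seg.strand == 1 else seg.end - 1 - d
                return seg.anc_chrom, seg.copy, anc
            offset += len(seg)
        raise IndexError(pos)


Genome = dict[str, DerivedChromosome]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_ancestral_chromosomes: int = 2
    chromosome_length_bp: int = 20_000_000
    n_offspring: int = 113
    markers_per_chromosome: int = 150
    #: events applied to the grayling-like lineage: (chrom_name, start, end, spans_centromere)
    inversion_events: list[tuple] = field(default_factory=list)
    #: events applied to the grayling-like lineage: (chrom_name, breakpoint)
    fission_events: list[tuple] = field(default_factory=list)
    #: events applied to the salmon-like lineage: (chrom_name_1, chrom_name_2)
    fusion_events: list[tuple] = field(default_factory=list)
    te_peak_width_bp: int = 1_000_000
    hit_noise_rate: float = 0.0
    #: centromere position as a fraction of the ancestral chromosome length
    #: (0.1 = acrocentric ancestor)
    centromere_fraction: float = 0.1

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG so every generator draws from one master seed."""
        import zlib

        key = zlib.crc32(name.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class Rearrangement:
    kind: str  # inversion | fission | fusion
    lineage: str  # grayling | salmon
    chromosome: str
    start: int | None = None
    end: int | None = None
    spans_centromere: bool | None = None
    products: tuple[str, ...] = ()


@dataclass
class TruthSet:
    rearrangements: list[Rearrangement] = field(default_factory=list)
    centromeres: dict[str, dict[str, int | None]] = field(default_factory=dict)
    marker_orders: dict[str, list] = field(default_factory=dict)
    te_abundance: dict | None = None


def _validate_events(config: SimulationConfig, chrom_lengths: dict[str, int]) -> None:
    by_chrom: dict[str, list[tuple[int, int, tuple]]] = {}
    for ev in config.inversion_events:
        chrom, start, end = ev[0], int(ev[1]), int(ev[2])
        if chrom not in chrom_lengths:
            raise ValueError(f"inversion on unknown chromosome {chrom!r}")
        if not (0 <= start < end <= chrom_lengths[chrom]):
            raise ValueError(f"inversion {ev} outside chromosome bounds")
        by_chrom.setdefault(chrom, []).append((start, end, ev))
    for ev in config.fission_events:
        chrom, bp = ev[0], int(ev[1])
        if chrom not in chrom_lengths:
            raise ValueError(f"fission on unknown chromosome {chrom!r}")
        if not (0 < bp < chrom_lengths[chrom]):
            raise ValueError(f"fission {ev} outside chromosome bounds")
        by_chrom.setdefault(chrom, []).append((bp, bp, ev))
    for events in by_chrom.values():
        events.sort()
        for (s1, e1, ev1), (s2, e2, ev2) in zip(events[:-1], events[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping events: {ev1} and {ev2}")


def _apply_inversion(chrom: DerivedChromosome, start: int, end: int) -> None:
    """Reverse the [start, end) interval of a derived chromosome in place."""
    new_segments: list[Segment] = []
    mid: list[Segment] = []
    offset = 0
    tail: list[Segment] = []
    for seg in chrom.segments:
        s0, s1 = offset, offset + len(seg)
        offset = s1
        cut_lo = max(start, s0)
        cut_hi = min(end, s1)
        if cut_hi <= cut_lo:  # no overlap with the inverted interval
            (new_segments if s1 <= start else tail).append(seg)
            continue
        # split seg into before / inside / after relative to [start, end)
        def sub(a: int, b: int) -> Segment:
            if seg.strand == 1:
                return replace(seg, start=seg.start + (a - s0), end=seg.start + (b - s0))
            return replace(seg, start=seg.end - (b - s0), end=seg.end - (a - s0))
        if cut_lo > s0:
            new_segments.append(sub(s0, cut_lo))
        mid.append(sub(cut_lo, cut_hi))
        if cut_hi < s1:
            tail.append(sub(cut_hi, s1))
    chrom.segments = new_segments + [s.reversed() for s in reversed(mid)] + tail


def _split(chrom: DerivedChromosome, breakpoint: int) -> tuple[list[Segment], list[Segment]]:
    left: list[Segment] = []
    right: list[Segment] = []
    offset = 0
    for seg in chrom.segments:
        s0, s1 = offset, offset + len(seg)
        offset = s1
        if s1 <= breakpoint:
            left.append(seg)
        elif s0 >= breakpoint:
            right.append(seg)
        else:
            d = breakpoint - s0
            if seg.strand == 1:
                left.append(replace(seg, end=seg.start + d))
                right.append(replace(seg, start=seg.start + d))
            else:
                left.append(replace(seg, start=seg.end - d))
                right.append(replace(seg, end=seg.end - d))
    return left, right


@dataclass
class KaryotypeSim:
    config: SimulationConfig
    ancestral_length: int
    ancestral_centromere: int
    grayling: Genome
    salmon: Genome
    truth: TruthSet

    def centromere_of(self, lineage: str, chrom_name: str) -> int | None:
        return self.truth.centromeres[lineage].get(chrom_name)


def simulate_karyotype(config: SimulationConfig) -> KaryotypeSim:
    """Duplicate an ancestral genome and apply per-lineage rearrangements.

    Returns the two derived genomes (segment lists over ancestral
    coordinates) plus the rearrangement log and per-chromosome derived
    centromere positions. Overlapping events on one chromosome are rejected
    with the offending pair reported.
    """
    L = config.chromosome_length_bp
    cen_anc = int(config.centromere_fraction * L)
    if not 0 < cen_anc < L:
        raise ValueError("centromere_fraction must place the centromere inside the chromosome")

    def duplicated() -> Genome:
        genome: Genome = {}
        for i in range(config.n_ancestral_chromosomes):
            for copy in ("A", "B"):
                name = f"{i + 1}{copy}"
                genome[name] = DerivedChromosome(name, [Segment(i, copy, 0, L)])
        return genome

    grayling = duplicated()
    salmon = duplicated()
    chrom_lengths = {name: c.length for name, c in grayling.items()}
    _validate_events(config, chrom_lengths)

    truth = TruthSet()

    def centromere(chrom: DerivedChromosome) -> int | None:
        hits = []
        for i in range(config.n_ancestral_chromosomes):
            for copy in ("A", "B"):
                pos = chrom.locate_ancestral(i, copy, cen_anc)
                if pos is not None:
                    hits.append(pos)
        if len(hits) == 1:
            return hits[0]
        return None  # zero (fission arm without centromere) or fused multi

    # grayling-like lineage: inversions then fissions
    for ev in config.inversion_events:
        chrom_name, start, end = ev[0], int(ev[1]), int(ev[2])
        declared_spans = None if len(ev) <= 3 or ev[3] is None else bool(ev[3])
        chrom = grayling[chrom_name]
        cen = centromere(chrom)
        spans = cen is not None and start <= cen < end
        if declared_spans is not None and spans != declared_spans:
            raise ValueError(
                f"inversion {ev}: spans_centromere={declared_spans} but the "
                f"centromere of {chrom_name} is at {cen}")
        _apply_inversion(chrom, start, end)
        truth.rearrangements.append(Rearrangement(
            "inversion", "grayling", chrom_name, start, end, spans))
    for ev in config.fission_events:
        chrom_name, bp = ev[0], int(ev[1])
        chrom = grayling.pop(chrom_name)
        left, right = _split(chrom, bp)
        n1, n2 = f"{chrom_name}.1", f"{chrom_name}.2"
        grayling[n1] = DerivedChromosome(n1, left)
        grayling[n2] = DerivedChromosome(n2, right)
        truth.rearrangements.append(Rearrangement(
            "fission", "grayling", chrom_name, bp, products=(n1, n2)))

    # salmon-like lineage: fusions only
    for ev in config.fusion_events:
        a, b = ev[0], ev[1]
        ca, cb = salmon.pop(a), salmon.pop(b)
        name = f"{a}+{b}"
        salmon[name] = DerivedChromosome(name, ca.segments + cb.segments)
        truth.rearrangements.append(Rearrangement(
            "fusion", "salmon", name, products=(a, b)))

    truth.centromeres = {
        "grayling": {n: centromere(c) for n, c in grayling.items()},
        "salmon": {n: centromere(c) for n, c in salmon.items()},
    }
    return KaryotypeSim(config, L, cen_anc, grayling, salmon, truth)


def total_length(genome: Genome) -> int:
    return sum(c.length for c in genome.values())


def render_fasta(genome: Genome, config: SimulationConfig) -> dict[str, str]:
    """Materialise literal sequence for a genome (deterministic per seed).

    Each ancestral (chromosome, copy) gets an i.i.d. random sequence shared
    by both lineages; derived chromosomes read it through their segment
    lists, reverse-complementing minus-strand segments.
    """
    rng = config.substream("sequence")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    anc: dict[tuple[int, str], np.ndarray] = {}
    for i in range(config.n_ancestral_chromosomes):
        base = rng.integers(0, 4, size=config.chromosome_length_bp)
        anc[(i, "A")] = base
        anc[(i, "B")] = base.copy()  # homeologs start identical
    comp = np.array([3, 2, 1, 0])
    out: dict[str, str] = {}
    for name, chrom in genome.items():
        parts = []
        for seg in chrom.segments:
            codes = anc[(seg.anc_chrom, seg.copy)][seg.start:seg.end]
            if seg.strand == -1:
                codes = comp[codes[::-1]]
            parts.append(codes)
        seq = bases[np.concatenate(parts)] if parts else np.array([], dtype="S1")
        out[name] = seq.tobytes().decode()
    return out
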