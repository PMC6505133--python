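"""Alignment-hit simulator.

Emulates whole-genome aligner tabular output between two derived genomes
that share ancestral coordinates. Each conserved ancestral segment common
to a chromosome pair produces a run of local hits (chopped to a typical hit
length, small gaps in between) whose strand reflects the inversion state;
a configurable fraction of spurious hits (too short or too diverged to pass
the identity >= 80 / match >= 100 filter, plus sub-block passing fragments)
exercises the filtering and chaining stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .karyotype import DerivedChromosome, Genome


def _segment_spans(chrom: DerivedChromosome):
    """Yield (anc_chrom, copy, anc_start, anc_end, strand, chrom_offset)."""
    offset = 0
    for seg in chrom.segments:
        yield seg.anc_chrom, seg.copy, seg.start, seg.end, seg.strand, offset
        offset += len(seg)


def simulate_alignment_hits(
    genome_qry: Genome,
    genome_ref: Genome,
    rng: np.random.Generator,
    noise_rate: float = 0.0,
    hit_len: int = 200_000,
    hit_gap: int = 1_000,
    identity_mean: float = 94.0,
    identity_sd: float = 2.0,
    same_copy_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hit table between two genomes sharing ancestral coordinates.

    With ``same_copy_only`` (default) only orthologous copies align
    (homeolog cross-hits are suppressed, as after repeat-masked alignment of
    diverged duplicates). ``noise_rate`` adds that fraction (of the true hit
    count) of spurious hits. Returns ``(hits, truth)`` where ``truth`` marks
    each row ``is_noise`` and names the source segment of true hits.
    1-based inclusive coordinates; minus-strand state is explicit in the
    ``strand`` column.
    """
    rows, truth_rows = [], []
    for qname, qchrom in genome_qry.items():
        for q_anc, q_copy, q_s, q_e, q_strand, q_off in _segment_spans(qchrom):
            for rname, rchrom in genome_ref.items():
                for r_anc, r_copy, r_s, r_e, r_strand, r_off in _segment_spans(rchrom):
                    if q_anc != r_anc:
                        continue
                    if same_copy_only and q_copy != r_copy:
                        continue
                    lo, hi = max(q_s, r_s), min(q_e, r_e)
                    if hi <= lo:
                        continue
                    strand = "+" if q_strand == r_strand else "-"
                    # chop the conserved interval into hit-sized pieces
                    for a in range(lo, hi, hit_len + hit_gap):
                        b = min(a + hit_len, hi)
                        if b - a < 2:
                            continue
                        q1 = _map_to_chrom(a, q_s, q_e, q_strand, q_off)
                        q2 = _map_to_chrom(b - 1, q_s, q_e, q_strand, q_off)
                        r1 = _map_to_chrom(a, r_s, r_e, r_strand, r_off)
                        r2 = _map_to_chrom(b - 1, r_s, r_e, r_strand, r_off)
                        qs, qe = sorted((q1, q2))
                        rs, re_ = sorted((r1, r2))
                        ident = float(np.clip(rng.normal(identity_mean, identity_sd),
                                              80.0, 100.0))
                        rows.append({
                            "qry_name": qname, "qry_start": qs + 1, "qry_end": qe + 1,
                            "ref_name": rname, "ref_start": rs + 1, "ref_end": re_ + 1,
                            "strand": strand, "identity": ident,
                            "match_len": qe - qs + 1,
                        })
                        truth_rows.append({
                            "is_noise": False, "anc_chrom": q_anc, "copy": q_copy,
                            "anc_start": a, "anc_end": b,
                        })
    n_true = len(rows)
    n_noise = int(round(noise_rate * n_true))
    q_names = list(genome_qry)
    r_names = list(genome_ref)
    for _ in range(n_noise):
        qname = q_names[rng.integers(len(q_names))]
        rname = r_names[rng.integers(len(r_names))]
        kind = rng.integers(3)
        if kind == 0:  # too short to pass the match-count filter
            length = int(rng.integers(20, 100))
            ident = float(rng.uniform(80, 99))
        elif kind == 1:  # too diverged to pass the identity filter
            length = int(rng.integers(200, 5000))
            ident = float(rng.uniform(55, 79.9))
        else:  # passes the filter but far below any block-size threshold
            length = int(rng.integers(100, 500))
            ident = float(rng.uniform(80, 95))
        qs = int(rng.integers(1, max(2, genome_qry[qname].length - length)))
        rs = int(rng.integers(1, max(2, genome_ref[rname].length - length)))
        rows.append({
            "qry_name": qname, "qry_start": qs, "qry_end": qs + length - 1,
            "ref_name": rname, "ref_start": rs, "ref_end": rs + length - 1,
            "strand": "+" if rng.random() < 0.5 else "-",
            "identity": round(ident, 1), "match_len": length,
        })
        truth_rows.append({"is_noise": True, "anc_chrom": -1, "copy": "",
                           "anc_start": -1, "anc_end": -1})
    hits = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return hits, truth


def _map_to_chrom(anc_pos: int, s: int, e: int, strand: int, offset: int) -> int:
    if strand == 1:
        return offset + (anc_pos - s)
    return offset + (e - 1 - anc_pos)
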