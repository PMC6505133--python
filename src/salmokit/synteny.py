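"""Synteny-assisted chromosome building and rearrangement detection.

Scaffolds are placed on reference chromosomes by summing aligned base pairs
and hit counts, ordered by a match-length-weighted median anchor, oriented
by a weighted strand vote, and concatenated with 100 bp N gaps (AGP 2.1
records mirror the emitted FASTA exactly). Between two chromosome-level
genomes, filtered hits (identity >= 80.0, match length >= 100) are chained
into collinear strand-consistent synteny blocks; inverted blocks are
classified as pericentric or paracentric by centromere containment.

All coordinates in dataframes and emitted tables are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HIT_COLUMNS = [
    "qry_name", "qry_start", "qry_end", "ref_name", "ref_start", "ref_end",
    "strand", "identity", "match_len",
]

MIN_IDENTITY = 80.0
MIN_MATCH = 100
GAP_LEN = 100


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_alignment_hits(path, dialect: str = "coords") -> tuple[pd.DataFrame, list[str]]:
    """Read alignment hits from show-coords-like or BLAST 12-column tables.

    dialect "coords": tab-separated columns ref_start, ref_end, qry_start,
    qry_end, ref_len, qry_len, identity, ref_name, qry_name (header line
    optional). dialect "blast_tab": standard outfmt-6 columns. Coordinates
    are normalised to 1-based inclusive start <= end with strand inferred
    from the original coordinate order. Returns ``(hits, malformed)`` where
    malformed lists "line N: reason" strings.
    """
    if dialect not in ("coords", "blast_tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows, malformed = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "coords":
                    if parts[0] == "ref_start":  # header
                        continue
                    rs, re_, qs, qe = (int(parts[i]) for i in range(4))
                    identity = float(parts[6])
                    ref_name, qry_name = parts[7], parts[8]
                else:
                    qry_name, ref_name = parts[0], parts[1]
                    identity = float(parts[2])
                    qs, qe = int(parts[6]), int(parts[7])
                    rs, re_ = int(parts[8]), int(parts[9])
            except (IndexError, ValueError) as exc:
                malformed.append(f"line {lineno}: {exc}")
                continue
            strand = "+" if (qs <= qe) == (rs <= re_) else "-"
            qs, qe = min(qs, qe), max(qs, qe)
            rs, re_ = min(rs, re_), max(rs, re_)
            rows.append({
                "qry_name": qry_name, "qry_start": qs, "qry_end": qe,
                "ref_name": ref_name, "ref_start": rs, "ref_end": re_,
                "strand": strand, "identity": identity,
                "match_len": qe - qs + 1,
            })
    return pd.DataFrame(rows, columns=HIT_COLUMNS), malformed


def write_alignment_hits(hits: pd.DataFrame, path, dialect: str = "coords") -> None:
    """Write hits in the show-coords-like or BLAST tabular layout (minus
    coordinates encode a "-" strand by swapped query coordinates)."""
    if dialect not in ("coords", "blast_tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "coords":
            fh.write("ref_start\tref_end\tqry_start\tqry_end\tref_len\tqry_len\t"
                     "identity\tref_name\tqry_name\n")
        for _, h in hits.iterrows():
            qs, qe = int(h.qry_start), int(h.qry_end)
            if h.strand == "-":
                qs, qe = qe, qs
            rlen = int(h.ref_end - h.ref_start + 1)
            qlen = abs(qe - qs) + 1
            if dialect == "coords":
                fh.write(f"{int(h.ref_start)}\t{int(h.ref_end)}\t{qs}\t{qe}\t"
                         f"{rlen}\t{qlen}\t{h.identity:g}\t{h.ref_name}\t{h.qry_name}\n")
            else:
                fh.write(f"{h.qry_name}\t{h.ref_name}\t{h.identity:g}\t{qlen}\t0\t0\t"
                         f"{qs}\t{qe}\t{int(h.ref_start)}\t{int(h.ref_end)}\t0\t0\n")


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldPlacement:
    scaffold: str
    chromosome: str | None
    anchor: float | None
    orientation: str | None
    score_bp: int = 0
    score_hits: int = 0
    evidence: str = "synteny"
    ambiguous: bool = False


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])


def best_reference_position(hits: pd.DataFrame, scaffold: str | None = None) -> ScaffoldPlacement:
    """Best reference chromosome for one scaffold's hits.

    Score per candidate chromosome = (sum of match lengths, hit count);
    winner by total bp, ties by hit count, remaining exact ties flagged
    ambiguous. Anchor is the match-length-weighted median of reference hit
    midpoints; orientation is the sign of the match-length-weighted strand
    vote ("+" on a tied vote).
    """
    name = scaffold if scaffold is not None else (
        hits["qry_name"].iloc[0] if len(hits) else "?")
    if len(hits) == 0:
        return ScaffoldPlacement(name, None, None, None, evidence="none")
    agg = hits.groupby("ref_name").agg(
        bp=("match_len", "sum"), n=("match_len", "size")).reset_index()
    agg = agg.sort_values(["bp", "n", "ref_name"], ascending=[False, False, True])
    top = agg.iloc[0]
    ambiguous = len(agg) > 1 and bool(
        (agg.iloc[1]["bp"] == top["bp"]) and (agg.iloc[1]["n"] == top["n"]))
    sel = hits[hits["ref_name"] == top["ref_name"]]
    mid = (sel["ref_start"].to_numpy() + sel["ref_end"].to_numpy()) / 2.0
    w = sel["match_len"].to_numpy(dtype=float)
    anchor = _weighted_median(mid, w)
    vote = float(np.sum(np.where(sel["strand"].to_numpy() == "-", -w, w)))
    orientation = "-" if vote < 0 else "+"
    return ScaffoldPlacement(name, str(top["ref_name"]), anchor, orientation,
                             int(top["bp"]), int(top["n"]), "synteny", ambiguous)


@dataclass
class SplitDecision:
    scaffold: str
    split_at: int  # query coordinate (1-based); split between split_at and split_at+1
    left_chrom: str
    right_chrom: str
    left_bp: int
    right_bp: int


def detect_chimeric_scaffolds(
    hits_by_scaffold: dict[str, pd.DataFrame] | pd.DataFrame,
    min_bp: int = 10_000,
) -> list[SplitDecision]:
    """Flag scaffolds whose query coordinates split into two segments aligned
    to different reference chromosomes, each with >= ``min_bp`` aligned bp,
    separated by a query gap. Proposed split = midpoint of the gap."""
    if isinstance(hits_by_scaffold, pd.DataFrame):
        hits_by_scaffold = dict(tuple(hits_by_scaffold.groupby("qry_name")))
    decisions = []
    for scaffold, hits in hits_by_scaffold.items():
        by_bp = hits.groupby("ref_name")["match_len"].sum().sort_values(ascending=False)
        if len(by_bp) < 2 or by_bp.iloc[1] < min_bp or by_bp.iloc[0] < min_bp:
            continue
        c1, c2 = by_bp.index[:2]
        h1 = hits[hits["ref_name"] == c1]
        h2 = hits[hits["ref_name"] == c2]
        # require clean separation along the query
        if h1["qry_end"].max() < h2["qry_start"].min():
            left, right, lc, rc = h1, h2, c1, c2
        elif h2["qry_end"].max() < h1["qry_start"].min():
            left, right, lc, rc = h2, h1, c2, c1
        else:
            continue
        gap_lo, gap_hi = int(left["qry_end"].max()), int(right["qry_start"].min())
        decisions.append(SplitDecision(
            scaffold, (gap_lo + gap_hi) // 2, str(lc), str(rc),
            int(left["match_len"].sum()), int(right["match_len"].sum())))
    return decisions


def order_and_orient(
    placements: Iterable[ScaffoldPlacement],
    linkage_positions: pd.DataFrame | None = None,
    cm_threshold: float = 10.0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-chromosome scaffold plan: synteny anchors, overridden by linkage.

    ``linkage_positions`` columns: scaffold, chrom, cm. A scaffold whose
    linkage chromosome differs from its synteny chromosome is moved to the
    linkage chromosome (override logged). Within a chromosome, a scaffold
    whose cM position disagrees with the anchor-implied position by more
    than ``cm_threshold`` (residual of the per-chromosome cm ~ anchor fit)
    has its anchor replaced by the fit-implied one. Returns
    ``(plan, unplaced, overrides)``; the plan is sorted by (chrom, anchor)
    with columns scaffold, chrom, anchor, orientation, evidence.
    """
    link = {}
    if linkage_positions is not None and len(linkage_positions):
        link = linkage_positions.set_index("scaffold")[["chrom", "cm"]].to_dict("index")
    rows, unplaced, overrides = [], [], []
    for p in placements:
        lp = link.get(p.scaffold)
        if p.chromosome is None and lp is None:
            unplaced.append(p.scaffold)
            continue
        chrom, anchor, evidence = p.chromosome, p.anchor, p.evidence
        if lp is not None:
            evidence = "both" if p.chromosome is not None else "linkage"
            if p.chromosome is not None and lp["chrom"] != p.chromosome:
                overrides.append(
                    f"{p.scaffold}: linkage places on {lp['chrom']}, synteny on "
                    f"{p.chromosome}; linkage wins")
                chrom, anchor = lp["chrom"], None  # anchor refit below from cM
        rows.append({
            "scaffold": p.scaffold, "chrom": chrom, "anchor": anchor,
            "orientation": p.orientation or "+", "evidence": evidence,
            "cm": link.get(p.scaffold, {}).get("cm", np.nan),
        })
    plan = pd.DataFrame(rows)
    if len(plan) == 0:
        return plan, unplaced, overrides

    # reconcile cM vs anchor within each chromosome
    for chrom, grp in plan.groupby("chrom"):
        both = grp.dropna(subset=["anchor", "cm"])
        if len(both) >= 3:
            coef = np.polyfit(both["cm"], both["anchor"], 1)
            pred = np.polyval(coef, both["cm"])
            resid_cm = np.abs(both["anchor"] - pred) / max(abs(coef[0]), 1e-9)
            for idx, off in resid_cm.items():
                if off > cm_threshold:
                    plan.loc[idx, "anchor"] = np.polyval(coef, plan.loc[idx, "cm"])
                    overrides.append(
                        f"{plan.loc[idx, 'scaffold']}: synteny anchor conflicts with "
                        f"linkage position by {off:.1f} cM; linkage wins")
        # anchors missing (moved scaffolds): interpolate from cM fit or rank
        missing = grp["anchor"].isna()
        if missing.any():
            if len(both) >= 2:
                coef = np.polyfit(both["cm"], both["anchor"], 1)
                for idx in grp.index[missing]:
                    plan.loc[idx, "anchor"] = np.polyval(coef, plan.loc[idx, "cm"])
            else:
                for idx in grp.index[missing]:
                    plan.loc[idx, "anchor"] = plan.loc[idx, "cm"]
    plan = plan.sort_values(["chrom", "anchor"], kind="stable").reset_index(drop=True)
    return plan.drop(columns="cm"), unplaced, overrides


# ---------------------------------------------------------------------------
# Chromosome construction (FASTA + AGP)
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def build_chromosomes(
    plan: pd.DataFrame,
    scaffold_seqs: dict[str, str],
    gap_len: int = GAP_LEN,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate planned scaffolds into chromosome sequences + AGP rows.

    Adjacent scaffolds are joined by exactly ``gap_len`` N characters;
    "-" scaffolds are reverse-complemented. The AGP (2.1 vocabulary:
    W components, N gaps of type scaffold / linkage yes / align_genus)
    mirrors the sequence bit-exactly.
    """
    chroms: dict[str, str] = {}
    agp_rows = []
    for chrom, grp in plan.groupby("chrom", sort=True):
        parts: list[str] = []
        pos = 0
        part_no = 0
        for i, (_, row) in enumerate(grp.iterrows()):
            if row["scaffold"] not in scaffold_seqs:
                raise KeyError(f"missing sequence for scaffold {row['scaffold']}")
            if i > 0:
                part_no += 1
                agp_rows.append({
                    "object": chrom, "object_beg": pos + 1, "object_end": pos + gap_len,
                    "part_number": part_no, "component_type": "N",
                    "component_id": str(gap_len), "component_beg": "scaffold",
                    "component_end": "yes", "orientation": "align_genus",
                })
                parts.append("N" * gap_len)
                pos += gap_len
            seq = scaffold_seqs[row["scaffold"]]
            if row["orientation"] == "-":
                seq = _revcomp(seq)
            part_no += 1
            agp_rows.append({
                "object": chrom, "object_beg": pos + 1, "object_end": pos + len(seq),
                "part_number": part_no, "component_type": "W",
                "component_id": row["scaffold"], "component_beg": 1,
                "component_end": len(scaffold_seqs[row["scaffold"]]),
                "orientation": row["orientation"],
            })
            parts.append(seq)
            pos += len(seq)
        chroms[chrom] = "".join(parts)
    return chroms, pd.DataFrame(agp_rows)


def agp_to_fasta(agp: pd.DataFrame, scaffold_seqs: dict[str, str]) -> dict[str, str]:
    """Reconstruct chromosome sequences from AGP rows (round-trip check)."""
    out: dict[str, str] = {}
    for chrom, grp in agp.groupby("object", sort=True):
        parts = []
        for _, row in grp.sort_values("part_number").iterrows():
            if row["component_type"] == "N":
                parts.append("N" * int(row["component_id"]))
            else:
                seq = scaffold_seqs[row["component_id"]]
                seq = seq[int(row["component_beg"]) - 1:int(row["component_end"])]
                if row["orientation"] == "-":
                    seq = _revcomp(seq)
                parts.append(seq)
        out[chrom] = "".join(parts)
    return out


def write_agp(agp: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for _, r in agp.iterrows():
            fh.write("\t".join(str(r[c]) for c in (
                "object", "object_beg", "object_end", "part_number",
                "component_type", "component_id", "component_beg",
                "component_end", "orientation")) + "\n")


def read_agp(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({
                "object": f[0], "object_beg": int(f[1]), "object_end": int(f[2]),
                "part_number": int(f[3]), "component_type": f[4],
                "component_id": f[5],
                "component_beg": f[6] if f[4] == "N" else int(f[6]),
                "component_end": f[7] if f[4] == "N" else int(f[7]),
                "orientation": f[8],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outgroup comparison, homeolog naming, synteny blocks
# ---------------------------------------------------------------------------

def filter_outgroup_hits(
    hits: pd.DataFrame,
    min_identity: float = MIN_IDENTITY,
    min_match: int = MIN_MATCH,
) -> pd.DataFrame:
    """Keep hits with identity >= 80.0 AND match length >= 100 (inclusive)."""
    mask = (hits["identity"] >= min_identity) & (hits["match_len"] >= min_match)
    return hits[mask].reset_index(drop=True)


def _footprint(hits: pd.DataFrame) -> tuple[int, int]:
    return int(hits["ref_start"].min()), int(hits["ref_end"].max())


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0] + 1, b[1] - b[0] + 1)


def assign_homeolog_names(
    hits: pd.DataFrame,
    secondary_bp_fraction: float = 0.2,
    split_overlap_threshold: float = 0.2,
) -> tuple[dict[str, str], list[str]]:
    """Name duplicated-genome chromosomes after their outgroup orthologs.

    Each query chromosome is matched to its best outgroup chromosome by
    total aligned bp (ties by hit count). The homeologs of outgroup
    chromosome N are named NA, NB, ... by descending aligned bp of the
    ancestral copy they represent; two chromosomes whose outgroup footprints
    barely overlap (< ``split_overlap_threshold``) are treated as fission
    products of one ancestral copy — the pair shares one rank and its second
    piece takes the next letter after all intact copies are lettered (so a
    split top-ranked copy yields e.g. 13A and 13C around an intact 13B).
    Chromosomes aligning to a second outgroup chromosome with more than
    ``secondary_bp_fraction`` of their best-chromosome bp are flagged.
    Returns ``(name_map, flags)``.
    """
    name_map: dict[str, str] = {}
    flags: list[str] = []
    assignments: dict[str, list[tuple[str, int]]] = {}
    for qry, grp in hits.groupby("qry_name"):
        agg = grp.groupby("ref_name").agg(
            bp=("match_len", "sum"), n=("match_len", "size")).reset_index()
        agg = agg.sort_values(["bp", "n", "ref_name"], ascending=[False, False, True])
        best = agg.iloc[0]
        if len(agg) > 1 and agg.iloc[1]["bp"] > secondary_bp_fraction * best["bp"]:
            flags.append(f"{qry}: secondary match to {agg.iloc[1]['ref_name']} "
                         f"({int(agg.iloc[1]['bp'])} bp)")
        assignments.setdefault(str(best["ref_name"]), []).append((qry, int(best["bp"])))

    letters = "ABCDEFGH"
    for ref, members in assignments.items():
        ref_num = "".join(ch for ch in ref if ch.isdigit()) or ref
        members = sorted(members, key=lambda t: (-t[1], t[0]))
        # group members into ancestral copies: fission products have
        # near-disjoint outgroup footprints with each other
        copies: list[list[tuple[str, int]]] = []
        feet = {q: _footprint(hits[(hits["qry_name"] == q) & (hits["ref_name"] == ref)])
                for q, _ in members}
        for q, bp in members:
            placed = False
            for copy in copies:
                if all(_overlap_fraction(feet[q], feet[q2]) < split_overlap_threshold
                       for q2, _ in copy):
                    copy.append((q, bp))
                    placed = True
                    break
            if not placed:
                copies.append([(q, bp)])
        copies.sort(key=lambda c: -sum(bp for _, bp in c))
        n_copies = len(copies)
        next_extra = n_copies  # letter index after one per copy
        for rank, copy in enumerate(copies):
            copy_sorted = sorted(copy, key=lambda t: (-t[1], t[0]))
            name_map[copy_sorted[0][0]] = f"{ref_num}{letters[rank]}"
            for q, _ in copy_sorted[1:]:
                name_map[q] = f"{ref_num}{letters[next_extra]}"
                next_extra += 1
    return name_map, flags


@dataclass
class SyntenyBlock:
    qry_name: str
    ref_name: str
    qry_start: int
    qry_end: int
    ref_start: int
    ref_end: int
    orientation: str
    mean_identity: float
    n_hits: int


def _chain_items(items: list[dict], max_gap: int, overlap_tol: int) -> list[list[dict]]:
    """Greedy chaining of query-sorted hit-like dicts into collinear,
    strand-consistent runs."""
    chains: list[list[dict]] = []
    chain: list[dict] = []
    for h in items:
        if chain:
            prev = chain[-1]
            if h["strand"] == "+":
                ref_gap = h["ref_start"] - prev["ref_end"]
            else:  # "-": reference descends along the ascending query
                ref_gap = prev["ref_start"] - h["ref_end"]
            ok = (
                h["strand"] == prev["strand"]
                and h["qry_start"] - prev["qry_end"] <= max_gap
                and -overlap_tol <= ref_gap <= max_gap
            )
            if not ok:
                chains.append(chain)
                chain = []
        chain.append(h)
    if chain:
        chains.append(chain)
    return chains


def extract_synteny_blocks(
    hits: pd.DataFrame,
    max_gap: int = 1_000_000,
    min_block: int = 100_000,
) -> list[SyntenyBlock]:
    """Chain filtered hits into maximal collinear, strand-consistent runs.

    Hits are chained along the query when they share strand, the query gap
    is <= ``max_gap``, the reference gap is <= ``max_gap`` and the reference
    coordinate progresses in the strand direction. Chaining runs in two
    passes: raw chains below ``min_block`` query span are set aside as
    putative noise and the surviving chains are re-chained, so an isolated
    spurious hit cannot split an otherwise contiguous block. Chains still
    spanning less than ``min_block`` are dropped. Blocks are returned
    sorted by (qry_name, qry_start).
    """
    blocks: list[SyntenyBlock] = []
    tol = min_block // 2
    for (qry, ref), grp in hits.groupby(["qry_name", "ref_name"]):
        items = grp.sort_values("qry_start").to_dict("records")
        first = _chain_items(items, max_gap, tol)
        survivors = [c for c in first
                     if c[-1]["qry_end"] - c[0]["qry_start"] + 1 >= min_block]
        merged: list[dict] = []
        for c in survivors:
            merged.extend(c)
        final = _chain_items(merged, max_gap, tol)
        for chain in final:
            qs = int(chain[0]["qry_start"])
            qe = int(max(h["qry_end"] for h in chain))
            if qe - qs + 1 < min_block:
                continue
            w = np.array([h["match_len"] for h in chain], dtype=float)
            ident = float(np.average([h["identity"] for h in chain], weights=w))
            blocks.append(SyntenyBlock(
                qry, ref, qs, qe,
                int(min(h["ref_start"] for h in chain)),
                int(max(h["ref_end"] for h in chain)),
                chain[0]["strand"], ident, len(chain)))
    blocks.sort(key=lambda b: (b.qry_name, b.qry_start))
    return blocks


def find_inverted_blocks(blocks: Sequence[SyntenyBlock]) -> list[SyntenyBlock]:
    """Blocks whose orientation opposes the majority (bp-weighted) strand of
    their query chromosome — the inversion candidates."""
    out = []
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.qry_name, []).append(b)
    for chrom_blocks in by_chrom.values():
        vote = sum((b.qry_end - b.qry_start + 1) * (1 if b.orientation == "+" else -1)
                   for b in chrom_blocks)
        majority = "+" if vote >= 0 else "-"
        out.extend(b for b in chrom_blocks if b.orientation != majority)
    return out


def classify_inversion(
    block: SyntenyBlock, centromere: float | None
) -> str:
    """"pericentric" iff the block's query interval contains the centromere,
    "paracentric" iff it does not, "unresolved" when the centromere is
    undetermined."""
    if centromere is None:
        return "unresolved"
    return ("pericentric" if block.qry_start <= centromere <= block.qry_end
            else "paracentric")
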