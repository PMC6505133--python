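"""Scaffold placement, chromosome building, synteny blocks and inversions."""

import numpy as np
import pandas as pd
import pytest

from salmokit.simulate import (SimulationConfig, render_fasta,
                               simulate_alignment_hits, simulate_karyotype)
from salmokit.synteny import (ScaffoldPlacement, agp_to_fasta,
                              assign_homeolog_names, best_reference_position,
                              build_chromosomes, classify_inversion,
                              detect_chimeric_scaffolds,
                              extract_synteny_blocks, filter_outgroup_hits,
                              find_inverted_blocks, order_and_orient,
                              read_agp, read_alignment_hits,
                              write_agp, write_alignment_hits)


def _hits(rows):
    df = pd.DataFrame(rows, columns=["qry_name", "qry_start", "qry_end",
                                     "ref_name", "ref_start", "ref_end",
                                     "strand", "identity"])
    df["match_len"] = df["qry_end"] - df["qry_start"] + 1
    return df


# -- readers ----------------------------------------------------------------

def test_coords_reader_normalizes_minus_strand(tmp_path):
    path = tmp_path / "h.tsv"
    path.write_text("ref_start\tref_end\tqry_start\tqry_end\tref_len\tqry_len\t"
                    "identity\tref_name\tqry_name\n"
                    "100\t200\t500\t400\t101\t101\t95.5\tchr1\tscafA\n")
    hits, malformed = read_alignment_hits(path, "coords")
    assert not malformed
    h = hits.iloc[0]
    assert h.strand == "-" and h.qry_start == 400 and h.qry_end == 500


def test_blast_tab_round_trip(tmp_path):
    rows = _hits([("s1", 10, 200, "c1", 1000, 1190, "+", 98.0),
                  ("s1", 300, 450, "c2", 5000, 5150, "-", 88.5)])
    path = tmp_path / "h.tsv"
    write_alignment_hits(rows, path, dialect="blast_tab")
    back, malformed = read_alignment_hits(path, "blast_tab")
    assert not malformed
    pd.testing.assert_frame_equal(back, rows, check_dtype=False)


def test_reader_reports_malformed_lines(tmp_path):
    lines = ["\t".join(map(str, [i, i + 50, i, i + 50, 51, 51, 90.0, "c", "s"]))
             for i in range(1, 11)]
    lines[4] = "not\tenough\tfields"
    path = tmp_path / "h.tsv"
    path.write_text("\n".join(lines) + "\n")
    hits, malformed = read_alignment_hits(path, "coords")
    assert len(hits) == 9
    assert len(malformed) == 1 and "line 5" in malformed[0]


def test_reader_unknown_dialect(tmp_path):
    with pytest.raises(ValueError):
        read_alignment_hits(tmp_path / "x", "maf")


# -- placement --------------------------------------------------------------

def test_best_position_by_total_bp_then_hits():
    hits = _hits([("s", 1, 5000, "chrA", 1, 5000, "+", 95),
                  ("s", 6000, 7000, "chrB", 1, 1001, "+", 95)])
    assert best_reference_position(hits).chromosome == "chrA"
    # equal bp, more hits wins
    tie = _hits([("s", 1, 1000, "chrA", 1, 1000, "+", 95),
                 ("s", 2000, 3000, "chrA", 2000, 3000, "+", 95),
                 ("s", 4000, 4499, "chrA", 4000, 4499, "+", 95),
                 ("s", 5000, 7501, "chrB", 1, 2502, "+", 95)])
    # chrA: 2501 bp over 3 hits; chrB: 2502 bp 1 hit -> chrB by bp
    assert best_reference_position(tie).chromosome == "chrB"
    tie2 = _hits([("s", 1, 1000, "chrA", 1, 1000, "+", 95),
                  ("s", 2000, 2999, "chrA", 2000, 2999, "+", 95),
                  ("s", 5000, 6999, "chrB", 1, 2000, "+", 95)])
    # 2000 bp each; chrA has 2 hits -> chrA
    assert best_reference_position(tie2).chromosome == "chrA"


def test_orientation_weighted_strand_vote():
    hits = _hits([("s", 1, 6000, "c", 1, 6000, "-", 95),      # 6000 bp "-"
                  ("s", 7000, 11000, "c", 7000, 11000, "+", 95)])  # 4001 bp "+"
    assert best_reference_position(hits).orientation == "-"


def test_unplaced_scaffold():
    p = best_reference_position(_hits([]), scaffold="lonely")
    assert p.chromosome is None and p.evidence == "none"


def test_chimera_detection_and_thresholds():
    chim = _hits([("s", 1, 20_000, "chr1", 1, 20_000, "+", 95),
                  ("s", 30_000, 55_000, "chr7", 1, 25_001, "+", 95)])
    decisions = detect_chimeric_scaffolds({"s": chim})
    assert len(decisions) == 1
    d = decisions[0]
    assert d.split_at == 25_000  # midpoint of the 20000..30000 gap
    assert {d.left_chrom, d.right_chrom} == {"chr1", "chr7"}
    # single-chromosome scaffold: no split
    mono = _hits([("s", 1, 20_000, "chr1", 1, 20_000, "+", 95),
                  ("s", 30_000, 55_000, "chr1", 40_000, 65_001, "+", 95)])
    assert detect_chimeric_scaffolds({"s": mono}) == []
    # second segment below min_bp: treated as noise
    small = _hits([("s", 1, 20_000, "chr1", 1, 20_000, "+", 95),
                   ("s", 30_000, 35_000, "chr7", 1, 5_001, "+", 95)])
    assert detect_chimeric_scaffolds({"s": small}) == []


def test_order_and_orient_linkage_override():
    placements = [
        ScaffoldPlacement("s1", "chr1", 1e6, "+", 1000, 2),
        ScaffoldPlacement("s2", "chr1", 2e6, "+", 1000, 2),
        ScaffoldPlacement("s3", "chr2", 5e5, "+", 800, 1),  # linkage says chr1
        ScaffoldPlacement("s4", None, None, None, 0, 0, evidence="none"),
    ]
    linkage = pd.DataFrame({"scaffold": ["s1", "s2", "s3"],
                            "chrom": ["chr1", "chr1", "chr1"],
                            "cm": [10.0, 20.0, 30.0]})
    plan, unplaced, overrides = order_and_orient(placements, linkage)
    assert unplaced == ["s4"]
    assert any("s3" in msg for msg in overrides)
    chr1 = plan[plan["chrom"] == "chr1"]
    assert list(chr1["scaffold"]) == ["s1", "s2", "s3"]  # cM order preserved


def test_order_without_conflicts_follows_anchors():
    placements = [ScaffoldPlacement(f"s{i}", "chr1", float(i), "+", 10, 1)
                  for i in (3, 1, 2)]
    plan, unplaced, overrides = order_and_orient(placements)
    assert list(plan["scaffold"]) == ["s1", "s2", "s3"]
    assert not overrides and not unplaced


# -- chromosome construction ------------------------------------------------

def _plan(rows):
    return pd.DataFrame(rows, columns=["scaffold", "chrom", "anchor", "orientation",
                                       "evidence"])


def test_build_chromosomes_gap_rule():
    seqs = {"a": "A" * 1000, "b": "C" * 2000}
    plan = _plan([("a", "chr1", 1.0, "+", "synteny"),
                  ("b", "chr1", 2.0, "+", "synteny")])
    chroms, agp = build_chromosomes(plan, seqs)
    assert len(chroms["chr1"]) == 3100
    assert chroms["chr1"][1000:1100] == "N" * 100
    single, _ = build_chromosomes(_plan([("a", "chr1", 1.0, "+", "s")]), seqs)
    assert single["chr1"] == seqs["a"]


def test_build_reverse_complements_minus_scaffolds():
    seqs = {"a": "AACGT"}
    chroms, _ = build_chromosomes(_plan([("a", "c", 1.0, "-", "s")]), seqs)
    assert chroms["c"] == "ACGTT"


def test_agp_fasta_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=rng.integers(200, 900)))
            for i in range(6)}
    plan = _plan([(f"s{i}", f"chr{i % 2}", float(i), "+-"[i % 2], "synteny")
                  for i in range(6)])
    chroms, agp = build_chromosomes(plan, seqs)
    assert agp_to_fasta(agp, seqs) == chroms
    # and through the on-disk AGP representation
    path = tmp_path / "x.agp"
    write_agp(agp, path)
    assert agp_to_fasta(read_agp(path), seqs) == chroms
    # length bookkeeping: scaffolds + 100 bp per internal gap
    for chrom, grp in plan.groupby("chrom"):
        expect = sum(len(seqs[s]) for s in grp["scaffold"]) + 100 * (len(grp) - 1)
        assert len(chroms[chrom]) == expect


def test_build_missing_scaffold_errors():
    with pytest.raises(KeyError, match="ghost"):
        build_chromosomes(_plan([("ghost", "c", 1.0, "+", "s")]), {})


# -- outgroup filtering and homeolog naming ---------------------------------

def test_filter_outgroup_inclusive_bounds_and_idempotent():
    hits = _hits([("q", 1, 100, "r", 1, 100, "+", 80.0),
                  ("q", 1, 99, "r", 1, 99, "+", 99.0),
                  ("q", 1, 500, "r", 1, 500, "+", 79.9)])
    kept = filter_outgroup_hits(hits)
    assert len(kept) == 1 and kept["identity"].iloc[0] == 80.0
    pd.testing.assert_frame_equal(filter_outgroup_hits(kept), kept)


def test_homeolog_naming_two_to_one():
    hits = _hits([("gA", 1, 900_000, "pike5", 1, 900_000, "+", 90),
                  ("gB", 1, 800_000, "pike5", 1, 800_000, "+", 88)])
    names, flags = assign_homeolog_names(hits)
    assert names == {"gA": "5A", "gB": "5B"}


def test_homeolog_naming_fission_products_share_copy():
    # one intact homeolog covering all of pike13, plus two complementary
    # fission products of the (larger) other copy
    hits = _hits([
        ("g_intact", 1, 800_000, "pike13", 1, 800_000, "+", 88),
        ("g_left", 1, 500_000, "pike13", 1, 500_000, "+", 90),
        ("g_right", 1, 480_000, "pike13", 510_000, 990_000, "+", 90),
    ])
    names, flags = assign_homeolog_names(hits)
    # the split copy carries more aligned bp -> letter A; its second piece
    # takes the first letter after the intact copies: 13C
    assert names["g_intact"] == "13B"
    assert {names["g_left"], names["g_right"]} == {"13A", "13C"}


def test_homeolog_naming_on_simulated_wgd(small_karyotype):
    """Both derived copies of each ancestral chromosome map to the same
    outgroup chromosome; fission products share one copy's lineage."""
    sim = small_karyotype
    # outgroup = the non-duplicated ancestor: one chromosome per ancestral
    from salmokit.simulate.karyotype import DerivedChromosome, Segment
    outgroup = {
        f"pike{i+1}": DerivedChromosome(
            f"pike{i+1}", [Segment(i, "A", 0, sim.ancestral_length)])
        for i in range(sim.config.n_ancestral_chromosomes)}
    rng = np.random.default_rng(0)
    hits, _ = simulate_alignment_hits(sim.grayling, outgroup, rng,
                                      same_copy_only=False)
    names, flags = assign_homeolog_names(filter_outgroup_hits(hits))
    # chromosomes 1A/1B pair on pike1; 2A and the two 2B fission halves on pike2
    assert {names["1A"], names["1B"]} == {"1A", "1B"}
    assert sorted(names[c] for c in ("2A", "2B.1", "2B.2")) == ["2A", "2B", "2C"]
    pieces = {names["2B.1"], names["2B.2"]}
    assert pieces in ({"2A", "2C"}, {"2B", "2C"})


# -- synteny blocks and inversion classification ----------------------------

def test_collinear_hits_chain_to_single_block():
    hits = _hits([("q", i * 10_000 + 1, i * 10_000 + 9_000,
                   "r", i * 10_000 + 1, i * 10_000 + 9_000, "+", 92)
                  for i in range(30)])
    blocks = extract_synteny_blocks(hits)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.orientation == "+" and b.n_hits == 30
    assert b.qry_start == 1 and b.qry_end == 299_000


def test_planted_inversion_gives_three_blocks(small_karyotype):
    sim = small_karyotype
    rng = np.random.default_rng(1)
    hits, _ = simulate_alignment_hits(sim.grayling, sim.salmon, rng)
    blocks = [b for b in extract_synteny_blocks(filter_outgroup_hits(hits))
              if b.qry_name == "1A"]
    assert [b.orientation for b in blocks] == ["+", "-", "+"]
    inv = blocks[1]
    # boundaries within one hit length of the planted event
    assert abs(inv.qry_start - 4_000_001) < 250_000
    assert abs(inv.qry_end - 9_000_000) < 250_000


def test_classify_inversion_rules():
    from salmokit.synteny import SyntenyBlock
    block = SyntenyBlock("c", "r", 1_000_000, 5_000_000, 1, 1, "-", 90.0, 5)
    assert classify_inversion(block, 2_000_000) == "pericentric"
    assert classify_inversion(block, 6_000_000) == "paracentric"
    assert classify_inversion(block, None) == "unresolved"


def test_noise_hits_removed_by_filter(small_karyotype):
    sim = small_karyotype
    rng = np.random.default_rng(2)
    hits, truth = simulate_alignment_hits(sim.grayling, sim.salmon, rng,
                                          noise_rate=0.5)
    kept = filter_outgroup_hits(hits)
    kept_noise = truth.loc[kept.index, "is_noise"]
    # identity/match-count filtering leaves only short passing noise, which
    # chaining then discards
    blocks_noisy = extract_synteny_blocks(kept)
    blocks_clean = extract_synteny_blocks(
        hits[~truth["is_noise"]].reset_index(drop=True))
    assert len(blocks_noisy) == len(blocks_clean)
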