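"""Synthetic-data generators: determinism, conservation, ground truth."""

import numpy as np
import pandas as pd
import pytest

from salmokit.simulate import (SimulationConfig, render_fasta,
                               simulate_alignment_hits, simulate_karyotype,
                               simulate_linkage_instance, simulate_rad_family,
                               simulate_repeat_landscape, total_length)
from salmokit.simulate.karyotype import Segment


# -- karyotype --------------------------------------------------------------

def test_identity_case_duplicates_ancestor():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=2,
                           chromosome_length_bp=1_000_000)
    sim = simulate_karyotype(cfg)
    for genome in (sim.grayling, sim.salmon):
        assert sorted(genome) == ["1A", "1B", "2A", "2B"]
        for chrom in genome.values():
            assert len(chrom.segments) == 1
            assert chrom.length == 1_000_000
    assert sim.truth.rearrangements == []


def test_fission_adds_chromosome_and_log_entry():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=2,
                           chromosome_length_bp=1_000_000,
                           fission_events=[("1A", 600_000)])
    sim = simulate_karyotype(cfg)
    assert len(sim.grayling) == 5
    assert {"1A.1", "1A.2"} <= set(sim.grayling)
    assert [r.kind for r in sim.truth.rearrangements] == ["fission"]
    # only one product carries the centromere
    cens = sim.truth.centromeres["grayling"]
    assert (cens["1A.1"] is None) != (cens["1A.2"] is None)


def test_pericentric_inversion_segments_match_hand_reversal():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=1,
                           chromosome_length_bp=1_000_000,
                           inversion_events=[("1A", 50_000, 300_000, True)])
    sim = simulate_karyotype(cfg)
    assert sim.grayling["1A"].segments == [
        Segment(0, "A", 0, 50_000, 1),
        Segment(0, "A", 50_000, 300_000, -1),
        Segment(0, "A", 300_000, 1_000_000, 1),
    ]
    # centromere (ancestrally at 100 kb) maps through the reversal
    assert sim.truth.centromeres["grayling"]["1A"] == 50_000 + (300_000 - 1 - 100_000)
    assert sim.truth.rearrangements[0].spans_centromere is True


def test_declared_spans_centromere_mismatch_rejected():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=1,
                           chromosome_length_bp=1_000_000,
                           inversion_events=[("1A", 500_000, 700_000, True)])
    with pytest.raises(ValueError, match="spans_centromere"):
        simulate_karyotype(cfg)


def test_overlapping_events_rejected_with_pair():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=1,
                           chromosome_length_bp=1_000_000,
                           inversion_events=[("1A", 100_000, 400_000, None),
                                             ("1A", 300_000, 500_000, None)])
    with pytest.raises(ValueError, match="overlapping"):
        simulate_karyotype(cfg)


def test_length_conservation_through_events():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=3,
                           chromosome_length_bp=2_000_000,
                           inversion_events=[("1A", 100_000, 900_000, None)],
                           fission_events=[("2A", 1_000_000)],
                           fusion_events=[("1B", "3B")])
    sim = simulate_karyotype(cfg)
    assert total_length(sim.grayling) == 6 * 2_000_000
    assert total_length(sim.salmon) == 6 * 2_000_000
    assert len(sim.salmon) == 5  # fusion shrinks the salmon-like karyotype


def test_fusions_only_touch_salmon_lineage():
    cfg = SimulationConfig(seed=0, n_ancestral_chromosomes=2,
                           chromosome_length_bp=1_000_000,
                           fusion_events=[("1A", "2A")])
    sim = simulate_karyotype(cfg)
    assert len(sim.grayling) == 4
    assert "1A+2A" in sim.salmon and len(sim.salmon) == 3


def test_determinism_seed_fixed():
    cfg = dict(seed=5, n_ancestral_chromosomes=2, chromosome_length_bp=500_000,
               markers_per_chromosome=20, n_offspring=30)
    a, b = (simulate_karyotype(SimulationConfig(**cfg)) for _ in range(2))
    fam_a = simulate_rad_family(a.grayling, a.config)
    fam_b = simulate_rad_family(b.grayling, b.config)
    pd.testing.assert_frame_equal(fam_a.sites, fam_b.sites)
    assert np.array_equal(fam_a.genotypes, fam_b.genotypes)
    assert np.array_equal(fam_a.coverage, fam_b.coverage)
    assert render_fasta(a.grayling, a.config) == render_fasta(b.grayling, b.config)


def test_render_fasta_reverse_complements_inversions():
    base = SimulationConfig(seed=3, n_ancestral_chromosomes=1,
                            chromosome_length_bp=10_000)
    plain = render_fasta(simulate_karyotype(base).grayling, base)
    inv_cfg = SimulationConfig(seed=3, n_ancestral_chromosomes=1,
                               chromosome_length_bp=10_000,
                               inversion_events=[("1A", 2_000, 5_000, None)])
    inverted = render_fasta(simulate_karyotype(inv_cfg).grayling, inv_cfg)
    comp = str.maketrans("ACGT", "TGCA")
    assert inverted["1A"][:2_000] == plain["1A"][:2_000]
    assert inverted["1A"][2_000:5_000] == \
        plain["1A"][2_000:5_000].translate(comp)[::-1]
    assert inverted["1A"][5_000:] == plain["1A"][5_000:]


# -- RAD family -------------------------------------------------------------

def test_zero_crossover_rate_constant_phases():
    cfg = SimulationConfig(seed=1, n_ancestral_chromosomes=1,
                           chromosome_length_bp=1_000_000,
                           markers_per_chromosome=10, n_offspring=40)
    sim = simulate_karyotype(cfg)
    fam = simulate_rad_family(sim.grayling, cfg, female_cm_per_mb=0.0,
                              missing_rate=0.0, bad_marker_fraction=0.0)
    for chrom in ("1A", "1B"):
        rows = fam.sites["chrom"] == chrom
        phases = fam.phases["female"][rows.to_numpy()]
        assert (phases == phases[0]).all()


def test_adjacent_recombination_fraction_matches_rate():
    cfg = SimulationConfig(seed=2, n_ancestral_chromosomes=1,
                           chromosome_length_bp=11_000_000,
                           markers_per_chromosome=12, n_offspring=10_000)
    sim = simulate_karyotype(cfg)
    genome = {"1A": sim.grayling["1A"]}  # one chromosome suffices
    fam = simulate_rad_family(genome, cfg, female_cm_per_mb=5.0,
                              missing_rate=0.0, bad_marker_fraction=0.0)
    phases = fam.phases["female"]
    # adjacent markers are 1 Mb apart: d = 0.05 Morgans;
    # expected flip probability = P(odd Poisson(d)) = (1 - exp(-2d)) / 2
    d = 0.05
    expect = (1 - np.exp(-2 * d)) / 2
    n = phases.shape[1]
    for i in range(11):
        obs = (phases[i] != phases[i + 1]).mean()
        sd = np.sqrt(expect * (1 - expect) / n)
        assert abs(obs - expect) < 3.5 * sd


def test_planted_distorted_marker_rejected_by_chisquare():
    from salmokit.radfilter import CrossType, segregation_test
    rng = np.random.default_rng(0)
    rejected = 0
    for _ in range(50):
        geno = (rng.random(113) < 0.1).astype(int)  # 9:1 instead of 1:1
        het = int(geno.sum())
        stat, p = segregation_test([113 - het, het], CrossType.test_cross_p1)
        rejected += p < 0.05
    assert rejected == 50  # 9:1 at n=113 is far beyond the 5% threshold


def test_family_requires_offspring_and_markers():
    cfg = SimulationConfig(seed=0, n_offspring=0)
    sim = simulate_karyotype(SimulationConfig(seed=0))
    with pytest.raises(ValueError):
        simulate_rad_family(sim.grayling, cfg)
    cfg2 = SimulationConfig(seed=0, markers_per_chromosome=1)
    with pytest.raises(ValueError):
        simulate_rad_family(sim.grayling, cfg2)


# -- repeat landscape -------------------------------------------------------

def test_modal_bin_is_centromere_bin():
    # centromere mid-bin (a centromere exactly on a bin boundary splits the
    # peak evenly between the two flanking bins)
    hits = 0
    L, cen = 10_000_000, 5_050_000
    for seed in range(40):
        rng = np.random.default_rng(seed)
        ann = simulate_repeat_landscape("c", L, cen, rng,
                                        peak_width_bp=1_000_000,
                                        n_tc1_peak=10_000)
        tc1 = ann[ann["superfamily"] == "Tc1-Mariner"]
        counts = np.bincount((tc1["start"] - 1) // 100_000, minlength=100)
        hits += int(np.argmax(counts)) == cen // 100_000
    assert hits >= 38  # modal bin matches in >=95% of runs


def test_zero_peak_gives_undetermined_centromere():
    from salmokit.repeats import bin_density, lowess_smooth, predict_centromere
    rng = np.random.default_rng(0)
    ann = simulate_repeat_landscape("c", 5_000_000, None, rng, n_tc1_peak=0,
                                    n_tc1_background=0)
    prof = lowess_smooth(bin_density(ann, "c", 5_000_000, "Tc1-Mariner"))
    assert predict_centromere(prof)[0] is None


def test_uniform_landscape_peak_position_unbiased():
    """Without a planted peak the smoothed argmax must not concentrate at any
    interior location. (The chromosome ends are excluded: one-sided lowess
    windows inflate the fit variance there, so the argmax lands on the edge
    bins more often than uniform — a boundary artifact, not a bias toward
    any genomic position.)"""
    from salmokit.repeats import bin_density, lowess_smooth
    from scipy import stats as sstats
    L = 5_000_000
    positions = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        ann = simulate_repeat_landscape("c", L, None, rng, n_tc1_peak=0,
                                        n_tc1_background=400)
        prof = lowess_smooth(bin_density(ann, "c", L, "Tc1-Mariner"))
        positions.append(int(np.argmax(prof.smoothed)))
    interior = [p for p in positions if 0 < p < 49]
    counts, _ = np.histogram(interior, bins=4, range=(1, 49))
    assert sstats.chisquare(counts).pvalue > 0.001
    # left/right symmetry of the full distribution
    left = sum(p < 25 for p in positions)
    assert abs(left - len(positions) / 2) < 3 * np.sqrt(len(positions)) / 2


def test_landscape_argument_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        simulate_repeat_landscape("c", 1_000_000, 500_000, rng, peak_width_bp=0)
    with pytest.raises(ValueError):
        simulate_repeat_landscape("c", 1_000_000, 2_000_000, rng)


# -- alignment hits ---------------------------------------------------------

def test_identical_genomes_full_length_plus_hits():
    cfg = SimulationConfig(seed=4, n_ancestral_chromosomes=1,
                           chromosome_length_bp=2_000_000)
    sim = simulate_karyotype(cfg)
    rng = np.random.default_rng(0)
    hits, truth = simulate_alignment_hits(sim.grayling, sim.salmon, rng,
                                          hit_len=2_000_000, hit_gap=0)
    assert not truth["is_noise"].any()
    assert (hits["strand"] == "+").all()
    assert (hits["match_len"] == 2_000_000).all()
    assert set(zip(hits["qry_name"], hits["ref_name"])) == \
        {("1A", "1A"), ("1B", "1B")}


def test_planted_inversion_yields_minus_hits_only_inside(small_karyotype):
    sim = small_karyotype
    rng = np.random.default_rng(3)
    hits, truth = simulate_alignment_hits(sim.grayling, sim.salmon, rng)
    h1a = hits[hits["qry_name"] == "1A"]
    minus = h1a[h1a["strand"] == "-"]
    assert len(minus) > 0
    assert minus["qry_start"].min() >= 4_000_001
    assert minus["qry_end"].max() <= 9_000_000


def test_linkage_instance_reference_scramble_is_consistent():
    inst = simulate_linkage_instance(0, n_markers=20, n_blocks=3, n_inverted=1)
    # reference order recovers the planted permutation of blocks
    ref_order = np.argsort(inst.ref_positions)
    rebuilt = []
    bounds = inst.block_bounds
    for bi in inst.block_permutation:
        block = list(range(bounds[bi], bounds[bi + 1]))
        rebuilt.extend(block[::-1] if bi in inst.inverted_blocks else block)
    assert ref_order.tolist() == rebuilt
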