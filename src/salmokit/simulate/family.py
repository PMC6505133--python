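"""Two-parent RAD family simulator.

Emulates the mapping-family design: two parents, 69 female and 44 male
offspring (113 total), markers spread along each chromosome, grandparental
phase inherited through a Poisson crossover process without interference
(an interval of d Morgans flips phase when it receives an odd number of
crossovers). Per-call read coverage follows a negative binomial with
configurable mean and dispersion (defaults 30 and 5). A configurable
fraction of markers is planted to violate each filtering rule (fragment
length, parental coverage, distorted segregation) and a configurable set of
offspring is planted with low coverage, so the filtering stage can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotype import Genome, SimulationConfig

#: default female recombination rate, cM per Mb (male rate = female / 1.75,
#: the study-level female:male map-distance ratio)
FEMALE_CM_PER_MB = 2.0
FEMALE_MALE_RATIO = 1.75
COVERAGE_MEAN = 30.0
COVERAGE_DISPERSION = 5.0


@dataclass
class FamilyTruth:
    """Ground truth of one simulated family."""

    marker_table: pd.DataFrame  # marker_id, chrom, pos_bp, cm_female, status, reason
    bad_offspring: list[str] = field(default_factory=list)

    def good_marker_ids(self) -> list[str]:
        t = self.marker_table
        return list(t.loc[t["status"] == "good", "marker_id"])


@dataclass
class RadFamily:
    """Simulated genotype matrix plus per-parent phase matrices."""

    sites: pd.DataFrame  # one row per marker (parent genotypes, coverages, fragment length)
    genotypes: np.ndarray  # (n_markers, n_offspring), 0/1/2, -1 missing
    coverage: np.ndarray  # (n_markers, n_offspring)
    offspring_ids: list[str]
    phases: dict[str, np.ndarray]  # parent -> (n_markers, n_offspring) 0/1/-1
    truth: FamilyTruth


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _simulate_phases(
    rng: np.random.Generator,
    morgans_between: np.ndarray,
    n_offspring: int,
) -> np.ndarray:
    """Phase matrix for one chromosome: Poisson crossovers, no interference."""
    n_markers = morgans_between.size + 1
    phases = np.empty((n_markers, n_offspring), dtype=np.int8)
    phases[0] = rng.integers(0, 2, size=n_offspring)
    if n_markers > 1:
        crossovers = rng.poisson(morgans_between[:, None],
                                 size=(morgans_between.size, n_offspring))
        flips = (crossovers % 2).astype(np.int8)
        phases[1:] = (phases[0][None, :] + np.cumsum(flips, axis=0)) % 2
    return phases


def simulate_rad_family(
    genome: Genome,
    config: SimulationConfig,
    female_cm_per_mb: float = FEMALE_CM_PER_MB,
    coverage_mean: float = COVERAGE_MEAN,
    coverage_dispersion: float = COVERAGE_DISPERSION,
    bad_marker_fraction: float = 0.03,
    n_bad_offspring: int = 0,
    missing_rate: float = 0.02,
    intercross_fraction: float = 0.4,
) -> RadFamily:
    """Simulate a RAD family genotyped on ``genome``.

    ``bad_marker_fraction`` is planted per violation type (fragment length,
    parental coverage, segregation distortion); ``n_bad_offspring`` offspring
    get low-coverage calls throughout. Raises ValueError when
    ``config.n_offspring`` < 1 or fewer than 2 markers per chromosome are
    requested.
    """
    if config.n_offspring < 1:
        raise ValueError("need at least one offspring")
    if config.markers_per_chromosome < 2:
        raise ValueError("need at least two markers per chromosome")
    rng = config.substream("family")
    n_off = config.n_offspring
    n_female = round(n_off * 69 / 113)
    offspring_ids = [f"off_{i:03d}_{'F' if i < n_female else 'M'}" for i in range(n_off)]

    site_rows = []
    phase_blocks = {"female": [], "male": []}
    male_cm_per_mb = female_cm_per_mb / FEMALE_MALE_RATIO
    for chrom_name, chrom in genome.items():
        m = config.markers_per_chromosome
        pos = np.linspace(0, chrom.length - 1, m).astype(np.int64)
        d_mb = np.diff(pos) / 1e6
        for parent, rate in (("female", female_cm_per_mb), ("male", male_cm_per_mb)):
            morgans = d_mb * rate / 100.0
            phase_blocks[parent].append(_simulate_phases(rng, morgans, n_off))
        cm = np.concatenate([[0.0], np.cumsum(d_mb * female_cm_per_mb)])
        for k in range(m):
            site_rows.append({
                "marker_id": f"{chrom_name}_m{k:04d}", "chrom": chrom_name,
                "pos_bp": int(pos[k]) + 1, "cm_female": float(cm[k]),
            })
    sites = pd.DataFrame(site_rows)
    n_markers = len(sites)
    phases = {p: np.vstack(blocks) for p, blocks in phase_blocks.items()}

    # cross design per marker
    u = rng.random(n_markers)
    cross = np.where(u < intercross_fraction, "intercross",
                     np.where(u < intercross_fraction + (1 - intercross_fraction) / 2,
                              "test_cross_p1", "test_cross_p2"))
    sites["cross_type"] = cross
    sites["p1_genotype"] = np.where(np.isin(cross, ["intercross", "test_cross_p1"]), 1, 0)
    sites["p2_genotype"] = np.where(np.isin(cross, ["intercross", "test_cross_p2"]), 1, 0)

    # genotypes from phases: allele from the informative parent's phase,
    # homozygous parent contributes allele 0
    g_f = phases["female"]
    g_m = phases["male"]
    geno = np.zeros((n_markers, n_off), dtype=np.int8)
    for i in range(n_markers):
        if cross[i] == "intercross":
            geno[i] = g_f[i] + g_m[i]
        elif cross[i] == "test_cross_p1":
            geno[i] = g_f[i]  # 0 -> hom, 1 -> het
        else:
            geno[i] = g_m[i]

    # plant filter violations
    status = np.array(["good"] * n_markers, dtype=object)
    reason = np.array([""] * n_markers, dtype=object)
    n_bad = int(round(bad_marker_fraction * n_markers))
    bad_idx = rng.choice(n_markers, size=min(3 * n_bad, n_markers), replace=False)
    frag_bad, cov_bad, seg_bad = (bad_idx[:n_bad], bad_idx[n_bad:2 * n_bad],
                                  bad_idx[2 * n_bad:3 * n_bad])
    fragment = rng.integers(182, 187, size=n_markers)
    fragment[frag_bad] = rng.choice([180, 181, 187, 190], size=frag_bad.size)
    p1_cov = _nb_counts(rng, 60, 10, n_markers).clip(9, 300)
    p2_cov = _nb_counts(rng, 60, 10, n_markers).clip(9, 300)
    which = rng.random(cov_bad.size) < 0.5
    p1_cov[cov_bad[which]] = rng.choice([4, 8, 320, 400], size=int(which.sum()))
    p2_cov[cov_bad[~which]] = rng.choice([4, 8, 320, 400], size=int((~which).sum()))
    status[frag_bad], reason[frag_bad] = "bad", "fragment_length"
    status[cov_bad], reason[cov_bad] = "bad", "coverage"
    # distorted segregation: 9:1 genotype draw, test-cross style
    for i in seg_bad:
        cross[i] = "test_cross_p1"
        sites.loc[i, ["cross_type", "p1_genotype", "p2_genotype"]] = \
            ["test_cross_p1", 1, 0]
        geno[i] = (rng.random(n_off) < 0.1).astype(np.int8)
        phases["female"][i] = geno[i]
    status[seg_bad], reason[seg_bad] = "bad", "segregation_distorted"

    sites["fragment_length"] = fragment
    sites["p1_coverage"] = p1_cov
    sites["p2_coverage"] = p2_cov

    coverage = _nb_counts(rng, coverage_mean, coverage_dispersion, (n_markers, n_off))
    bad_off = list(rng.choice(n_off, size=n_bad_offspring, replace=False)) \
        if n_bad_offspring else []
    for j in bad_off:
        coverage[:, j] = _nb_counts(rng, 4.0, coverage_dispersion, n_markers)

    missing = rng.random((n_markers, n_off)) < missing_rate
    geno = geno.astype(np.int8)
    geno[missing] = -1
    coverage[missing] = 0
    for parent in phases:
        phases[parent] = phases[parent].astype(np.int8)
        phases[parent][missing] = -1

    truth = FamilyTruth(
        marker_table=sites.assign(status=status, reason=reason)[
            ["marker_id", "chrom", "pos_bp", "cm_female", "status", "reason"]],
        bad_offspring=[offspring_ids[j] for j in bad_off],
    )
    return RadFamily(sites, geno, coverage, offspring_ids, phases, truth)


# ---------------------------------------------------------------------------
# Direct salmonization instances
# ---------------------------------------------------------------------------

@dataclass
class LinkageInstance:
    """One linkage group with a planted block scramble against a reference."""

    phases: np.ndarray  # (n_markers, n_offspring), true-order rows
    ref_positions: np.ndarray  # reference coordinate per marker (true-order rows)
    true_order: np.ndarray  # identity permutation (markers are in true order)
    block_bounds: list[int]
    block_permutation: tuple[int, ...]  # reference order of the true blocks
    inverted_blocks: tuple[int, ...]  # true-block ids reversed in the reference
    adjacent_cm: np.ndarray


def simulate_linkage_instance(
    seed: int,
    n_markers: int = 40,
    n_blocks: int = 5,
    n_inverted: int = 1,
    n_offspring: int = 100,
    adjacent_cm_range: tuple[float, float] = (2.0, 5.0),
) -> LinkageInstance:
    """Phase data in a known true order plus reference coordinates that
    scramble contiguous blocks (a permutation with one or more internally
    reversed blocks) — the salmonization search problem with known answer.

    The permutation is drawn non-identity and the inverted blocks hold at
    least two markers, so the planted rearrangement is always recoverable.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    if n_blocks > n_markers // 2:
        raise ValueError("too many blocks for the marker count")
    adj = rng.uniform(*adjacent_cm_range, size=n_markers - 1)
    phases = _simulate_phases(rng, adj / 100.0, n_offspring)

    # contiguous blocks of at least 2 markers each
    cuts = sorted(rng.choice(np.arange(2, n_markers - 1, 2), size=n_blocks - 1,
                             replace=False)) if n_blocks > 1 else []
    bounds = [0] + list(cuts) + [n_markers]
    blocks = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_blocks)]

    perm = tuple(rng.permutation(n_blocks))
    while n_blocks > 1 and perm == tuple(range(n_blocks)) and n_inverted == 0:
        perm = tuple(rng.permutation(n_blocks))
    inverted = tuple(sorted(rng.choice(n_blocks, size=n_inverted, replace=False)))

    ref_order = []
    for bi in perm:
        b = blocks[bi]
        ref_order.extend(b[::-1] if bi in inverted else b)
    ref_positions = np.empty(n_markers)
    ref_positions[np.asarray(ref_order)] = np.arange(n_markers) * 1e6

    return LinkageInstance(
        phases=phases.astype(np.int8),
        ref_positions=ref_positions,
        true_order=np.arange(n_markers),
        block_bounds=bounds,
        block_permutation=perm,
        inverted_blocks=inverted,
        adjacent_cm=adj,
    )
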