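"""Canonical simulation studies exercising the pipeline end to end.

Each function runs one validation study under fixed, documented conditions
(problem sizes in docs/methods.md) and returns raw per-run results, so the
same protocol backs both the test suite and the reproduction script. All
randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import linkage, radfilter, repeats
from .simulate import (
    SimulationConfig,
    simulate_alignment_hits,
    simulate_karyotype,
    simulate_linkage_instance,
    simulate_repeat_landscape,
)
from .synteny import (
    classify_inversion,
    extract_synteny_blocks,
    filter_outgroup_hits,
    find_inverted_blocks,
)


def _child_seeds(seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence(seed, spawn_key=(stream,))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Salmonization parameter recovery
# ---------------------------------------------------------------------------

def salmonization_recovery(
    seed: int,
    n_runs: int = 100,
    n_markers: int = 40,
    n_blocks: int = 5,
    n_inverted: int = 1,
    n_offspring: int = 100,
) -> list[dict]:
    """Refine planted block-scrambled groups; record whether the true marker
    order (up to whole-group reversal) was recovered."""
    out = []
    for s in _child_seeds(seed, n_runs, stream=1):
        inst = simulate_linkage_instance(
            s, n_markers=n_markers, n_blocks=n_blocks,
            n_inverted=n_inverted, n_offspring=n_offspring)
        pm = linkage.PhaseMatrix(inst.phases, list(range(n_markers)))
        res = linkage.salmonize_group("sim", pm, inst.ref_positions)
        fo = res.final_order
        recovered = bool(
            np.array_equal(fo, inst.true_order)
            or np.array_equal(fo[::-1], inst.true_order))
        out.append({"instance": inst, "result": res, "matrix": pm,
                    "recovered": recovered})
    return out


# ---------------------------------------------------------------------------
# Centromere and karyotype recovery
# ---------------------------------------------------------------------------

#: Frozen conditions of the centromere study: a compact 5 Mb chromosome
#: (50 bins) carrying a broad Gaussian pericentromeric Tc1-Mariner domain
#: (sd 875 kb) of 12,000 annotation records over an 800-record uniform
#: background, centromere uniform in [0.2, 0.8] of the length.
CENTROMERE_STUDY = dict(
    chrom_length=5_000_000,
    peak_width_bp=3_500_000,
    n_tc1_peak=12_000,
    n_tc1_background=800,
    cen_range=(0.2, 0.8),
)


def centromere_recovery(seed: int, n_chromosomes: int = 100) -> pd.DataFrame:
    """Predict centromeres and karyotype classes on simulated landscapes."""
    cfg = CENTROMERE_STUDY
    L = cfg["chrom_length"]
    rows = []
    for s in _child_seeds(seed, n_chromosomes, stream=2):
        rng = np.random.default_rng(s)
        cen = int(rng.uniform(*cfg["cen_range"]) * L)
        ann = simulate_repeat_landscape(
            "chr", L, cen, rng, peak_width_bp=cfg["peak_width_bp"],
            n_tc1_peak=cfg["n_tc1_peak"],
            n_tc1_background=cfg["n_tc1_background"],
            n_rtex=500, n_background=500)
        prof = repeats.lowess_smooth(
            repeats.bin_density(ann, "chr", L, "Tc1-Mariner"))
        pos, ambiguous = repeats.predict_centromere(prof)
        true_model = repeats.karyotype_class(L, cen)
        pred_model = repeats.karyotype_class(L, pos) if pos is not None else None
        rows.append({
            "true_cen": cen, "predicted_cen": pos,
            "err_bins": (abs(pos - cen) // prof.bin_width if pos is not None
                         else np.inf),
            "within_1_bin": pos is not None
            and abs(int(pos // prof.bin_width) - cen // prof.bin_width) <= 1,
            "true_ratio": true_model.arm_ratio,
            "true_class": true_model.karyotype,
            "pred_class": pred_model.karyotype if pred_model else None,
            "ambiguous": ambiguous,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inversion-call recovery
# ---------------------------------------------------------------------------

def _random_inversions(rng: np.random.Generator, chrom_names, L: int, cen: int):
    events = []
    for name in chrom_names:
        if rng.random() < 0.5:  # pericentric: interval spans the centromere
            start = int(rng.uniform(0.2 * cen, 0.8 * cen))
            end = int(rng.uniform(cen + 0.1 * L, cen + 0.4 * L))
        else:  # paracentric: interval on the long arm
            start = int(rng.uniform(cen + 0.15 * L, cen + 0.4 * L))
            end = start + int(rng.uniform(0.15 * L, 0.3 * L))
        events.append((name, start, min(end, L - 1), None))
    return events


def inversion_recovery(
    seed: int,
    n_runs: int = 50,
    noise_rate: float = 0.0,
    chrom_length: int = 20_000_000,
) -> list[dict]:
    """Two-lineage simulations: plant inversions, extract synteny blocks,
    classify pericentric/paracentric, compare with the rearrangement log."""
    out = []
    for s in _child_seeds(seed, n_runs, stream=3):
        rng = np.random.default_rng(s)
        cen = int(0.1 * chrom_length)
        cfg = SimulationConfig(
            seed=s, n_ancestral_chromosomes=2, chromosome_length_bp=chrom_length,
            hit_noise_rate=noise_rate,
            inversion_events=_random_inversions(rng, ["1A", "2A"], chrom_length, cen))
        sim = simulate_karyotype(cfg)
        hits, _ = simulate_alignment_hits(
            sim.grayling, sim.salmon, cfg.substream("hits"), noise_rate=noise_rate)
        blocks = extract_synteny_blocks(filter_outgroup_hits(hits))
        calls = sorted(
            (b.qry_name,
             classify_inversion(b, sim.centromere_of("grayling", b.qry_name)))
            for b in find_inverted_blocks(blocks))
        truth = sorted(
            (r.chromosome, "pericentric" if r.spans_centromere else "paracentric")
            for r in sim.truth.rearrangements if r.kind == "inversion")
        out.append({"sim": sim, "calls": calls, "truth": truth,
                    "blocks": blocks, "recovered": calls == truth})
    return out


# ---------------------------------------------------------------------------
# Statistical calibration
# ---------------------------------------------------------------------------

def segregation_null_rate(
    seed: int,
    n_reps: int = 200,
    n_markers: int = 2000,
    n_offspring: int = 113,
    alpha: float = 0.05,
) -> dict:
    """Pre-FDR rejection rate of the intercross segregation test under the
    exact Mendelian null."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_offspring, [0.25, 0.5, 0.25],
                             size=n_reps * n_markers)
    expected = n_offspring * np.array([0.25, 0.5, 0.25])
    stat = ((counts - expected) ** 2 / expected).sum(axis=1)
    p = sstats.chi2.sf(stat, df=2)
    rate = float((p < alpha).mean())
    per_rep = (p < alpha).reshape(n_reps, n_markers).mean(axis=1)
    se = float(np.sqrt(alpha * (1 - alpha) / (n_reps * n_markers)))
    return {"rate": rate, "se": se, "n_tests": n_reps * n_markers,
            "per_rep_sd": float(per_rep.std(ddof=1)),
            "within_3se": abs(rate - alpha) <= 3 * se}


def exact_intercross_test_level(n_offspring: int = 113, alpha: float = 0.05) -> float:
    """Exact null rejection probability of the Pearson 1:2:1 chi-square at
    ``alpha``, by complete multinomial enumeration (independent oracle for
    the calibration study; the asymptotic level differs from ``alpha`` by
    the chi-square approximation error at finite n)."""
    from math import exp, lgamma

    n = n_offspring
    logfact = [lgamma(k + 1) for k in range(n + 1)]
    logp = np.log([0.25, 0.5, 0.25])
    expected = n * np.array([0.25, 0.5, 0.25])
    level = 0.0
    for a in range(n + 1):
        for b in range(n + 1 - a):
            c = n - a - b
            stat = (((a - expected[0]) ** 2) / expected[0]
                    + ((b - expected[1]) ** 2) / expected[1]
                    + ((c - expected[2]) ** 2) / expected[2])
            if sstats.chi2.sf(stat, df=2) < alpha:
                level += exp(logfact[n] - logfact[a] - logfact[b] - logfact[c]
                             + a * logp[0] + b * logp[1] + c * logp[2])
    return level


def lrt_null_pvalues(
    seed: int, n_reps: int = 500, n_chromosomes: int = 48
) -> np.ndarray:
    """LRT p-values of the arm-ratio term when its true effect is zero."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    for i in range(n_reps):
        size = rng.uniform(6, 45, n_chromosomes)
        ratio = rng.uniform(1, 9, n_chromosomes)
        y = 2.0 * size + rng.normal(0, 10, n_chromosomes)
        ps[i] = repeats.map_length_model(y, size, ratio).lrt_p
    return ps


def outlier_calibration(
    seed: int, n_reps: int = 100, n_elements: int = 100
) -> dict:
    """Planted-outlier detection and exact-proportionality false positives."""
    rng = np.random.default_rng(seed)
    detected = 0
    false_positives = 0
    for _ in range(n_reps):
        a = rng.uniform(1e3, 1e7, n_elements)
        b = 1.4 * a
        # exact proportionality: no element may be flagged
        res = repeats.abundance_outliers(a, b)
        false_positives += int(res.table["outlier"].sum())
        # plant one element absent in A, huge in B
        a2, b2 = a.copy(), b * np.exp2(rng.normal(0, 0.2, n_elements))
        a2[0], b2[0] = 0.0, 1e6
        res2 = repeats.abundance_outliers(a2, b2)
        if bool(res2.table["outlier"].iloc[0]) and \
                res2.table["direction"].iloc[0] == "B-enriched":
            detected += 1
    return {"detected": detected, "n_reps": n_reps,
            "false_positives": false_positives}
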