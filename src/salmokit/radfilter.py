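"""RAD marker and offspring filters for linkage-map input.

Filtering rules (all thresholds configurable, defaults read literally from
the study design they implement):

* parental site filter — restriction fragment length 182-186 bp inclusive
  and per-base read coverage 9-300 inclusive in BOTH parents;
* informativeness — at least one heterozygous parent, biallelic offspring
  genotypes;
* Mendelian segregation — Pearson chi-square against 1:1 (test cross) or
  1:2:1 (intercross) expectations, with Benjamini-Hochberg FDR control over
  the whole marker set; distorted markers are removed;
* offspring filter — an offspring is retained iff >= 1,000 of its markers
  are genotyped at coverage > 8 (strict).

Genotypes are coded 0/1/2 (= AA/AB/BB) with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

FRAGMENT_RANGE = (182, 186)
PARENT_COV_RANGE = (9, 300)
OFFSPRING_MIN_MARKERS = 1000
OFFSPRING_MIN_COV = 8  # strict: coverage must exceed this


class CrossType(str, Enum):
    test_cross_p1 = "test_cross_p1"  # parent 1 heterozygous, parent 2 homozygous
    test_cross_p2 = "test_cross_p2"
    intercross = "intercross"  # both parents heterozygous


def cross_type(p1_genotype: int, p2_genotype: int) -> CrossType | None:
    """Cross design of a marker from the parental genotypes; None when
    neither parent is heterozygous (uninformative)."""
    h1, h2 = p1_genotype == 1, p2_genotype == 1
    if h1 and h2:
        return CrossType.intercross
    if h1:
        return CrossType.test_cross_p1
    if h2:
        return CrossType.test_cross_p2
    return None


def filter_parent_sites(
    sites: pd.DataFrame,
    fragment_range: tuple[int, int] = FRAGMENT_RANGE,
    coverage_range: tuple[int, int] = PARENT_COV_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the fragment-length and parental-coverage filters.

    ``sites`` needs columns ``fragment_length``, ``p1_coverage``,
    ``p2_coverage``. Returns ``(kept, report)`` where ``report`` has one row
    per removed or rejected record with a ``reason`` code
    (fragment_length | coverage | missing_fields); input order is preserved
    in both frames.
    """
    lo_f, hi_f = fragment_range
    lo_c, hi_c = coverage_range
    reasons = []
    for _, row in sites.iterrows():
        if pd.isna(row.get("fragment_length")) or pd.isna(row.get("p1_coverage")) \
                or pd.isna(row.get("p2_coverage")):
            reasons.append("missing_fields")
        elif not (lo_f <= row["fragment_length"] <= hi_f):
            reasons.append("fragment_length")
        elif not (lo_c <= row["p1_coverage"] <= hi_c and lo_c <= row["p2_coverage"] <= hi_c):
            reasons.append("coverage")
        else:
            reasons.append("")
    reasons = pd.Series(reasons, index=sites.index, name="reason")
    kept = sites[reasons == ""]
    report = sites[reasons != ""].copy()
    report["reason"] = reasons[reasons != ""]
    return kept, report


def segregation_test(counts: np.ndarray | list[int], cross: CrossType) -> tuple[float, float]:
    """Pearson chi-square for Mendelian segregation.

    ``counts`` are observed genotype-class counts over non-missing
    offspring: (n_hom, n_het) for a test cross (expected 1:1) or
    (n_AA, n_AB, n_BB) for an intercross (expected 1:2:1). Returns
    ``(statistic, p)``; p is nan when no offspring were observed.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return float("nan"), float("nan")
    if cross is CrossType.intercross:
        if counts.size != 3:
            raise ValueError("intercross expects 3 genotype classes")
        expected = n * np.array([0.25, 0.5, 0.25])
    else:
        if counts.size != 2:
            raise ValueError("test cross expects 2 genotype classes")
        expected = n * np.array([0.5, 0.5])
    stat, p = sstats.chisquare(counts, expected)
    return float(stat), float(p)


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns the boolean *retain* mask.

    A marker is retained when its segregation test is NOT rejected after
    FDR control (True = keep). Empty input -> empty mask. NaN p-values
    (no data) are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    keep = np.zeros(p.size, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rejected, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        keep[ok] = ~rejected
    return keep


def filter_offspring(
    coverage: np.ndarray,
    offspring_ids: list[str] | None = None,
    min_markers: int = OFFSPRING_MIN_MARKERS,
    min_coverage: int = OFFSPRING_MIN_COV,
) -> list:
    """Offspring retained iff >= ``min_markers`` markers have coverage
    strictly above ``min_coverage``.

    ``coverage`` is a (n_markers, n_offspring) array of per-call read
    coverages (0 for missing calls).
    """
    coverage = np.asarray(coverage)
    qualifying = (coverage > min_coverage).sum(axis=0)
    keep = qualifying >= min_markers
    ids = offspring_ids if offspring_ids is not None else list(range(coverage.shape[1]))
    return [i for i, k in zip(ids, keep) if k]


@dataclass
class FilterReport:
    """Per-rule removal counts from the full marker-selection pipeline."""

    n_input: int = 0
    removed: dict = field(default_factory=dict)  # reason -> count
    n_retained: int = 0
    retained_ids: list = field(default_factory=list)
    removed_ids: dict = field(default_factory=dict)  # reason -> ids
    retained_offspring: list = field(default_factory=list)

    def count(self, reason: str, marker_id) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + 1
        self.removed_ids.setdefault(reason, []).append(marker_id)


def _genotype_counts(genos: np.ndarray, cross: CrossType) -> np.ndarray:
    obs = genos[genos >= 0]
    if cross is CrossType.intercross:
        return np.bincount(obs, minlength=3)[:3]
    # test cross: classes are the two genotypes segregating 1:1; with the
    # 0/1/2 coding these are het (1) and the homozygote matching the
    # homozygous parent. Count het vs non-het.
    het = int((obs == 1).sum())
    return np.array([len(obs) - het, het])


def select_informative_markers(
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    coverage: np.ndarray,
    offspring_ids: list[str] | None = None,
    alpha: float = 0.05,
    min_markers: int = OFFSPRING_MIN_MARKERS,
    min_coverage: int = OFFSPRING_MIN_COV,
    missing_flag_fraction: float = 0.10,
    apply_parent_filters: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full marker-selection pipeline.

    Composition: parental site filters -> heterozygous-parent requirement ->
    biallelic-in-offspring requirement -> per-marker segregation chi-square
    -> BH retention over the whole set -> offspring filter. Markers with
    more than ``missing_flag_fraction`` missing offspring calls are flagged
    (column ``high_missing``) but kept.

    ``sites`` rows align with the rows of ``genotypes``/``coverage``
    ((n_markers, n_offspring), coded 0/1/2/-1). Returns the retained-marker
    table (with cross type, chi-square statistic and p) and a FilterReport.
    """
    report = FilterReport(n_input=len(sites))
    sites = sites.reset_index(drop=True)
    genotypes = np.asarray(genotypes)
    coverage = np.asarray(coverage)

    if apply_parent_filters:
        kept, parent_report = filter_parent_sites(sites)
        for _, row in parent_report.iterrows():
            report.count(row["reason"], row.get("marker_id", row.name))
    else:
        kept = sites

    rows = []
    for idx, row in kept.iterrows():
        mid = row.get("marker_id", idx)
        ct = cross_type(int(row["p1_genotype"]), int(row["p2_genotype"]))
        genos = genotypes[idx]
        if ct is None:
            report.count("uninformative", mid)
            continue
        observed = genos[genos >= 0]
        alleles = np.unique(observed)
        if np.any((observed < 0) | (observed > 2)) or alleles.size > 3:
            report.count("not_biallelic", mid)
            continue
        if ct is not CrossType.intercross and 1 in alleles and alleles.size > 2:
            # a test cross segregates two genotype classes; a third class
            # implies a non-biallelic or erroneous site
            report.count("not_biallelic", mid)
            continue
        if observed.size == 0:
            report.count("all_missing", mid)
            continue
        stat, p = segregation_test(_genotype_counts(genos, ct), ct)
        rows.append({
            "row": idx, "marker_id": mid, "cross_type": ct.value,
            "chi2": stat, "p": p,
            "high_missing": float((genos < 0).mean()) > missing_flag_fraction,
        })

    tested = pd.DataFrame(rows)
    if len(tested):
        keep_mask = bh_fdr(tested["p"].to_numpy(), alpha=alpha)
        for _, row in tested[~keep_mask].iterrows():
            report.count("segregation_distorted", row["marker_id"])
        tested = tested[keep_mask].reset_index(drop=True)

    retained_rows = tested["row"].to_numpy() if len(tested) else np.array([], int)
    report.retained_offspring = filter_offspring(
        coverage[retained_rows], offspring_ids,
        min_markers=min_markers, min_coverage=min_coverage,
    )
    result = kept.loc[retained_rows].reset_index(drop=True) if len(tested) else kept.iloc[:0]
    if len(tested):
        result = result.assign(
            cross_type=tested["cross_type"].to_numpy(),
            chi2=tested["chi2"].to_numpy(),
            p=tested["p"].to_numpy(),
            high_missing=tested["high_missing"].to_numpy(),
        )
    report.n_retained = len(result)
    report.retained_ids = list(result.get("marker_id", result.index))
    return result, report
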