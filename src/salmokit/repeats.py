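"""Transposable-element curation, classification and landscape analysis.

This module covers the repeat side of the pipeline:

* library curation — drop repeats whose best database hit is a host protein;
* the 80-80-80 homology rule for nucleotide-level classification, with a
  protein-level fallback at e-value < 1e-10;
* per-superfamily abundance (merged-interval base pairs and percent
  coverage) and the class-I : class-II abundance ratio;
* per-chromosome density profiles in 100 kb bins, lowess smoothing
  (f = 0.2), Tc1-Mariner-peak centromere prediction and Levan-style
  karyotype classes from the long:short arm ratio;
* cross-species abundance outliers from a log2 linear model;
* the map-length ~ size + arm-ratio model with a likelihood-ratio test;
* canonical k-mer repetitiveness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

DEFAULT_BIN = 100_000
#: Levan-style centromeric-index thresholds for metacentric / submetacentric.
KARYOTYPE_THRESHOLDS = (1.7, 3.0)


# ---------------------------------------------------------------------------
# Library curation and classification
# ---------------------------------------------------------------------------

@dataclass
class TEClassification:
    repeat_id: str
    te_class: str | None  # "I", "II" or None
    order: str | None
    superfamily: str | None
    evidence: str  # nucleotide | protein | unclassified | host_gene_removed


def curate_repeat_library(best_hits: pd.DataFrame) -> tuple[list[str], list[str], list[str]]:
    """Split a repeat library into host genes, TE candidates and no-hit repeats.

    ``best_hits`` has one row per (repeat_id, database) best hit with columns
    ``repeat_id``, ``database`` ("repeat" or "protein") and ``bitscore``.
    A repeat is removed as a putative host gene iff its overall best-scoring
    hit (by bit score across both databases) is to the protein database.

    Returns ``(retained_ids, host_gene_ids, no_hit_ids_among_retained)``;
    repeats with no hits at all must be supplied as rows with NaN bitscore or
    simply be absent — absent repeats cannot be curated here and are the
    caller's responsibility.
    """
    required = {"repeat_id", "database", "bitscore"}
    if not required.issubset(best_hits.columns):
        raise ValueError(f"best_hits needs columns {sorted(required)}")
    retained: list[str] = []
    hosts: list[str] = []
    nohits: list[str] = []
    for rid, grp in best_hits.groupby("repeat_id", sort=False):
        scored = grp.dropna(subset=["bitscore"])
        if scored.empty:
            retained.append(rid)
            nohits.append(rid)
            continue
        best = scored.loc[scored["bitscore"].idxmax()]
        if best["database"] == "protein":
            hosts.append(rid)
        else:
            retained.append(rid)
    return retained, hosts, nohits


def classify_te(
    repeat_id: str,
    effective_length: int,
    nt_hit: dict | None = None,
    prot_hit: dict | None = None,
) -> TEClassification:
    """Classify one repeat by the 80-80-80 nucleotide rule with protein fallback.

    ``nt_hit`` / ``prot_hit`` carry the best database hit of each search:
    keys ``aln_len``, ``identity`` (percent), ``evalue``, and the database
    annotation ``te_class``, ``order``, ``superfamily``. The nucleotide hit
    is accepted iff aln_len >= 80 bp AND identity >= 80% AND aln_len covers
    >= 80% of the effective (unknown-base-free) query length, all inclusive.
    Otherwise the protein hit is accepted iff its e-value < 1e-10 (strict).
    """
    if effective_length <= 0:
        raise ValueError("effective query length must be positive")
    if nt_hit is not None:
        cov = 100.0 * nt_hit["aln_len"] / effective_length
        if nt_hit["aln_len"] >= 80 and nt_hit["identity"] >= 80.0 and cov >= 80.0:
            return TEClassification(
                repeat_id, nt_hit.get("te_class"), nt_hit.get("order"),
                nt_hit.get("superfamily"), "nucleotide",
            )
    if prot_hit is not None and prot_hit["evalue"] < 1e-10:
        return TEClassification(
            repeat_id, prot_hit.get("te_class"), prot_hit.get("order"),
            prot_hit.get("superfamily"), "protein",
        )
    return TEClassification(repeat_id, None, None, None, "unclassified")


def classify_library(hits: pd.DataFrame, effective_lengths: dict[str, int]) -> pd.DataFrame:
    """Vector wrapper: best nucleotide and protein hits per repeat -> table.

    ``hits`` columns: repeat_id, search ("nt" | "prot"), aln_len, identity,
    evalue, bitscore, te_class, order, superfamily.
    """
    rows = []
    for rid, grp in hits.groupby("repeat_id", sort=False):
        nt = grp[grp["search"] == "nt"]
        pr = grp[grp["search"] == "prot"]
        nt_hit = nt.loc[nt["bitscore"].idxmax()].to_dict() if len(nt) else None
        pr_hit = pr.loc[pr["bitscore"].idxmax()].to_dict() if len(pr) else None
        cls = classify_te(rid, effective_lengths[rid], nt_hit, pr_hit)
        rows.append(cls.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Abundance
# ---------------------------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total covered bp of 1-based inclusive intervals after merging overlaps."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    total = 0
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        if s[i] <= cur_e + 1:
            cur_e = max(cur_e, int(e[i]))
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = int(s[i]), int(e[i])
    total += cur_e - cur_s + 1
    return total


def abundance_table(
    annotations: pd.DataFrame,
    assembly_length: int,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-superfamily bp and percent coverage from a repeat annotation table.

    ``annotations`` columns: chrom, start, end (1-based inclusive),
    superfamily; optional te_class, order (carried through). Overlapping
    intervals of the same superfamily on the same chromosome are merged
    before summing so no base is counted twice. Percent coverage is
    bp / assembly_length x 100, reported to one decimal.
    """
    if chrom_lengths is not None:
        for _, row in annotations.iterrows():
            limit = chrom_lengths.get(row["chrom"])
            if limit is not None and (row["start"] < 1 or row["end"] > limit):
                raise ValueError(
                    f"interval {row['start']}-{row['end']} outside {row['chrom']}"
                )
    meta_cols = [c for c in ("te_class", "order") if c in annotations.columns]
    rows = []
    for sf, grp in annotations.groupby("superfamily", sort=False):
        bp = 0
        for _, cgrp in grp.groupby("chrom", sort=False):
            bp += merge_intervals(cgrp["start"].to_numpy(), cgrp["end"].to_numpy())
        row = {"superfamily": sf, "bp": bp,
               "pct_coverage": round(100.0 * bp / assembly_length, 1)}
        for c in meta_cols:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def class_ratio(table: pd.DataFrame, bp_col: str = "bp") -> float:
    """Class-I (retrotransposon) : class-II (DNA transposon) bp ratio.

    ``table`` needs ``te_class`` ("I"/"II"/other) and a bp column. Rows whose
    class is neither I nor II (unclassified repeats) are excluded. Reported
    to one decimal, as in per-genome abundance summaries.
    """
    c1 = table.loc[table["te_class"] == "I", bp_col].sum()
    c2 = table.loc[table["te_class"] == "II", bp_col].sum()
    if c2 == 0:
        raise ValueError("no class-II bp; ratio undefined")
    return round(float(c1) / float(c2), 1)


# ---------------------------------------------------------------------------
# Density profiles, centromeres, karyotypes
# ---------------------------------------------------------------------------

@dataclass
class RepeatProfile:
    chromosome: str
    superfamily: str
    bin_width: int
    raw: np.ndarray
    smoothed: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.raw)

    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class ChromosomeModel:
    chromosome: str
    length: int
    centromere: float | None
    arm_ratio: float | None
    karyotype: str | None  # M / SM / T, or None when undetermined
    ambiguous_peak: bool = False


def bin_density(
    annotations: pd.DataFrame,
    chromosome: str,
    chrom_length: int,
    superfamily: str,
    bin_width: int = DEFAULT_BIN,
) -> RepeatProfile:
    """Count elements of one superfamily in fixed-width bins.

    An element is assigned to the bin containing its start (1-based); the
    final partial bin is retained.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(1, -(-chrom_length // bin_width))
    sel = annotations[
        (annotations["chrom"] == chromosome)
        & (annotations["superfamily"] == superfamily)
    ]
    idx = (sel["start"].to_numpy(dtype=np.int64) - 1) // bin_width
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return RepeatProfile(chromosome, superfamily, bin_width, counts)


def lowess_smooth(profile: RepeatProfile, f: float = 0.2) -> RepeatProfile:
    """Locally weighted regression over bin midpoints (span ``f``, 3 robust
    iterations); with fewer than 3 bins the raw profile is passed through."""
    import warnings
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if profile.n_bins < 3:
        warnings.warn("fewer than 3 bins; returning raw profile unsmoothed")
        return RepeatProfile(profile.chromosome, profile.superfamily,
                             profile.bin_width, profile.raw, profile.raw.copy())
    x = profile.bin_midpoints()
    sm = lowess(profile.raw, x, frac=f, it=3, return_sorted=False)
    return RepeatProfile(profile.chromosome, profile.superfamily,
                         profile.bin_width, profile.raw, np.asarray(sm))


def predict_centromere(
    profile: RepeatProfile, tol: float = 1e-9
) -> tuple[float | None, bool]:
    """Centromere position = midpoint of the argmax bin of the smoothed
    Tc1-Mariner profile.

    Returns ``(position, ambiguous)``. The position is None (undetermined)
    when the profile is empty or flat (no peak: all values within ``tol`` of
    each other). When several separated bins tie for the maximum within
    ``tol``, the earliest is returned with ``ambiguous=True``.
    """
    y = profile.smoothed if profile.smoothed is not None else profile.raw
    if y is None or len(y) == 0:
        return None, False
    y = np.asarray(y, dtype=float)
    if np.ptp(y) <= tol:
        return None, False
    peak = float(np.max(y))
    ties = np.flatnonzero(y >= peak - tol)
    pos = (ties[0] + 0.5) * profile.bin_width
    return float(pos), len(ties) > 1


def karyotype_class(
    chrom_length: int,
    centromere: float | None,
    chromosome: str = "",
    thresholds: tuple[float, float] = KARYOTYPE_THRESHOLDS,
) -> ChromosomeModel:
    """Long:short arm ratio and M/SM/T karyotype class.

    M iff ratio <= 1.7, SM iff 1.7 < ratio <= 3.0, T iff ratio > 3.0
    (thresholds configurable). Centromere None -> everything undetermined.
    """
    if centromere is None:
        return ChromosomeModel(chromosome, chrom_length, None, None, None)
    if not 0 < centromere < chrom_length:
        raise ValueError("centromere must lie strictly inside the chromosome")
    arms = sorted([centromere, chrom_length - centromere])
    ratio = arms[1] / arms[0]
    t_m, t_sm = thresholds
    cls = "M" if ratio <= t_m else ("SM" if ratio <= t_sm else "T")
    return ChromosomeModel(chromosome, chrom_length, float(centromere),
                           float(ratio), cls)


def chromosome_models(
    annotations: pd.DataFrame,
    chrom_lengths: dict[str, int],
    superfamily: str = "Tc1-Mariner",
    bin_width: int = DEFAULT_BIN,
    f: float = 0.2,
) -> list[ChromosomeModel]:
    """End-to-end per-chromosome centromere + karyotype prediction."""
    models = []
    for chrom, length in chrom_lengths.items():
        prof = lowess_smooth(
            bin_density(annotations, chrom, length, superfamily, bin_width), f=f
        )
        pos, ambiguous = predict_centromere(prof)
        model = karyotype_class(length, pos, chromosome=chrom)
        model.ambiguous_peak = ambiguous
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Cross-species abundance outliers
# ---------------------------------------------------------------------------

@dataclass
class OutlierResult:
    table: pd.DataFrame  # element, abundance_a, abundance_b, residual, outlier, direction
    slope: float
    intercept: float
    resid_sd: float


def abundance_outliers(
    abundance_a: pd.Series | Sequence[float],
    abundance_b: pd.Series | Sequence[float],
    names: Sequence[str] | None = None,
    z: float = 1.96,
    min_sd: float = 0.01,
) -> OutlierResult:
    """Elements with divergent abundance between two genomes.

    Fits OLS of log2(b+1) on log2(a+1); an element is an outlier iff its
    absolute residual exceeds ``z`` sample standard deviations of the
    residuals. Direction: positive residual -> enriched in genome B.
    When the residual SD falls below ``min_sd`` log2 units the two genomes
    are proportional to numerical precision (the +1 offset alone bends an
    exactly proportional pair off the fitted line) and nothing is flagged.
    """
    a = np.asarray(abundance_a, dtype=float)
    b = np.asarray(abundance_b, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 elements for the outlier regression")
    x = np.log2(a + 1.0)
    y = np.log2(b + 1.0)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = float(np.std(resid, ddof=1))
    if sd <= min_sd:
        outlier = np.zeros(a.size, dtype=bool)
    else:
        outlier = np.abs(resid) > z * sd
    direction = np.where(resid > 0, "B-enriched", "A-enriched")
    tbl = pd.DataFrame({
        "element": list(names) if names is not None else np.arange(a.size),
        "abundance_a": a, "abundance_b": b,
        "residual": resid, "outlier": outlier,
        "direction": np.where(outlier, direction, ""),
    })
    return OutlierResult(tbl, float(beta[1]), float(beta[0]), sd)


# ---------------------------------------------------------------------------
# Map length ~ size + arm ratio
# ---------------------------------------------------------------------------

@dataclass
class MapLengthModelResult:
    params: pd.Series
    pvalues: pd.Series
    adj_r2: float
    lrt_stat: float
    lrt_p: float
    n: int

    def summary(self) -> str:
        lines = ["map_length ~ size_mb + arm_ratio  (OLS, n=%d)" % self.n]
        for name in self.params.index:
            lines.append(
                f"  {name:>12s}  {self.params[name]: .4f}  p={self.pvalues[name]:.4g}"
            )
        lines.append(f"  adjusted R^2 = {self.adj_r2:.4f}")
        lines.append(
            f"  LRT vs size-only model: chi2(1) = {self.lrt_stat:.3f}, p = {self.lrt_p:.4g}"
        )
        return "\n".join(lines)


def map_length_model(
    map_length: Sequence[float],
    size_mb: Sequence[float],
    arm_ratio: Sequence[float],
) -> MapLengthModelResult:
    """Fit map_length ~ chromosome size + long:short arm ratio.

    The full OLS model is compared with the size-only reduced model by a
    likelihood-ratio chi-square test on 1 df. Collinear predictors abort
    the fit.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({
        "map_length": np.asarray(map_length, float),
        "size_mb": np.asarray(size_mb, float),
        "arm_ratio": np.asarray(arm_ratio, float),
    }).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 chromosomes with complete data")
    X_full = sm.add_constant(df[["size_mb", "arm_ratio"]])
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        raise ValueError("collinear predictors; fit aborted")
    full = sm.OLS(df["map_length"], X_full).fit()
    red = sm.OLS(df["map_length"], sm.add_constant(df[["size_mb"]])).fit()
    lrt = 2.0 * (full.llf - red.llf)
    p = float(sstats.chi2.sf(lrt, df=1))
    return MapLengthModelResult(full.params, full.pvalues,
                                float(full.rsquared_adj), float(lrt), p, len(df))


# ---------------------------------------------------------------------------
# k-mer repetitiveness
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def kmer_repetitiveness(
    sequences: Iterable[str], k: int = 31, canonical: bool = True
) -> float:
    """Fraction of k-mer instances whose k-mer occurs two or more times.

    k-mers containing non-ACGT characters are skipped. With ``canonical``
    (default) a k-mer and its reverse complement are counted as one. Raises
    ValueError when no k-mer can be counted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            if canonical:
                kmer = _canonical(kmer)
            counts[kmer] = counts.get(kmer, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable k-mers")
    repeated = sum(c for c in counts.values() if c >= 2)
    return repeated / total
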