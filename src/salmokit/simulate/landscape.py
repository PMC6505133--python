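"""Repeat-landscape simulator.

Plants a unimodal Tc1-Mariner density peak at the centromere and elevated
RTE-X density near the chromosome ends over a uniform background of mixed
superfamilies — the repeat geography that the centromere-prediction stage
assumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BACKGROUND_SUPERFAMILIES = ("Gypsy", "Jockey", "hAT", "L1")


def simulate_repeat_landscape(
    chrom_name: str,
    chrom_length: int,
    centromere: int | None,
    rng: np.random.Generator,
    peak_width_bp: int = 1_000_000,
    n_tc1_peak: int = 2000,
    n_tc1_background: int = 500,
    n_rtex: int = 1000,
    n_background: int = 2000,
    element_length_range: tuple[int, int] = (200, 2000),
) -> pd.DataFrame:
    """One chromosome's repeat-annotation table (chrom, start, end,
    superfamily; 1-based inclusive coordinates).

    ``centromere=None`` (or ``n_tc1_peak=0``) omits the centromeric peak, the
    degenerate case in which downstream prediction must report undetermined.
    Raises ValueError for a non-positive peak width.
    """
    if peak_width_bp <= 0:
        raise ValueError("peak width must be positive")
    if centromere is not None and not 0 <= centromere < chrom_length:
        raise ValueError("centromere outside chromosome")
    starts: list[np.ndarray] = []
    families: list[np.ndarray] = []

    if centromere is not None and n_tc1_peak:
        peak = rng.normal(centromere, peak_width_bp / 4.0, size=n_tc1_peak)
        starts.append(np.clip(peak, 0, chrom_length - 1))
        families.append(np.repeat("Tc1-Mariner", n_tc1_peak))
    if n_tc1_background:
        starts.append(rng.uniform(0, chrom_length, size=n_tc1_background))
        families.append(np.repeat("Tc1-Mariner", n_tc1_background))
    if n_rtex:
        # subtelomeric: exponential decay from each chromosome end
        half = n_rtex // 2
        scale = chrom_length * 0.05
        left = rng.exponential(scale, size=half)
        right = chrom_length - 1 - rng.exponential(scale, size=n_rtex - half)
        ends = np.concatenate([left, right])
        starts.append(np.clip(ends, 0, chrom_length - 1))
        families.append(np.repeat("RTE-X", n_rtex))
    if n_background:
        starts.append(rng.uniform(0, chrom_length, size=n_background))
        families.append(rng.choice(BACKGROUND_SUPERFAMILIES, size=n_background))

    start = np.concatenate(starts).astype(np.int64) + 1  # to 1-based
    fam = np.concatenate(families)
    lengths = rng.integers(*element_length_range, size=start.size)
    end = np.minimum(start + lengths - 1, chrom_length)
    order = np.argsort(start, kind="stable")
    return pd.DataFrame({
        "chrom": chrom_name,
        "start": start[order],
        "end": end[order],
        "superfamily": fam[order],
    })
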