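"""Packaged reference tables and the arithmetic recomputed from them.

The shipped TSVs hold published abundance and assembly-stage statistics for
the European grayling and Atlantic salmon chromosome-level assemblies; the
functions below re-derive the headline summary numbers (class ratios, total
repeat coverage, stage-over-stage percent changes, per-superfamily percent
coverages) from the raw columns with the package's own statistics code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .asmstats import percent_change
from .repeats import class_ratio


def _read(name: str) -> pd.DataFrame:
    with resources.files("salmokit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def te_abundance_table() -> pd.DataFrame:
    return _read("te_abundance_published.tsv")


def assembly_stage_table() -> pd.DataFrame:
    return _read("assembly_stages_published.tsv").set_index("statistic")


def lineage_specific_elements() -> pd.DataFrame:
    return _read("lineage_specific_elements.tsv")


def worked_examples() -> dict[str, float]:
    """Summary numbers recomputed from the raw published columns."""
    te = te_abundance_table()
    stages = assembly_stage_table()
    assembly_len = {
        "grayling": int(stages.loc["total_length", "stage3"]),
    }
    out: dict[str, float] = {}
    out["class_ratio_grayling"] = class_ratio(te, bp_col="grayling_bp")
    out["class_ratio_salmon"] = class_ratio(te, bp_col="salmon_bp")
    total_bp = int(te["grayling_bp"].sum())
    out["total_repeat_bp_grayling"] = total_bp
    out["total_repeat_pct_grayling"] = round(
        100.0 * total_bp / assembly_len["grayling"], 1)
    out["n50_change_stage2_pct"] = percent_change(
        stages.loc["n50", "stage1"], stages.loc["n50", "stage2"])
    out["l50_change_stage2_pct"] = percent_change(
        stages.loc["l50", "stage1"], stages.loc["l50", "stage2"])
    out["max_length_change_stage2_pct"] = percent_change(
        stages.loc["max_length", "stage1"], stages.loc["max_length", "stage2"])
    out["scaffold_count_change_stage2_pct"] = percent_change(
        stages.loc["scaffolds", "stage1"], stages.loc["scaffolds", "stage2"])

    def pct(superfamily: str, decimals: int = 1) -> float:
        bp = int(te.loc[te["superfamily"] == superfamily, "grayling_bp"].iloc[0])
        return round(100.0 * bp / assembly_len["grayling"], decimals)

    out["tc1_mariner_pct_grayling"] = pct("Tc1-Mariner")
    out["jockey_pct_grayling"] = pct("Jockey")
    hat10 = lineage_specific_elements().set_index("element")
    out["hat10_pct_grayling"] = round(
        100.0 * int(hat10.loc["hAT-10", "grayling_bp"]) / assembly_len["grayling"], 2)
    return out
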