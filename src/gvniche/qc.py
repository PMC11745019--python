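"""Genome quality control on marker-gene statistics, plus taxonomy summaries.

Candidate giant-virus MAGs are screened with three statistics produced by
upstream marker annotation: the number of universal cellular housekeeping
gene hits (UNI56, high values suggest cellular contamination), the number of
the nine core giant-virus orthologous groups detected (GVOG9, low values
suggest a fragmentary or non-GV bin), and the mean duplication factor of the
seven single-copy core groups (GVOG7df, high values suggest a chimeric bin).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_table, write_table

__all__ = [
    "GENOME_TABLE_COLUMNS",
    "QC_CUTOFFS",
    "load_genome_table",
    "marker_qc_filter",
    "taxonomy_summary",
]

GENOME_TABLE_COLUMNS = (
    "genome_id",
    "total_length_bp",
    "gc",
    "n_genes",
    "uni56",
    "gvog9",
    "gvog7df",
    "order",
    "family",
)

#: Pass rule: uni56 < 10 AND gvog9 >= 4 AND gvog7df <= 3.
QC_CUTOFFS = {"uni56_max_exclusive": 10, "gvog9_min": 4, "gvog7df_max": 3.0}


def load_genome_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    if "genome_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'genome_id'")
    return df


def marker_qc_filter(
    records: pd.DataFrame,
    *,
    uni56_max_exclusive: int = 10,
    gvog9_min: int = 4,
    gvog7df_max: float = 3.0,
    min_gvog: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a genome table into QC passes and fails.

    Boundary semantics are literal: UNI56 strictly below 10, GVOG9 at least
    4, GVOG7 duplication factor at most 3. A record missing any statistic
    fails with reason ``missing_stat``. ``min_gvog`` optionally re-applies
    the upstream >=N GVOG pre-selection (off by default, as inputs are
    normally pre-screened). The fail table carries a ``qc_fail_reasons``
    column with ';'-joined violated rules.
    """
    needed = ["uni56", "gvog9", "gvog7df"]
    for col in needed:
        if col not in records.columns:
            raise ValueError(f"genome table missing required column {col!r}")
    reasons = []
    for _, row in records.iterrows():
        why: list[str] = []
        if any(pd.isna(row[col]) for col in needed):
            why.append("missing_stat")
        else:
            if min_gvog is not None and row["gvog9"] < min_gvog:
                why.append(f"gvog9<{min_gvog}")
            if not row["uni56"] < uni56_max_exclusive:
                why.append(f"uni56>={uni56_max_exclusive}")
            if not row["gvog9"] >= gvog9_min:
                why.append(f"gvog9<{gvog9_min}")
            if not row["gvog7df"] <= gvog7df_max:
                why.append(f"gvog7df>{gvog7df_max}")
        reasons.append(";".join(why))
    reasons = pd.Series(reasons, index=records.index)
    passed = records[reasons == ""].copy()
    failed = records[reasons != ""].copy()
    failed["qc_fail_reasons"] = reasons[reasons != ""]
    return passed, failed


def taxonomy_summary(records: pd.DataFrame, rank: str = "order") -> pd.DataFrame:
    """Counts and percentages of genomes per taxon at the given rank.

    Missing labels are reported as 'unclassified'. Percentages are
    100 * count / total to one decimal, allocated by largest remainder so the
    reported column sums to exactly 100.0.
    """
    if rank not in records.columns:
        raise ValueError(f"genome table has no rank column {rank!r}")
    taxa = records[rank].fillna("unclassified").replace("", "unclassified")
    counts = taxa.value_counts()
    total = int(counts.sum())
    out = counts.rename_axis("taxon").reset_index(name="count")
    exact = 1000.0 * out["count"] / total  # tenths of a percent
    floors = np.floor(exact).astype(int)
    short = int(round(exact.sum())) - int(floors.sum())
    order = np.argsort(-(exact - floors).to_numpy(), kind="stable")
    floors.iloc[order[:short]] += 1
    out["percent"] = floors / 10.0
    return out


def write_qc_report(passed: pd.DataFrame, failed: pd.DataFrame, path: str | Path, **meta) -> None:
    report = pd.concat(
        [
            passed.assign(qc_pass=True, qc_fail_reasons=""),
            failed.assign(qc_pass=False),
        ],
        ignore_index=True,
    )
    write_table(report, path, metadata=meta)
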