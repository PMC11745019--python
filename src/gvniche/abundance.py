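"""Genome abundance from contig coverage: aggregation, breadth filtering,
RPKM normalization, size-fraction partitioning and presence intersections.

The central object is :class:`AbundanceMatrix`, a genome x sample table of
normalized abundance paired with a breadth-of-coverage table (fraction of
genome bases covered by >=1 read). A genome counts as *present* in a sample
only when its breadth reaches the presence threshold (default 70%); below it
the abundance is zeroed, a conservative rule that trades false negatives for
protection against spurious cross-mapping between related genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io import read_table, write_table

__all__ = [
    "SAMPLE_SHEET_COLUMNS",
    "CONTIG_COVERAGE_COLUMNS",
    "AbundanceMatrix",
    "load_sample_sheet",
    "load_contig_coverage",
    "validate_sample_sheet",
    "validate_contig_coverage",
    "genome_lengths",
    "genome_coverage",
    "rpkm",
    "build_abundance",
    "presence_filter",
    "size_fraction_ratio",
    "upset_intersections",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "depth_m", "fraction", "replicate", "total_reads")
CONTIG_COVERAGE_COLUMNS = (
    "sample_id",
    "contig_id",
    "genome_id",
    "length_bp",
    "mean_depth",
    "covered_bases",
    "mapped_reads",
)
FRACTIONS = ("cellular", "viral")


def validate_sample_sheet(sheet: pd.DataFrame, path: str = "samples") -> pd.DataFrame:
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(sheet["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"{path}: unknown fraction labels {sorted(bad)}; expected {FRACTIONS}")
    if (sheet["total_reads"] <= 0).any():
        raise ValueError(f"{path}: total_reads must be > 0")
    return sheet


def validate_contig_coverage(cov: pd.DataFrame, path: str = "contig_coverage") -> pd.DataFrame:
    for col in CONTIG_COVERAGE_COLUMNS:
        if col not in cov.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    owners = cov.groupby("contig_id")["genome_id"].nunique()
    shared = owners[owners > 1]
    if len(shared):
        raise ValueError(
            f"{path}: contig(s) listed under multiple genomes: {list(shared.index[:5])}"
        )
    if (cov["covered_bases"] > cov["length_bp"]).any():
        raise ValueError(f"{path}: covered_bases exceeds length_bp")
    if ((cov["mean_depth"] == 0) & (cov["covered_bases"] > 0)).any():
        raise ValueError(f"{path}: covered_bases > 0 requires mean_depth > 0")
    return cov


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(read_table(path), str(path))


def load_contig_coverage(path: str | Path) -> pd.DataFrame:
    return validate_contig_coverage(read_table(path), str(path))


def genome_lengths(cov: pd.DataFrame) -> pd.Series:
    """Total length per genome from the unique contigs in a coverage table."""
    contigs = cov.drop_duplicates("contig_id")
    lengths = contigs.groupby("contig_id")["length_bp"].first()
    # a contig must keep one length across samples
    per_sample = cov.groupby("contig_id")["length_bp"].nunique()
    if (per_sample > 1).any():
        bad = per_sample[per_sample > 1].index[0]
        raise ValueError(f"contig {bad!r} has inconsistent length_bp across samples")
    return contigs.groupby("genome_id")["length_bp"].sum()


def genome_coverage(cov: pd.DataFrame, genome_id: str, sample_id: str) -> tuple[float, float]:
    """Length-weighted mean depth and breadth of one genome in one sample.

    depth = sum(contig length x contig mean depth) / genome length,
    breadth = sum(covered bases) / genome length. Contigs of the genome with
    no record in the sample contribute zero depth and zero covered bases.
    """
    mine = cov[cov["genome_id"] == genome_id]
    if mine.empty:
        raise KeyError(f"unknown genome_id {genome_id!r}")
    total_len = mine.drop_duplicates("contig_id")["length_bp"].sum()
    in_sample = mine[mine["sample_id"] == sample_id]
    depth = float((in_sample["length_bp"] * in_sample["mean_depth"]).sum()) / total_len
    breadth = float(in_sample["covered_bases"].sum()) / total_len
    return depth, breadth


def rpkm(mapped_reads: float, genome_length_bp: float, total_reads: float) -> float:
    """Reads per kilobase of genome per million mapped reads."""
    if genome_length_bp <= 0 or total_reads <= 0:
        raise ValueError("genome length and total reads must be > 0")
    return mapped_reads * 1e9 / (genome_length_bp * total_reads)


@dataclass
class AbundanceMatrix:
    """Genome x sample abundance with its companion breadth matrix.

    ``basis`` records the normalization ('rpkm' or 'depth'); ``filtered``
    flags whether the breadth presence rule has been applied.
    """

    values: pd.DataFrame
    breadth: pd.DataFrame
    basis: Literal["rpkm", "depth"] = "rpkm"
    filtered: bool = False
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.breadth.index) or not self.values.columns.equals(
            self.breadth.columns
        ):
            raise ValueError("abundance and breadth matrices must share genomes and samples")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")

    @property
    def genomes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix (abundance > 0 after filtering)."""
        if not self.filtered:
            raise ValueError("presence is defined on the breadth-filtered matrix")
        return self.values > 0

    def depth_means(self, sheet: pd.DataFrame) -> pd.DataFrame:
        """Average replicate samples into one column per depth."""
        depth_of = sheet.set_index("sample_id")["depth_m"]
        grouped = self.values.T.groupby(self.values.columns.map(depth_of)).mean().T
        return grouped.sort_index(axis=1)

    def to_tsv(self, path: str | Path, **meta) -> None:
        out = self.values.rename_axis("genome_id").reset_index()
        write_table(out, path, metadata={"basis": self.basis, "filtered": self.filtered, **meta})


def build_abundance(
    cov: pd.DataFrame,
    sheet: pd.DataFrame,
    basis: Literal["rpkm", "depth"] = "rpkm",
) -> AbundanceMatrix:
    """Aggregate contig coverage into a raw genome x sample abundance matrix.

    RPKM basis uses mapped read counts against each sample's library size;
    depth basis uses the length-weighted mean contig depth. Breadth is
    computed identically for both.
    """
    validate_contig_coverage(cov)
    validate_sample_sheet(sheet)
    lengths = genome_lengths(cov)
    samples = list(sheet["sample_id"])
    unknown = set(cov["sample_id"]) - set(samples)
    if unknown:
        raise ValueError(f"coverage references unknown sample(s): {sorted(unknown)[:5]}")

    def _pivot(col: str) -> pd.DataFrame:
        table = cov.pivot_table(
            index="genome_id", columns="sample_id", values=col, aggfunc="sum", fill_value=0.0
        )
        return table.reindex(index=lengths.index, columns=samples, fill_value=0.0)

    breadth = _pivot("covered_bases").div(lengths, axis=0)
    if basis == "rpkm":
        reads = _pivot("mapped_reads")
        totals = sheet.set_index("sample_id")["total_reads"].reindex(samples)
        values = reads.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    elif basis == "depth":
        weighted = cov.assign(_w=cov["length_bp"] * cov["mean_depth"]).pivot_table(
            index="genome_id", columns="sample_id", values="_w", aggfunc="sum", fill_value=0.0
        )
        weighted = weighted.reindex(index=lengths.index, columns=samples, fill_value=0.0)
        values = weighted.div(lengths, axis=0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return AbundanceMatrix(values=values, breadth=breadth, basis=basis, filtered=False)


def presence_filter(matrix: AbundanceMatrix, threshold: float = 0.70) -> AbundanceMatrix:
    """Zero abundances where breadth < threshold; >= threshold is kept.

    Idempotent; the boundary is inclusive ("at least" the threshold fraction
    of bases covered counts as present).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    kept = matrix.values.where(matrix.breadth >= threshold, 0.0)
    return AbundanceMatrix(
        values=kept,
        breadth=matrix.breadth.copy(),
        basis=matrix.basis,
        filtered=True,
        threshold=threshold,
    )


def size_fraction_ratio(matrix: AbundanceMatrix, sheet: pd.DataFrame) -> pd.Series:
    """Per-genome partition ratio between the two size fractions.

    With S the summed abundance over cellular-fraction (0.22 um) samples and
    A the sum over viral-fraction (0.02 um) samples, the ratio is
    (S - A) / (S + A): +1 means cellular-exclusive, -1 viral-exclusive,
    0 an even split. A genome with no signal in either fraction is reported
    missing (NaN), not 0.
    """
    validate_sample_sheet(sheet)
    by_fraction = sheet.set_index("sample_id")["fraction"]
    present = set(by_fraction)
    if set(FRACTIONS) - present:
        raise ValueError(f"sample sheet must contain both fractions {FRACTIONS}")
    cellular = [s for s in matrix.samples if by_fraction.get(s) == "cellular"]
    viral = [s for s in matrix.samples if by_fraction.get(s) == "viral"]
    s_sum = matrix.values[cellular].sum(axis=1)
    a_sum = matrix.values[viral].sum(axis=1)
    total = s_sum + a_sum
    with np.errstate(invalid="ignore"):
        ratio = (s_sum - a_sum) / total
    ratio[total == 0] = np.nan
    ratio.name = "fraction_ratio"
    return ratio


def upset_intersections(
    matrix: AbundanceMatrix,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts of genomes per exclusive presence pattern (UpSet-style).

    ``grouping`` maps sample ids to group labels (e.g. habitats); by default
    each sample is its own group. Patterns are '&'-joined sorted group
    labels; genomes absent everywhere are not counted, so the counts sum to
    the number of genomes present in at least one group.
    """
    presence = matrix.presence()
    if grouping is not None:
        missing = [s for s in presence.columns if s not in grouping]
        if missing:
            raise ValueError(f"grouping lacks sample(s): {missing[:5]}")
        presence = presence.T.groupby(presence.columns.map(dict(grouping))).any().T
    patterns = presence.apply(
        lambda row: "&".join(sorted(col for col in presence.columns[row.to_numpy()])), axis=1
    )
    patterns = patterns[patterns != ""]
    counts = patterns.value_counts().rename_axis("pattern").reset_index(name="count")
    return counts.sort_values(["count", "pattern"], ascending=[False, True]).reset_index(drop=True)
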