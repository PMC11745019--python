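"""Coverage-weighted functional profiles and their contrasts across samples,
habitats and ecological types.

Gene abundance inherits the normalized coverage of the contig (by default,
the genome's breadth-filtered abundance applied uniformly to its contigs);
summing over KEGG-pathway annotations gives a pathway x sample matrix that
can be correlated against the environmental profile (CIM-style), projected
onto the 3-simplex across ecotype groups, or summarized as marker-gene
carriage rates and horizontal-transfer taxon percentages.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .habitat import EnvProfile, interpolate_profile, _complete_linkage, _pairwise_complete_distances
from .io import read_table

__all__ = [
    "ANNOTATION_COLUMNS",
    "MARKER_VOCABULARY",
    "load_annotations",
    "gene_abundance",
    "pathway_matrix",
    "env_pathway_correlation",
    "ternary_proportions",
    "marker_prevalence",
    "taxon_percentages",
]

ANNOTATION_COLUMNS = (
    "gene_id",
    "genome_id",
    "contig_id",
    "kegg_pathways",
    "pfams",
    "markers",
    "best_hit_taxon",
)

#: Marker labels the profiler knows about. VirR (viral rhodopsin) carries a
#: phylogenetic group suffix; querying the bare family name matches both.
MARKER_VOCABULARY = (
    "VirR",
    "VirR_group1",
    "VirR_group2",
    "photolyase",
    "K_channel",
    "sulfite_exporter",
    "SfsA",
)


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV (eggNOG-style '#'-prefixed header tolerated).

    Column mapping from eggNOG-mapper v2 output: ``#query`` -> gene_id,
    ``KEGG_Pathway`` -> kegg_pathways, ``PFAMs`` -> pfams; genome/contig
    membership and marker labels come from the upstream binning/marker scan.
    """
    df = read_table(path, dtype=str)
    renames = {"query": "gene_id", "KEGG_Pathway": "kegg_pathways", "PFAMs": "pfams"}
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    for col in ("gene_id", "genome_id", "contig_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("kegg_pathways", "pfams", "markers", "best_hit_taxon"):
        if col not in df.columns:
            df[col] = ""
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    return df


def _split_list(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text or text == "-":
        return []
    return [item.strip() for item in text.split(",") if item.strip()]


def gene_abundance(
    ann: pd.DataFrame,
    matrix: AbundanceMatrix,
    cov: pd.DataFrame | None = None,
    mode: str = "genome",
) -> pd.DataFrame:
    """Gene x sample abundance inherited from contig coverage.

    mode='genome' (default): every gene takes its genome's breadth-filtered
    normalized abundance in the sample (the genome-level normalization).
    mode='contig': genes take their own contig's mean depth, masked to zero
    wherever the genome fails the breadth filter (requires ``cov``).
    """
    if not matrix.filtered:
        raise ValueError("gene abundance is defined on the breadth-filtered matrix")
    unknown = set(ann["genome_id"]) - set(matrix.genomes)
    if unknown:
        raise ValueError(f"annotations reference unknown genome(s): {sorted(unknown)[:5]}")
    if mode == "genome":
        if cov is not None:
            known_contigs = set(cov["contig_id"])
            orphans = set(ann["contig_id"]) - known_contigs
            if orphans:
                raise ValueError(f"annotated contig(s) absent from coverage: {sorted(orphans)[:5]}")
        values = matrix.values.loc[ann["genome_id"]].to_numpy()
    elif mode == "contig":
        if cov is None:
            raise ValueError("mode='contig' requires the contig coverage table")
        orphans = set(ann["contig_id"]) - set(cov["contig_id"])
        if orphans:
            raise ValueError(f"annotated contig(s) absent from coverage: {sorted(orphans)[:5]}")
        depth = cov.pivot_table(
            index="contig_id", columns="sample_id", values="mean_depth", aggfunc="sum", fill_value=0.0
        ).reindex(columns=matrix.samples, fill_value=0.0)
        depth = depth.reindex(ann["contig_id"].unique(), fill_value=0.0)
        mask = (matrix.values > 0).loc[ann["genome_id"]].to_numpy()
        values = depth.loc[ann["contig_id"]].to_numpy() * mask
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(values, index=pd.Index(ann["gene_id"], name="gene_id"), columns=matrix.samples)


def pathway_matrix(
    gene_ab: pd.DataFrame,
    ann: pd.DataFrame,
    *,
    fractional: bool = False,
    relative: bool = False,
) -> pd.DataFrame:
    """Pathway x sample abundance: sum of member-gene abundances.

    A gene listing k pathways contributes its full abundance to each of them
    (``fractional=True`` splits 1/k instead). ``relative`` normalizes each
    sample column to sum to 1.
    """
    pathways = ann.set_index("gene_id")["kegg_pathways"].map(_split_list)
    rows: dict[str, np.ndarray] = {}
    arr = gene_ab.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(gene_ab.index)}
    for gene, plist in pathways.items():
        if not plist or gene not in gene_pos:
            continue
        weight = 1.0 / len(plist) if fractional else 1.0
        contribution = arr[gene_pos[gene]] * weight
        for pw in plist:
            if pw in rows:
                rows[pw] = rows[pw] + contribution
            else:
                rows[pw] = contribution.copy()
    if not rows:
        return pd.DataFrame(columns=gene_ab.columns, index=pd.Index([], name="pathway"))
    pm = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ab.columns).sort_index()
    pm.index.name = "pathway"
    if relative:
        sums = pm.sum(axis=0).replace(0, np.nan)
        pm = pm.div(sums, axis=1).fillna(0.0)
    return pm


def _linkage_order(values: np.ndarray) -> list[int]:
    """Row ordering from complete-linkage clustering (euclidean), by
    repeatedly cutting the merge history; rows within a cluster keep input
    order, clusters are ordered by their smallest member index."""
    n = values.shape[0]
    if n <= 2:
        return list(range(n))
    dist = _pairwise_complete_distances(values)
    member_sets, _ = _complete_linkage(dist, 2)
    order: list[int] = []

    def _expand(members: tuple[int, ...]) -> list[int]:
        if len(members) <= 2:
            return sorted(members)
        sub = values[list(members)]
        sub_sets, _ = _complete_linkage(_pairwise_complete_distances(sub), 2)
        out: list[int] = []
        for s in sorted(sub_sets, key=min):
            out.extend(_expand(tuple(members[i] for i in s)))
        return out

    for cluster in sorted(member_sets, key=min):
        order.extend(_expand(cluster))
    return order


def env_pathway_correlation(
    pm: pd.DataFrame,
    env: EnvProfile,
    sheet: pd.DataFrame,
    *,
    aggregate: str = "depth_mean",
) -> pd.DataFrame:
    """Pathway x environmental-variable Pearson matrix, CIM-ordered.

    Samples are averaged per depth (default) and paired with the measured or
    interpolated environmental value at that depth; rows and columns are
    reordered by complete-linkage clustering of the correlation matrix so
    co-varying pathways/variables sit together.
    """
    if pm.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    depth_of = sheet.set_index("sample_id")["depth_m"]
    if aggregate == "depth_mean":
        grouped = pm.T.groupby(pm.columns.map(depth_of)).mean().T.sort_index(axis=1)
    elif aggregate == "none":
        grouped = pm.copy()
        grouped.columns = pm.columns.map(depth_of)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    depths = sorted(set(float(d) for d in grouped.columns))
    measured = set(env.depths.tolist())
    env_at = env.data if set(depths) <= measured else interpolate_profile(env, depths).data
    env_block = env_at.loc[depths]

    arr_p = grouped.to_numpy(dtype=float)
    corr = np.full((pm.shape[0], env_block.shape[1]), np.nan)
    for j, var in enumerate(env_block.columns):
        y = env_block[var].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        if mask.sum() < 3 or np.std(y[mask]) == 0:
            continue
        for i in range(arr_p.shape[0]):
            x = arr_p[i, mask]
            if np.std(x) == 0:
                continue
            corr[i, j] = np.corrcoef(x, y[mask])[0, 1]
    out = pd.DataFrame(corr, index=grouped.index, columns=env_block.columns)
    filled = out.fillna(0.0).to_numpy()
    row_order = _linkage_order(filled)
    col_order = _linkage_order(filled.T)
    return out.iloc[row_order, col_order]


def ternary_proportions(
    pm: pd.DataFrame,
    gene_ab: pd.DataFrame,
    ann: pd.DataFrame,
    calls: pd.DataFrame,
    groups: Sequence[str] = ("surface_only", "exported", "deep_adapted"),
) -> pd.DataFrame:
    """Per-pathway composition across three ecotype groups (3-simplex).

    For each pathway, the mean per-genome pathway abundance (summed over
    samples and member genes) is computed inside each group and the three
    means are normalized to sum to 1. Pathways with zero signal in all three
    groups are omitted.
    """
    if len(groups) != 3:
        raise ValueError("exactly three groups required")
    ecotype_of = calls.set_index("genome_id")["ecotype"]
    group_members = {g: ecotype_of.index[ecotype_of == g] for g in groups}
    empty = [g for g, members in group_members.items() if len(members) == 0]
    if empty:
        warnings.warn(f"empty ecotype group(s) {empty}; no ternary coordinates computed", stacklevel=2)
        return pd.DataFrame(columns=list(groups), index=pd.Index([], name="pathway"))

    total_per_gene = gene_ab.sum(axis=1)
    ann_idx = ann.set_index("gene_id")
    genome_of = ann_idx["genome_id"]
    pathways_of = ann_idx["kegg_pathways"].map(_split_list)

    # genome x pathway total abundance
    records: dict[tuple[str, str], float] = {}
    for gene, total in total_per_gene.items():
        for pw in pathways_of.get(gene, []):
            key = (genome_of[gene], pw)
            records[key] = records.get(key, 0.0) + float(total)
    if not records:
        return pd.DataFrame(columns=list(groups), index=pd.Index([], name="pathway"))
    gp = pd.Series(records).rename_axis(["genome_id", "pathway"]).unstack(fill_value=0.0)

    rows = {}
    for pw in pm.index:
        if pw not in gp.columns:
            continue
        means = []
        for g in groups:
            members = [m for m in group_members[g] if m in gp.index]
            means.append(float(gp.loc[members, pw].mean()) if members else 0.0)
        total = sum(means)
        if total == 0:
            continue
        rows[pw] = [m / total for m in means]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))
    out.index.name = "pathway"
    return out


def _carries_marker(labels: list[str], marker: str) -> int:
    return sum(1 for lab in labels if lab == marker or lab.startswith(marker + "_"))


def marker_prevalence(
    ann: pd.DataFrame,
    grouping: pd.Series,
    marker: str,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Carriage rate and mean copy number of a marker per genome group.

    ``grouping`` maps genome_id to a group label (ecotype or habitat).
    Carriage rate is the fraction of the group's genomes with >= 1 copy;
    mean_copies averages copy number over carriers only (NaN when none).
    Groups listed in ``groups`` but holding no genomes report NaN, not 0.
    """
    if marker not in MARKER_VOCABULARY:
        warnings.warn(f"marker {marker!r} not in the built-in vocabulary", stacklevel=2)
    marker_lists = ann["markers"].map(_split_list)
    copies_per_gene = marker_lists.map(lambda labels: _carries_marker(labels, marker))
    copies = (
        pd.Series(copies_per_gene.to_numpy(), index=ann["genome_id"])
        .groupby(level=0)
        .sum()
        .reindex(grouping.index, fill_value=0)
    )
    rows = []
    order = list(groups) if groups is not None else sorted(set(grouping.dropna()))
    for g in order:
        members = grouping.index[grouping == g]
        if len(members) == 0:
            rows.append({"group": g, "n_genomes": 0, "carriage_rate": np.nan, "mean_copies": np.nan})
            continue
        member_copies = copies.loc[members]
        carriers = member_copies[member_copies > 0]
        rows.append(
            {
                "group": g,
                "n_genomes": int(len(members)),
                "carriage_rate": float(len(carriers)) / len(members),
                "mean_copies": float(carriers.mean()) if len(carriers) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def taxon_percentages(ann: pd.DataFrame, min_count: int = 50) -> pd.DataFrame:
    """Percentage of annotated genes per best-hit taxon, rare taxa pooled.

    Genes without a best-hit taxon are excluded from the percentage base and
    reported in the result's ``attrs['n_unannotated']``. Taxa observed fewer
    than ``min_count`` times are pooled into 'other'.
    """
    taxa = ann["best_hit_taxon"].replace("", np.nan)
    n_unannotated = int(taxa.isna().sum())
    taxa = taxa.dropna()
    counts = taxa.value_counts()
    pooled = counts[counts < min_count].sum()
    kept = counts[counts >= min_count]
    out = kept.rename_axis("taxon").reset_index(name="count")
    if pooled:
        out = pd.concat(
            [out, pd.DataFrame([{"taxon": "other", "count": int(pooled)}])], ignore_index=True
        )
    total = out["count"].sum()
    out["percent"] = 100.0 * out["count"] / total if total else 0.0
    out.attrs["n_unannotated"] = n_unannotated
    return out
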