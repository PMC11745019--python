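"""Habitat assignment and ecological typing of genomes from their
depth-abundance distributions.

Each genome's abundance row is z-scored across samples; the habitat of the
sample with the highest z is taken as the genome's most probable habitat.
Combining that argmax with the presence pattern across habitats yields an
ecological type: genomes confined to one layer (surface_only,
chemocline_only, deep_only), genomes reaching the deep layer whose abundance
peaks at the surface (exported, consistent with sinking-particle transport),
genomes peaking in the deep layer itself (deep_adapted), and multi-layer
generalists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .habitat import HabitatPartition

__all__ = ["ECOTYPES", "ZMatrix", "zscore_matrix", "assign_habitat", "classify_ecotype"]

ECOTYPES = (
    "surface_only",
    "chemocline_only",
    "deep_only",
    "exported",
    "deep_adapted",
    "generalist",
    "undetected",
)


@dataclass
class ZMatrix:
    """Row-wise z-scores of a genome x sample abundance matrix.

    ``degenerate`` flags genomes whose row is constant (including all-zero);
    those rows are set to z = 0 everywhere and carry no argmax information.
    """

    z: pd.DataFrame
    degenerate: pd.Series

    @property
    def genomes(self) -> list[str]:
        return list(self.z.index)


def zscore_matrix(matrix: AbundanceMatrix, ddof: int = 1) -> ZMatrix:
    """Standardize each genome's abundance row: z = (x - mean) / sd.

    Sample standard deviation (ddof=1) by default. Requires >= 2 samples;
    constant rows are flagged degenerate and zeroed by convention.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = pd.Series(sd.ravel() == 0, index=values.index, name="degenerate")
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (arr - mean) / safe_sd
    z[degenerate.to_numpy(), :] = 0.0
    return ZMatrix(z=pd.DataFrame(z, index=values.index, columns=values.columns), degenerate=degenerate)


def _habitat_order(partition: HabitatPartition) -> dict[str, int]:
    # labels are already ordered shallow -> deep
    return {label: i for i, label in enumerate(partition.labels)}


def _sample_habitats(samples: list[str], partition: HabitatPartition, sheet: pd.DataFrame) -> pd.Series:
    depth_of = sheet.set_index("sample_id")["depth_m"]
    missing = [s for s in samples if s not in depth_of.index]
    if missing:
        raise ValueError(f"sample sheet lacks sample(s): {missing[:5]}")
    return pd.Series({s: partition.habitat_for_depth(depth_of[s]) for s in samples})


def assign_habitat(
    z: ZMatrix,
    partition: HabitatPartition,
    sheet: pd.DataFrame,
    *,
    aggregate_replicates: bool = False,
) -> pd.Series:
    """Most probable habitat per genome: habitat of the max-z sample.

    Exact ties are broken toward the shallowest habitat. Degenerate genomes
    get no habitat (None). With ``aggregate_replicates`` the z matrix is
    first averaged per depth before taking the argmax.
    """
    zdf = z.z
    if aggregate_replicates:
        depth_of = sheet.set_index("sample_id")["depth_m"]
        zdf = zdf.T.groupby(zdf.columns.map(depth_of)).mean().T
        habitat_of = pd.Series(
            {d: partition.habitat_for_depth(d) for d in zdf.columns}
        )
    else:
        habitat_of = _sample_habitats(list(zdf.columns), partition, sheet)
    order = _habitat_order(partition)

    arr = zdf.to_numpy()
    out: dict[str, str | None] = {}
    for i, genome in enumerate(zdf.index):
        if z.degenerate[genome]:
            out[genome] = None
            continue
        row = arr[i]
        top = row.max()
        tied = [habitat_of[c] for c, v in zip(zdf.columns, row) if v == top]
        out[genome] = min(tied, key=lambda h: order[h])
    return pd.Series(out, name="habitat")


def classify_ecotype(
    matrix: AbundanceMatrix,
    z: ZMatrix,
    partition: HabitatPartition,
    sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Niche calls: one habitat + ecotype per genome.

    Decision ladder, first match wins:

    1. absent from every sample after breadth filtering -> undetected;
    2. present only in the shallowest habitat -> surface_only;
    3. present only in the middle habitat -> chemocline_only;
    4. present only in the deepest habitat -> deep_only;
    5. present in the deepest habitat and max-z habitat is the shallowest
       -> exported;
    6. present in the deepest habitat and max-z habitat is the deepest
       -> deep_adapted;
    7. otherwise -> generalist.

    Rules 2-4 generalize to any k as "present in exactly one habitat".
    Returns a frame with genome_id, habitat, ecotype, max_z and a per-habitat
    presence-pattern string such as ``mixolimnion:2/8;...``.
    """
    presence = matrix.presence()
    habitat_of = _sample_habitats(list(presence.columns), partition, sheet)
    habitats = assign_habitat(z, partition, sheet)
    labels = partition.labels
    shallowest, deepest = labels[0], labels[-1]

    single_layer_names = {labels[0]: "surface_only"}
    if len(labels) == 3:
        single_layer_names[labels[1]] = "chemocline_only"
        single_layer_names[labels[2]] = "deep_only"
    else:  # non-default k: name by position
        for i, lab in enumerate(labels[1:-1], start=2):
            single_layer_names[lab] = f"layer{i}_only"
        if len(labels) > 1:
            single_layer_names[labels[-1]] = "deep_only"

    per_habitat = presence.T.groupby(presence.columns.map(habitat_of)).sum().T
    totals = habitat_of.value_counts()

    rows = []
    for genome in matrix.genomes:
        present_in = [lab for lab in labels if per_habitat.loc[genome].get(lab, 0) > 0]
        max_z = float(z.z.loc[genome].max()) if not z.degenerate[genome] else float("nan")
        habitat = habitats[genome]
        if not present_in:
            ecotype, habitat = "undetected", None
        elif len(present_in) == 1:
            ecotype = single_layer_names[present_in[0]]
        elif deepest in present_in and habitat == shallowest:
            ecotype = "exported"
        elif deepest in present_in and habitat == deepest:
            ecotype = "deep_adapted"
        else:
            ecotype = "generalist"
        pattern = ";".join(
            f"{lab}:{int(per_habitat.loc[genome].get(lab, 0))}/{int(totals[lab])}" for lab in labels
        )
        rows.append(
            {
                "genome_id": genome,
                "habitat": habitat,
                "ecotype": ecotype,
                "max_z": max_z,
                "pattern": pattern,
            }
        )
    return pd.DataFrame(rows)
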