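"""Configuration objects for simulation and pipeline runs.

Configs load from TOML or YAML; unknown keys are rejected so typos fail
loudly. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimConfig", "RunConfig", "load_mapping", "DEFAULT_DEPTHS_M", "DEFAULT_ECOTYPE_MIX"]

#: Sampling depths (m) of the emulated stratified-lake campaign.
DEFAULT_DEPTHS_M = (2.0, 6.0, 14.0, 22.0, 34.0, 40.0, 55.0, 65.0)

#: Planted ecotype composition: roughly half the community confined to the
#: surface layer, a tenth to the chemocline, the rest split between exported,
#: deep-adapted and multi-layer generalist populations — mirroring the
#: skewed layer occupancy seen in stratified polar lakes.
DEFAULT_ECOTYPE_MIX = {
    "surface_only": 0.45,
    "chemocline_only": 0.10,
    "exported": 0.10,
    "deep_adapted": 0.15,
    "generalist": 0.20,
}

#: Viral-rhodopsin carriage probability by layer of a genome's home habitat.
DEFAULT_VIRR_RATES = {"mixolimnion": 0.507, "chemocline": 0.60, "monimolimnion": 0.742}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic stratified-lake community generator.

    Defaults emulate the study design the pipeline targets: 8 depths with
    1 cellular + 3 viral-fraction metagenomes each, a three-layer water
    column split at 10 m and 28 m, 64 eukaryote taxa, and layer-dependent
    viral-rhodopsin carriage (50.7% surface, 74.2% deep).
    """

    seed: int = 0
    depths_m: tuple[float, ...] = DEFAULT_DEPTHS_M
    layer_boundaries_m: tuple[float, float] = (10.0, 28.0)
    n_genomes: int = 200
    ecotype_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ECOTYPE_MIX))
    n_euk_taxa: int = 64
    reads_per_sample: int = 1_000_000
    contig_length_law: tuple[float, float] = (9.9, 0.6)  # log-normal (mu, sigma) of bp
    virr_rate_by_layer: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VIRR_RATES))
    noise_sd: float = 0.2
    coverage_scale: float = 30.0  # peak genome mean depth (x) at unit relative abundance
    read_length_bp: int = 150
    cellular_exclusive_frac: float = 0.2  # genomes invisible in the viral fraction
    euk_link_frac: float = 0.5
    euk_link_strength: float = 1.0
    viral_flag_rate: float = 0.6  # chance a contig is independently flagged as viral

    def __post_init__(self) -> None:
        depths = tuple(float(d) for d in self.depths_m)
        object.__setattr__(self, "depths_m", depths)
        if len(depths) < 1 or any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depths_m must be non-empty and strictly increasing")
        b1, b2 = self.layer_boundaries_m
        if not (min(depths) < b1 < b2 < max(depths)):
            raise ValueError(
                "layer boundaries must be strictly increasing and inside the depth range"
            )
        total = sum(self.ecotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ecotype_mix must sum to 1 (got {total})")
        unknown = set(self.ecotype_mix) - set(DEFAULT_ECOTYPE_MIX)
        if unknown:
            raise ValueError(f"unknown ecotype(s) in mix: {sorted(unknown)}")
        for name, rate in list(self.virr_rate_by_layer.items()) + [
            ("cellular_exclusive_frac", self.cellular_exclusive_frac),
            ("euk_link_frac", self.euk_link_frac),
            ("viral_flag_rate", self.viral_flag_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {name}={rate} outside [0, 1]")
        if any(p < 0 for p in self.ecotype_mix.values()):
            raise ValueError("ecotype_mix proportions must be non-negative")
        if self.n_genomes < 1 or self.reads_per_sample < 1:
            raise ValueError("n_genomes and reads_per_sample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def layer_of_depth(self, depth: float) -> str:
        b1, b2 = self.layer_boundaries_m
        if depth <= b1:
            return "mixolimnion"
        if depth <= b2:
            return "chemocline"
        return "monimolimnion"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulate config key(s): {sorted(unknown)}")
        coerced = dict(mapping)
        for key in ("depths_m", "layer_boundaries_m", "contig_length_law"):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` is set (inputs are generated) or all input paths are
    given. Thresholds default to the analysis' canonical values: 70% breadth
    presence, 0.5 correlation cutoff, QC cutoffs uni56 < 10 / gvog9 >= 4 /
    gvog7df <= 3, k = 3 habitats.
    """

    seed: int = 0
    simulate: SimConfig | None = None
    env_tsv: str | None = None
    samples_tsv: str | None = None
    coverage_tsv: str | None = None
    genomes_tsv: str | None = None
    annotations_tsv: str | None = None
    eukaryotes_tsv: str | None = None
    breadth_threshold: float = 0.70
    correlation_cutoff: float = 0.5
    k_habitats: int = 3
    abundance_basis: str = "rpkm"
    aggregate_replicates: bool = False
    spls_components: int = 2
    spls_keep_x: int | None = None
    spls_keep_y: int | None = None
    qc_uni56_max_exclusive: int = 10
    qc_gvog9_min: int = 4
    qc_gvog7df_max: float = 3.0
    marker: str = "VirR"
    taxon_min_count: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.breadth_threshold <= 1.0:
            raise ValueError("breadth_threshold must lie in [0, 1]")
        if not 0.0 <= self.correlation_cutoff <= 1.0:
            raise ValueError("correlation_cutoff must lie in [0, 1]")
        if self.abundance_basis not in ("rpkm", "depth"):
            raise ValueError("abundance_basis must be 'rpkm' or 'depth'")
        if self.k_habitats < 1:
            raise ValueError("k_habitats must be >= 1")
        if self.simulate is None:
            required = ("env_tsv", "samples_tsv", "coverage_tsv", "genomes_tsv")
            missing = [name for name in required if getattr(self, name) is None]
            if missing:
                raise ValueError(
                    f"without a [simulate] block these inputs are required: {missing}"
                )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        coerced = dict(mapping)
        if isinstance(coerced.get("simulate"), dict):
            sim = dict(coerced["simulate"])
            sim.setdefault("seed", coerced.get("seed", 0))
            coerced["simulate"] = SimConfig.from_mapping(sim)
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_mapping(load_mapping(path))


def load_mapping(path: str | Path) -> dict:
    """Load a TOML (.toml) or YAML (.yaml/.yml) mapping."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return data
    raise ValueError(f"{path}: unsupported config format (use .toml or .yaml)")
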