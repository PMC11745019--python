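"""Synthetic stratified-lake metagenome generator.

Emits every table the pipeline consumes — environmental depth profiles,
sample sheet, per-contig coverage statistics, genome QC/taxonomy records,
gene annotations and a eukaryote abundance table — with the statistical
structure the analysis assumes, plus the planted ground truth needed for
recovery tests.

The generator works at the level of coverage summary statistics rather than
reads: a genome's relative abundance at each depth follows its ecotype's
depth curve, contig mean depth is proportional to that abundance, and the
covered fraction of each contig is drawn around the Lander-Waterman
expectation 1 - exp(-c) at mean depth c (beta-distributed jitter), which is
what a uniform random read layout produces. Cellular-fraction samples carry
the full community signal; viral-fraction replicates carry a per-genome
pass-through factor (0 for a configurable subset, planting genomes exclusive
to the cellular fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .functions import ANNOTATION_COLUMNS
from .habitat import EnvProfile
from .io import write_table

__all__ = [
    "LakeSimulator",
    "PlantedTruth",
    "SimulationResult",
    "expected_breadth",
    "draw_breadth",
    "ecotype_curve",
    "SURFACE_PATHWAYS",
    "DEEP_PATHWAYS",
    "SHARED_PATHWAYS",
]

# KEGG-style pathway pools biased toward the surface and deep habitats; the
# shared pool is drawn everywhere. Labels follow the nomenclature emitted by
# standard annotation pipelines.
SURFACE_PATHWAYS = (
    "Photosynthesis",
    "Photosynthesis - antenna proteins",
    "Plant-pathogen interaction",
    "Circadian entrainment",
    "Flavonoid biosynthesis",
    "Mismatch repair",
    "Citrate cycle (TCA cycle)",
    "Fatty acid biosynthesis",
    "Fatty acid elongation",
)
DEEP_PATHWAYS = (
    "Pyruvate metabolism",
    "Pentose and glucuronate interconversions",
    "Fructose and mannose metabolism",
    "Galactose metabolism",
    "Starch and sucrose metabolism",
    "Gluconeogenesis",
    "Carbon fixation pathways in prokaryotes",
    "Fatty acid degradation",
    "Nitrogen metabolism",
)
SHARED_PATHWAYS = (
    "DNA replication",
    "Purine metabolism",
    "Pyrimidine metabolism",
    "Amino sugar and nucleotide sugar metabolism",
    "Oxidative phosphorylation",
    "Glycolysis / Gluconeogenesis",
)

#: Layer a genome's ecotype is anchored to (for annotation biases).
ECOTYPE_LAYER = {
    "surface_only": "mixolimnion",
    "exported": "mixolimnion",
    "chemocline_only": "chemocline",
    "generalist": "chemocline",
    "deep_adapted": "monimolimnion",
}

#: Carriage probability of the auxiliary markers by layer.
MARKER_RATES = {
    "photolyase": {"mixolimnion": 0.60, "chemocline": 0.35, "monimolimnion": 0.15},
    "K_channel": {"mixolimnion": 0.50, "chemocline": 0.30, "monimolimnion": 0.05},
    "sulfite_exporter": {"mixolimnion": 0.10, "chemocline": 0.30, "monimolimnion": 0.60},
    "SfsA": {"mixolimnion": 0.10, "chemocline": 0.20, "monimolimnion": 0.35},
}

#: Best-hit taxon frequencies for the horizontal-transfer signal; ~60% of
#: annotated genes hit eukaryote lineages, ~32% prokaryote, ~8% viral, and a
#: sprinkle of rare taxa exercises the <min_count pooling. Weight mass left
#: over is emitted as unannotated genes.
TAXON_FREQS = {
    "Eukaryota;unassigned": 0.170,
    "Eukaryota;Streptophyta": 0.110,
    "Eukaryota;Fungi": 0.090,
    "Eukaryota;Metazoa": 0.080,
    "Eukaryota;Chlorophyta": 0.025,
    "Eukaryota;Ciliophora": 0.020,
    "Eukaryota;Amoebozoa": 0.015,
    "Bacteria;Proteobacteria": 0.150,
    "Bacteria;Bacteroidota": 0.070,
    "Bacteria;Cyanobacteria": 0.030,
    "Archaea;Euryarchaeota": 0.020,
    "Viruses;Nucleocytoviricota": 0.060,
    "Viruses;Phycodnaviridae": 0.010,
    "Eukaryota;Rhodophyta": 0.0009,
    "Eukaryota;Apusomonadidae": 0.0006,
    "Archaea;Asgardarchaeota": 0.0005,
}

EUK_TAXON_STEMS = (
    "Choanozoa", "Ciliophora", "Chlorophyta", "Haptophyta", "Chrysophyceae",
    "Fungi", "Apicomplexa", "Euglenozoa", "Bolidomonas", "Dictyochophyceae",
    "Raphidophyceae", "Xanthophyceae", "Nucleariidae", "Rhodophyta",
    "Apusomonadidae", "Mantamonadidae",
)


def expected_breadth(mean_depth: float) -> float:
    """Lander-Waterman expectation: covered fraction at mean depth c."""
    return 1.0 - math.exp(-mean_depth)


def draw_breadth(mean_depth: np.ndarray, rng: np.random.Generator, concentration: float = 300.0) -> np.ndarray:
    """Draw realized breadths around 1 - exp(-c) with beta jitter.

    ``concentration`` is the beta pseudo-count; larger values keep realized
    breadth tighter around the expectation. c = 0 gives exactly 0.
    """
    c = np.asarray(mean_depth, dtype=float)
    mean = 1.0 - np.exp(-c)
    out = np.zeros_like(mean)
    pos = mean > 0
    interior = pos & (mean < 1.0 - 1e-12)
    alpha = mean[interior] * concentration
    beta = (1.0 - mean[interior]) * concentration
    out[interior] = rng.beta(alpha, beta)
    out[pos & ~interior] = 1.0
    return out


def ecotype_curve(ecotype: str, depth: float, boundaries: tuple[float, float]) -> float:
    """Relative-abundance depth curve of each planted ecotype (peak ~1).

    surface_only decays from the shallowest depth and vanishes below the
    upper boundary; chemocline_only is a bump between the boundaries;
    exported peaks at the surface with a slow exponential decay that stays
    detectable at the bottom; deep_adapted is near-zero above the lower
    boundary, faintly detectable in the chemocline and maximal below it;
    generalist spans the whole column with a weak mid-column optimum (a
    strictly flat profile would leave the abundance maximum to noise, i.e.
    no defined modal habitat to recover).
    """
    b1, b2 = boundaries
    mid = 0.5 * (b1 + b2)
    if ecotype == "surface_only":
        return math.exp(-(depth - 2.0) / 8.0) if depth <= b1 else 0.0
    if ecotype == "chemocline_only":
        if b1 < depth <= b2:
            return math.exp(-((depth - mid) ** 2) / (2 * 4.0**2))
        return 0.0
    if ecotype == "exported":
        return math.exp(-(depth - 2.0) / 35.0)
    if ecotype == "deep_adapted":
        if depth > b2:
            return 1.0
        if depth > b1:
            return 0.15
        return 0.005
    if ecotype == "generalist":
        return 0.35 + 0.65 * math.exp(-((depth - mid) ** 2) / (2 * 8.0**2))
    raise ValueError(f"unknown ecotype {ecotype!r}")


@dataclass
class PlantedTruth:
    """Ground truth behind one simulated community.

    ``genomes``: genome_id, ecotype, peak depth, scale, viral pass-through;
    ``abundance``: genome x sample true (noise-free fraction-adjusted)
    relative abundance; ``euk_links``: taxon, linked genome (or none), link
    strength; ``pathway_bias``: pathway, habitat pool it belongs to.
    """

    genomes: pd.DataFrame
    abundance: pd.DataFrame
    euk_links: pd.DataFrame
    pathway_bias: pd.DataFrame

    def to_tsv(self, path: str | Path, **meta) -> None:
        write_table(self.genomes, path, metadata=meta)


@dataclass
class SimulationResult:
    env: EnvProfile
    sheet: pd.DataFrame
    coverage: pd.DataFrame
    genome_table: pd.DataFrame
    annotations: pd.DataFrame
    eukaryotes: pd.DataFrame
    truth: PlantedTruth

    def write(self, outdir: str | Path, seed: int) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"seed": seed, "generator": "gvniche.simulate"}
        paths = {
            "env": outdir / "env.tsv",
            "samples": outdir / "samples.tsv",
            "coverage": outdir / "contig_coverage.tsv",
            "genomes": outdir / "genomes.tsv",
            "annotations": outdir / "annotations.tsv",
            "eukaryotes": outdir / "eukaryotes.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.env.to_tsv(paths["env"], **meta)
        write_table(self.sheet, paths["samples"], metadata=meta)
        write_table(self.coverage, paths["coverage"], metadata=meta)
        write_table(self.genome_table, paths["genomes"], metadata=meta)
        write_table(self.annotations, paths["annotations"], metadata=meta)
        write_table(
            self.eukaryotes.rename_axis("taxon").reset_index(), paths["eukaryotes"], metadata=meta
        )
        self.truth.to_tsv(paths["truth"], **meta)
        return paths


class LakeSimulator:
    """Deterministic generator of one synthetic lake survey.

    Independent random streams are spawned per stage from the config seed,
    so e.g. regenerating annotations does not perturb the community draw.
    """

    def __init__(self, config: SimConfig | None = None, **overrides):
        if config is None:
            config = SimConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a config or keyword overrides, not both")
        self.config = config
        self._community: tuple | None = None

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.config.seed), stream]))

    # ------------------------------------------------------------------ env
    def gen_env(self) -> EnvProfile:
        """Environmental depth profile with three-layer piecewise structure.

        Oxygen and irradiance are high in the surface layer and exactly zero
        below the lower boundary; salinity is near-fresh above the upper
        boundary and rises toward marine values (~35 g/kg) below; sulfate,
        sulfide, iron and manganese increase with depth. Gradients are
        concentrated at the layer interfaces (as density stratification
        produces step-like profiles). Gaussian measurement noise is relative:
        sd = noise_sd x the local variable value, so zero baselines stay
        exactly zero.
        """
        cfg = self.config
        rng = self._rng(1)
        b1, b2 = cfg.layer_boundaries_m
        depths = np.asarray(cfg.depths_m)

        def layered(d: float, mixo: float, chemo: float, moni: float) -> float:
            if d <= b1:
                return mixo
            if d <= b2:
                return chemo
            return moni

        baseline = {
            "temperature": [layered(d, 3.5, 5.5, 8.5) + 0.02 * d for d in depths],
            "salinity": [layered(d, 0.3, 15.0, 35.0) for d in depths],
            "oxygen": [layered(d, 12.0, 4.0, 0.0) for d in depths],
            "chlorophyll_a": [layered(d, 2.0, 4.5, 2.5) for d in depths],
            "par": [30.0 * math.exp(-0.15 * d) if d <= b1 else (2.0 if d <= b2 else 0.0) for d in depths],
            "sulfate": [layered(d, 0.1, 12.0, 26.0) for d in depths],
            "h2s": [layered(d, 0.0, 0.5, 2.5) + 0.02 * max(0.0, d - b2) for d in depths],
            "total_fe": [layered(d, 0.1, 1.5, 4.0) for d in depths],
            "total_mn": [layered(d, 0.02, 0.8, 2.5) for d in depths],
        }
        df = pd.DataFrame(baseline, index=depths)
        if cfg.noise_sd > 0:
            for col in df.columns:
                values = df[col].to_numpy(dtype=float)
                noise = rng.normal(0.0, cfg.noise_sd, size=len(df))
                df[col] = np.clip(values * (1.0 + noise), 0.0, None)
        return EnvProfile(df)

    # ------------------------------------------------------------ community
    def gen_community(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
        """Contig coverage, sample sheet, genome QC table and planted truth."""
        if self._community is not None:
            return self._community
        cfg = self.config
        rng = self._rng(2)
        b = cfg.layer_boundaries_m

        # --- sample sheet: 1 cellular + 3 viral replicates per depth
        rows = []
        for d in cfg.depths_m:
            rows.append(("S{:02.0f}C".format(d), d, "cellular", 0))
            for rep in (1, 2, 3):
                rows.append(("S{:02.0f}V{}".format(d, rep), d, "viral", rep))
        sheet = pd.DataFrame(rows, columns=["sample_id", "depth_m", "fraction", "replicate"])
        sheet["total_reads"] = np.round(
            cfg.reads_per_sample * rng.uniform(0.9, 1.1, size=len(sheet))
        ).astype(int)

        # --- genomes: deterministic ecotype counts by largest remainder
        names = sorted(cfg.ecotype_mix)
        quotas = np.array([cfg.ecotype_mix[n] * cfg.n_genomes for n in names])
        counts = np.floor(quotas).astype(int)
        remainder = cfg.n_genomes - counts.sum()
        for idx in np.argsort(-(quotas - counts))[:remainder]:
            counts[idx] += 1
        ecotypes = rng.permutation(np.repeat(names, counts))

        genome_ids = [f"GV{i + 1:04d}" for i in range(cfg.n_genomes)]
        scales = rng.lognormal(mean=0.0, sigma=0.4, size=cfg.n_genomes)
        n_exclusive = int(round(cfg.cellular_exclusive_frac * cfg.n_genomes))
        passthrough = np.ones(cfg.n_genomes)
        passthrough[rng.choice(cfg.n_genomes, size=n_exclusive, replace=False)] = 0.0

        mu, sigma = cfg.contig_length_law
        contig_rows = []
        for gi, gid in enumerate(genome_ids):
            n_contigs = 4 + rng.poisson(6)
            lengths = np.clip(np.round(rng.lognormal(mu, sigma, size=n_contigs)), 1500, 300_000)
            for ci, length in enumerate(lengths):
                contig_rows.append((f"{gid}_c{ci + 1:03d}", gid, int(length), bool(rng.random() < cfg.viral_flag_rate)))
        contigs = pd.DataFrame(contig_rows, columns=["contig_id", "genome_id", "length_bp", "viral_flag"])
        genome_len = contigs.groupby("genome_id")["length_bp"].sum().reindex(genome_ids)

        # --- true abundance per genome x sample (fraction-adjusted, noiseless)
        curve = np.array(
            [[ecotype_curve(e, d, b) for d in sheet["depth_m"]] for e in ecotypes]
        )
        frac_factor = np.where(
            sheet["fraction"].to_numpy() == "viral", passthrough[:, None], 1.0
        )
        true_abund = curve * scales[:, None] * frac_factor
        truth_abund = pd.DataFrame(true_abund, index=genome_ids, columns=sheet["sample_id"])

        noise = (
            rng.lognormal(mean=0.0, sigma=cfg.noise_sd, size=true_abund.shape)
            if cfg.noise_sd > 0
            else 1.0
        )
        realized = true_abund * noise

        # --- coverage rows: contig mean depth follows genome abundance
        cov_blocks = []
        sample_ids = sheet["sample_id"].to_numpy()
        genome_index = {g: i for i, g in enumerate(genome_ids)}
        contig_genome_idx = contigs["genome_id"].map(genome_index).to_numpy()
        lengths = contigs["length_bp"].to_numpy()
        library_factor = sheet["total_reads"].to_numpy() / cfg.reads_per_sample
        for si, sid in enumerate(sample_ids):
            # depth scales with the sample's realized library size, so
            # RPKM normalization cancels it downstream
            c = realized[contig_genome_idx, si] * cfg.coverage_scale * library_factor[si]
            breadth = draw_breadth(c, rng)
            covered = np.minimum(np.round(breadth * lengths), lengths).astype(int)
            covered[c <= 0] = 0
            mapped = np.round(c * lengths / cfg.read_length_bp).astype(int)
            block = pd.DataFrame(
                {
                    "sample_id": sid,
                    "contig_id": contigs["contig_id"],
                    "genome_id": contigs["genome_id"],
                    "length_bp": lengths,
                    "mean_depth": c,
                    "covered_bases": covered,
                    "mapped_reads": mapped,
                    "viral_flag": contigs["viral_flag"],
                }
            )
            cov_blocks.append(block[block["mean_depth"] > 0])
        coverage = pd.concat(cov_blocks, ignore_index=True)

        # --- genome QC/taxonomy table (dominant order mirrors a real GV
        #     community: one predominant order plus minor ones)
        order_pool = ["Imitervirales", "Pimascovirales", "Asfuvirales", "Pandoravirales"]
        order_probs = [0.92, 0.04, 0.03, 0.01]
        orders = rng.choice(order_pool, size=cfg.n_genomes, p=order_probs)
        family = np.where(orders == "Imitervirales", "Mesomimiviridae", "unclassified")
        genome_table = pd.DataFrame(
            {
                "genome_id": genome_ids,
                "total_length_bp": genome_len.to_numpy(),
                "gc": np.round(rng.normal(0.35, 0.05, cfg.n_genomes), 4),
                "n_genes": (genome_len.to_numpy() // 1100).astype(int),
                "uni56": rng.poisson(2.1, cfg.n_genomes),
                "gvog9": np.clip(rng.binomial(9, 0.85, cfg.n_genomes), 0, 9),
                "gvog7df": np.round(np.clip(rng.normal(1.8, 0.5, cfg.n_genomes), 1.0, None), 3),
                "order": orders,
                "family": family,
            }
        )

        truth = PlantedTruth(
            genomes=pd.DataFrame(
                {
                    "genome_id": genome_ids,
                    "ecotype": ecotypes,
                    "peak_depth_m": [
                        cfg.depths_m[int(np.argmax([ecotype_curve(e, d, b) for d in cfg.depths_m]))]
                        for e in ecotypes
                    ],
                    "scale": scales,
                    "viral_passthrough": passthrough,
                }
            ),
            abundance=truth_abund,
            euk_links=pd.DataFrame(columns=["taxon", "genome_id", "link_strength"]),
            pathway_bias=pd.DataFrame(
                [(p, "mixolimnion") for p in SURFACE_PATHWAYS]
                + [(p, "monimolimnion") for p in DEEP_PATHWAYS]
                + [(p, "shared") for p in SHARED_PATHWAYS],
                columns=["pathway", "habitat_bias"],
            ),
        )
        self._community = (coverage, sheet, genome_table, truth)
        return self._community

    # ----------------------------------------------------------- eukaryotes
    def gen_eukaryotes(self) -> pd.DataFrame:
        """Eukaryote taxon x sample abundance over the cellular samples.

        A configurable fraction of taxa track a linked genome's true
        abundance profile (plus multiplicative noise); the rest follow
        independent depth-niche profiles (a Gaussian optimum at a random
        depth with a random niche width over a small baseline). The link
        table is recorded in the planted truth.
        """
        cfg = self.config
        _, sheet, _, truth = self.gen_community()
        rng = self._rng(3)
        cellular = sheet[sheet["fraction"] == "cellular"]
        samples = list(cellular["sample_id"])
        depths = cellular["depth_m"].to_numpy()

        n_linked = int(round(cfg.euk_link_frac * cfg.n_euk_taxa))
        genome_ids = list(truth.abundance.index)
        linked_genomes = rng.choice(genome_ids, size=n_linked, replace=len(genome_ids) < n_linked)

        taxa, rows, links = [], [], []
        for i in range(cfg.n_euk_taxa):
            stem = EUK_TAXON_STEMS[i % len(EUK_TAXON_STEMS)]
            taxon = f"{stem}_{i // len(EUK_TAXON_STEMS) + 1}"
            taxa.append(taxon)
            noise = rng.lognormal(0.0, max(cfg.noise_sd, 1e-12), size=len(samples))
            if i < n_linked and cfg.euk_link_strength > 0:
                gid = linked_genomes[i]
                base = truth.abundance.loc[gid, samples].to_numpy(dtype=float)
                profile = cfg.euk_link_strength * base * noise
                links.append((taxon, gid, cfg.euk_link_strength))
            else:
                optimum = rng.uniform(min(depths), max(depths))
                width = rng.uniform(3.0, 12.0)
                curve = 0.05 + np.exp(-((depths - optimum) ** 2) / (2 * width**2))
                profile = curve * rng.lognormal(0.0, 0.4) * noise
                links.append((taxon, "", 0.0))
            rows.append(profile)
        euk = pd.DataFrame(np.maximum(np.asarray(rows), 0.0), index=taxa, columns=samples)
        euk.index.name = "taxon"
        truth.euk_links = pd.DataFrame(links, columns=["taxon", "genome_id", "link_strength"])
        return euk

    # ---------------------------------------------------------- annotations
    def gen_annotations(self) -> pd.DataFrame:
        """Gene annotations with habitat-biased pathways and marker carriage.

        Genes are laid on contigs (~1 gene / 1.1 kb); each draws 0-2 KEGG
        pathway labels from its genome's layer-biased pool; viral-rhodopsin
        carriage per genome is Bernoulli with the layer rate of the genome's
        ecotype (copy number >= 1 when carried, more copies at depth);
        best-hit taxa follow a fixed frequency table.
        """
        cfg = self.config
        coverage, _, _, truth = self.gen_community()
        rng = self._rng(4)
        contigs = coverage.drop_duplicates("contig_id")[["contig_id", "genome_id", "length_bp"]]
        ecotype_of = truth.genomes.set_index("genome_id")["ecotype"]

        taxon_labels = list(TAXON_FREQS)
        taxon_p = np.array(list(TAXON_FREQS.values()))
        p_unannotated = 1.0 - taxon_p.sum()

        rows = []
        for gid, sub in contigs.groupby("genome_id", sort=True):
            layer = ECOTYPE_LAYER[ecotype_of[gid]]
            gene_records = []
            for _, contig in sub.iterrows():
                n_genes = max(1, int(contig["length_bp"] // 1100))
                for _ in range(n_genes):
                    gene_records.append(contig["contig_id"])
            n = len(gene_records)

            n_pathways = rng.choice([0, 1, 2], size=n, p=[0.3, 0.5, 0.2])
            pathway_lists = []
            for k in n_pathways:
                chosen = set()
                for _ in range(int(k)):
                    u = rng.random()
                    if layer == "mixolimnion":
                        pool = SURFACE_PATHWAYS if u < 0.6 else SHARED_PATHWAYS
                    elif layer == "monimolimnion":
                        pool = DEEP_PATHWAYS if u < 0.6 else SHARED_PATHWAYS
                    else:
                        pool = (SURFACE_PATHWAYS, DEEP_PATHWAYS, SHARED_PATHWAYS)[
                            int(rng.integers(3))
                        ]
                    chosen.add(pool[int(rng.integers(len(pool)))])
                pathway_lists.append(",".join(sorted(chosen)))

            taxa = np.where(
                rng.random(n) < p_unannotated,
                "",
                np.asarray(taxon_labels)[rng.choice(len(taxon_labels), size=n, p=taxon_p / taxon_p.sum())],
            )

            markers = [[] for _ in range(n)]
            virr_rate = cfg.virr_rate_by_layer[layer]
            if rng.random() < virr_rate:
                group = "VirR_group2" if rng.random() < 0.595 else "VirR_group1"
                copies = 1 + rng.poisson(0.6 if layer == "monimolimnion" else 0.15)
                for slot in rng.choice(n, size=min(copies, n), replace=False):
                    markers[slot].append(group)
            for marker, rates in MARKER_RATES.items():
                if rng.random() < rates[layer]:
                    markers[int(rng.integers(n))].append(marker)

            for j, contig_id in enumerate(gene_records):
                rows.append(
                    {
                        "gene_id": f"{gid}_g{j + 1:05d}",
                        "genome_id": gid,
                        "contig_id": contig_id,
                        "kegg_pathways": pathway_lists[j],
                        "pfams": "",
                        "markers": ",".join(markers[j]),
                        "best_hit_taxon": taxa[j],
                    }
                )
        return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))

    # -------------------------------------------------------------- bundle
    def simulate_all(self) -> SimulationResult:
        env = self.gen_env()
        coverage, sheet, genome_table, truth = self.gen_community()
        eukaryotes = self.gen_eukaryotes()
        annotations = self.gen_annotations()
        return SimulationResult(
            env=env,
            sheet=sheet,
            coverage=coverage,
            genome_table=genome_table,
            annotations=annotations,
            eukaryotes=eukaryotes,
            truth=truth,
        )
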