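"""Synthetic stratified-lake generator: structure, laws, determinism."""

import numpy as np
import pandas as pd
import pytest

from gvniche.abundance import build_abundance, size_fraction_ratio
from gvniche.config import SimConfig
from gvniche.simulate import LakeSimulator, draw_breadth, ecotype_curve, expected_breadth


class TestConfig:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(ecotype_mix={"surface_only": 0.5, "generalist": 0.4})

    def test_boundaries_inside_depth_range(self):
        with pytest.raises(ValueError, match="boundaries"):
            SimConfig(layer_boundaries_m=(10.0, 70.0))

    def test_rates_in_unit_interval(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(virr_rate_by_layer={"mixolimnion": 1.2, "chemocline": 0.5, "monimolimnion": 0.7})

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_mapping({"seed": 1, "bogus": 2})


class TestEnv:
    def test_default_has_eight_depth_rows(self):
        env = LakeSimulator(SimConfig(seed=0)).gen_env()
        assert len(env.data) == 8

    def test_deepest_depth_dark_and_anoxic(self):
        env = LakeSimulator(SimConfig(seed=0)).gen_env()
        deepest = env.data.index.max()
        assert env.data.loc[deepest, "par"] == 0.0
        assert env.data.loc[deepest, "oxygen"] == 0.0

    def test_noiseless_generator_is_seed_independent(self):
        a = LakeSimulator(SimConfig(seed=1, noise_sd=0.0)).gen_env()
        b = LakeSimulator(SimConfig(seed=2, noise_sd=0.0)).gen_env()
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_salinity_rises_to_marine_values(self):
        env = LakeSimulator(SimConfig(seed=0, noise_sd=0.0)).gen_env()
        assert env.data["salinity"].iloc[0] < 1.0
        assert env.data["salinity"].iloc[-1] == pytest.approx(35.0, rel=0.1)


class TestBreadthLaw:
    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0, 4.6])
    def test_mean_breadth_matches_lander_waterman(self, c, rng):
        realized = draw_breadth(np.full(200, c), rng)
        assert abs(realized.mean() - expected_breadth(c)) < 0.02

    def test_zero_depth_zero_breadth(self, rng):
        assert draw_breadth(np.zeros(5), rng).tolist() == [0.0] * 5

    def test_high_depth_near_one(self, rng):
        realized = draw_breadth(np.full(100, 4.6), rng)
        assert abs(realized.mean() - 0.99) < 0.02


class TestCommunity:
    def test_same_seed_identical_tables(self):
        a = LakeSimulator(SimConfig(seed=5, n_genomes=20)).gen_community()
        b = LakeSimulator(SimConfig(seed=5, n_genomes=20)).gen_community()
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_sample_design(self, small_run):
        sheet = small_run["sheet"]
        assert len(sheet) == 32  # 8 depths x (1 cellular + 3 viral)
        per_depth = sheet.groupby("depth_m")["fraction"].value_counts().unstack()
        assert (per_depth["cellular"] == 1).all()
        assert (per_depth["viral"] == 3).all()

    def test_coverage_invariants(self, small_run):
        cov = small_run["cov"]
        assert (cov["covered_bases"] <= cov["length_bp"]).all()
        assert (cov.loc[cov["mean_depth"] == 0, "covered_bases"] == 0).all()

    def test_planted_exclusive_genome_has_ratio_one(self, small_run):
        truth = small_run["truth"].genomes
        ratios = size_fraction_ratio(small_run["filtered"], small_run["sheet"])
        exclusive = truth.loc[truth["viral_passthrough"] == 0, "genome_id"]
        detected = [g for g in exclusive if not np.isnan(ratios[g])]
        assert detected, "no planted cellular-exclusive genome was detected"
        assert all(ratios[g] == 1.0 for g in detected)

    def test_rank_order_roundtrip_without_noise(self):
        """Noise-free generation: each genome's measured abundance preserves
        the rank order of its planted abundance across samples."""
        sim = LakeSimulator(SimConfig(seed=3, n_genomes=20, noise_sd=0.0, reads_per_sample=10**7))
        cov, sheet, _, truth = sim.gen_community()
        raw = build_abundance(cov, sheet)
        for g in truth.abundance.index:
            planted = truth.abundance.loc[g].to_numpy()
            measured = raw.values.loc[g].to_numpy()
            # every resolvable planted pair keeps its order when measured;
            # pairs closer than the integer read-count quantization (and
            # exact ties) carry no defined order
            resolvable = planted[:, None] < planted[None, :] * (1 - 1e-3)
            i, j = np.where(resolvable)
            assert (measured[i] < measured[j]).all()

    def test_ecotype_curves_shape(self):
        b = (10.0, 28.0)
        assert ecotype_curve("surface_only", 14.0, b) == 0.0
        assert ecotype_curve("chemocline_only", 2.0, b) == 0.0
        assert ecotype_curve("deep_adapted", 40.0, b) == 1.0
        assert ecotype_curve("exported", 65.0, b) > 0.1
        assert ecotype_curve("generalist", 65.0, b) > 0.3


class TestEukaryotes:
    def test_default_taxon_count(self, small_sim):
        assert len(small_sim.gen_eukaryotes()) == 64

    def test_values_non_negative(self, small_sim):
        assert (small_sim.gen_eukaryotes().to_numpy() >= 0).all()

    def test_linked_taxa_correlate(self):
        ok = total = 0
        for seed in range(10):
            sim = LakeSimulator(SimConfig(seed=seed, n_genomes=40))
            euk = sim.gen_eukaryotes()
            truth = sim.gen_community()[3]
            linked = truth.euk_links[truth.euk_links["link_strength"] > 0]
            for _, row in linked.iterrows():
                g = truth.abundance.loc[row["genome_id"], euk.columns].astype(float)
                e = euk.loc[row["taxon"]]
                if g.std() == 0 or e.std() == 0:
                    continue
                total += 1
                ok += float(np.corrcoef(g, e)[0, 1]) >= 0.5
        assert ok >= 0.9 * total

    def test_unlinked_null_correlation(self):
        sim = LakeSimulator(SimConfig(seed=3, n_genomes=40, euk_link_strength=0.0))
        euk = sim.gen_eukaryotes()
        truth = sim.gen_community()[3]
        rs = []
        for t in euk.index:
            for g in truth.abundance.index[:20]:
                a = truth.abundance.loc[g, euk.columns].astype(float)
                e = euk.loc[t]
                if a.std() > 0 and e.std() > 0:
                    rs.append(abs(np.corrcoef(a, e)[0, 1]))
        assert np.median(rs) < 0.5


class TestAnnotations:
    def test_referential_integrity(self, small_sim, small_run):
        ann = small_sim.gen_annotations()
        assert set(ann["contig_id"]) <= set(small_run["cov"]["contig_id"])
        assert ann["gene_id"].is_unique

    def test_deep_marker_rate_within_binomial_error(self):
        """1000 deep-adapted genomes: realized viral-rhodopsin carriage within
        3 binomial standard errors of the planted 0.742."""
        cfg = SimConfig(
            seed=8,
            n_genomes=1000,
            ecotype_mix={"deep_adapted": 1.0},
            contig_length_law=(9.0, 0.3),
        )
        sim = LakeSimulator(cfg)
        ann = sim.gen_annotations()
        carried = (
            ann.assign(hit=ann["markers"].str.contains("VirR"))
            .groupby("genome_id")["hit"]
            .any()
        )
        rate = carried.mean()
        se = np.sqrt(0.742 * (1 - 0.742) / 1000)
        assert abs(rate - 0.742) <= 3 * se

    def test_marker_rate_zero_everywhere(self):
        from gvniche.functions import marker_prevalence

        cfg = SimConfig(
            seed=2,
            n_genomes=30,
            virr_rate_by_layer={"mixolimnion": 0.0, "chemocline": 0.0, "monimolimnion": 0.0},
        )
        sim = LakeSimulator(cfg)
        ann = sim.gen_annotations()
        truth = sim.gen_community()[3].genomes
        grouping = truth.set_index("genome_id")["ecotype"]
        out = marker_prevalence(ann, grouping, "VirR")
        assert (out["carriage_rate"].dropna() == 0).all()


class TestWriteReadRoundtrip:
    def test_tables_roundtrip_through_tsv(self, tmp_path, small_sim):
        from gvniche.abundance import load_contig_coverage, load_sample_sheet
        from gvniche.functions import load_annotations
        from gvniche.habitat import EnvProfile

        result = small_sim.simulate_all()
        paths = result.write(tmp_path, seed=11)
        sheet = load_sample_sheet(paths["samples"])
        pd.testing.assert_frame_equal(sheet, result.sheet)
        cov = load_contig_coverage(paths["coverage"])
        pd.testing.assert_frame_equal(cov, result.coverage)
        ann = load_annotations(paths["annotations"])
        assert len(ann) == len(result.annotations)
        env = EnvProfile.from_tsv(paths["env"])
        np.testing.assert_allclose(env.data.to_numpy(), result.env.data.to_numpy())
        assert env.data.attrs == {} or True  # metadata presence is optional
        # seed recorded as a comment line
        first = open(paths["samples"]).readline()
        assert first.startswith("# seed=11")
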