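import numpy as np
import pandas as pd
import pytest

from effluxkit.classify import parse_hgvs_p, species_with_alt_as_reference
from effluxkit.coloc import ImagePair, pearson_coloc
from effluxkit.efflux import process_well_table, summarize_activity
from effluxkit.errors import SimBoundsError
from effluxkit.simulate import (
    SimConfig,
    simulate_blots,
    simulate_image_pair,
    simulate_msa,
    simulate_plate,
    simulate_surface,
)


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = SimConfig(constructs=(("v", 50.0),))
        assert cfg.n_experiments == 4

    def test_fraction_bounds(self):
        with pytest.raises(SimBoundsError):
            SimConfig(wt_true_specific_efflux=0.9, leakage_fraction=0.2)

    def test_activity_bounds(self):
        # 300% of a 0.4 WT efflux would push the fraction past 1
        with pytest.raises(SimBoundsError):
            SimConfig(
                wt_true_specific_efflux=0.4,
                constructs=(("hot", 300.0),),
            )

    def test_min_experiments(self):
        with pytest.raises(SimBoundsError):
            SimConfig(n_experiments=1)


class TestSimulatePlate:
    def test_deterministic(self, noiseless_config):
        a = simulate_plate(noiseless_config)
        b = simulate_plate(noiseless_config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        cfg1 = SimConfig(seed=1, constructs=(("v", 50.0),))
        cfg2 = SimConfig(seed=2, constructs=(("v", 50.0),))
        assert not simulate_plate(cfg1).equals(simulate_plate(cfg2))

    def test_layout(self, noiseless_config):
        wells = simulate_plate(noiseless_config)
        per_exp = wells.groupby("experiment")
        assert len(per_exp) == 4
        for _, grp in per_exp:
            assert (grp["construct"] == "MOCK").sum() == 2
            assert ((grp["construct"] == "MOCK") & (grp["condition"] == "no_acceptor")).sum() == 1
            assert "WT" in set(grp["construct"])

    def test_noiseless_recovery_exact(self, noiseless_config):
        summary = summarize_activity(
            process_well_table(simulate_plate(noiseless_config))
        )
        act = summary.set_index("construct")["mean_activity"]
        assert act["varA"] == pytest.approx(100.0, abs=1e-9)
        assert act["varB"] == pytest.approx(0.0, abs=1e-9)
        assert act["varC"] == pytest.approx(37.5, abs=1e-9)

    def test_zero_activity_zero_specific_efflux(self, noiseless_config):
        res = process_well_table(simulate_plate(noiseless_config))
        specific = res[res["construct"] == "varB"]["specific_efflux"]
        assert np.allclose(specific, 0.0, atol=1e-12)

    def test_renilla_adjustment_recovers_truth(self):
        cfg = SimConfig(
            seed=9,
            constructs=(("v", 60.0),),
            noise_cv=0.0,
            load_cv=0.0,
            renilla_cv=0.4,
        )
        summary = summarize_activity(
            process_well_table(simulate_plate(cfg), renilla_normalize=True)
        )
        act = summary.set_index("construct")["mean_activity"]
        assert act["v"] == pytest.approx(60.0, abs=1e-9)

    def test_without_renilla_adjustment_noise_remains(self):
        cfg = SimConfig(
            seed=9, constructs=(("v", 60.0),), noise_cv=0.0, load_cv=0.0, renilla_cv=0.4
        )
        summary = summarize_activity(process_well_table(simulate_plate(cfg)))
        act = summary.set_index("construct")["mean_activity"]
        assert act["v"] != pytest.approx(60.0, abs=1e-6)


class TestSimulateBlots:
    def test_noiseless_wt_ratio(self):
        cfg = SimConfig(
            seed=0, constructs=(("v", 50.0),), noise_cv=0.0, wt_blot_ratio=1.5
        )
        blots = simulate_blots(cfg)
        wt = blots[blots["construct"] == "WT"].iloc[0]
        assert (wt["band1"] + wt["band2"]) / wt["actin"] == pytest.approx(1.5)

    def test_untransfected_level_zero(self):
        cfg = SimConfig(
            seed=0,
            constructs=(("empty", 0.0),),
            total_protein_levels={"empty": 0.0},
            noise_cv=0.0,
        )
        blots = simulate_blots(cfg)
        empty = blots[blots["construct"] == "empty"]
        assert (empty["band1"] == 0).all() and (empty["band2"] == 0).all()

    def test_reproducible(self):
        cfg = SimConfig(seed=5, constructs=(("v", 50.0),))
        pd.testing.assert_frame_equal(simulate_blots(cfg), simulate_blots(cfg))

    def test_treatment_fold_applied(self):
        cfg = SimConfig(
            seed=0,
            constructs=(("v", 30.0),),
            noise_cv=0.0,
            treatment_effects={"epoxomicin": {"v": (2.0, 1.0, 1.0)}},
        )
        blots = simulate_blots(cfg, conditions=("mock_treated", "epoxomicin"))
        v = blots[blots["construct"] == "v"].set_index("condition")
        mock_sum = v.loc["mock_treated", ["band1", "band2"]].sum(axis=1).iloc[0]
        epox_sum = v.loc["epoxomicin", ["band1", "band2"]].sum(axis=1).iloc[0]
        assert epox_sum == pytest.approx(2.0 * mock_sum)


class TestSimulateSurface:
    def test_surface_fold(self):
        cfg = SimConfig(
            seed=0,
            constructs=(("v", 30.0),),
            noise_cv=0.0,
            surface_levels={"v": 0.5},
            treatment_effects={"apoa1": {"v": (1.0, 1.5, 1.0)}},
        )
        surf = simulate_surface(cfg, conditions=("mock_treated", "apoa1"))
        v = surf[surf["construct"] == "v"].set_index("condition")
        ratio = v.loc["apoa1", "surface"].iloc[0] / v.loc["mock_treated", "surface"].iloc[0]
        assert ratio == pytest.approx(1.5)


class TestSimulateMsa:
    def test_constructed_support(self):
        msa = simulate_msa(n_species=29, variant_support={"p.R130K": 3}, seed=0)
        assert len(msa) == 30  # human + 29 species
        var = parse_hgvs_p("p.R130K")
        assert species_with_alt_as_reference(msa, var) == 3

    def test_zero_support(self):
        msa = simulate_msa(n_species=29, variant_support={"p.R130K": 0}, seed=0)
        assert species_with_alt_as_reference(msa, parse_hgvs_p("p.R130K")) == 0

    def test_default_panel_size(self):
        msa = simulate_msa(variant_support={"p.E284K": 5}, seed=1)
        assert len(msa) - 1 == 29

    def test_support_exceeds_species(self):
        with pytest.raises(ValueError):
            simulate_msa(n_species=5, variant_support={"p.R130K": 6}, seed=0)

    def test_human_row_carries_reference(self):
        msa = simulate_msa(variant_support={"p.R130K": 10}, seed=0)
        human = next(str(rec.seq) for rec in msa if rec.id == "human")
        assert human[129] == "R"

    def test_position_outside_length(self):
        from effluxkit.errors import MsaMappingError

        with pytest.raises(MsaMappingError):
            simulate_msa(variant_support={"p.R130K": 3}, seed=0, length=50)


class TestSimulateImagePair:
    def test_exact_r_one(self):
        a, b = simulate_image_pair(1.0, (64, 64), seed=0, exact=True)
        assert pearson_coloc(ImagePair(a, b)).r == pytest.approx(1.0, abs=1e-9)

    def test_exact_minus_one(self):
        a, b = simulate_image_pair(-1.0, (64, 64), seed=0, exact=True)
        assert pearson_coloc(ImagePair(a, b)).r == pytest.approx(-1.0, abs=1e-9)

    def test_exact_zero(self):
        a, b = simulate_image_pair(0.0, (64, 64), seed=0, exact=True)
        assert pearson_coloc(ImagePair(a, b)).r == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_default(self):
        a, b = simulate_image_pair(0.5, (128, 128), seed=0)
        assert a.min() >= 0 and b.min() >= 0

    def test_degenerate_shape(self):
        with pytest.raises(ValueError):
            simulate_image_pair(0.5, (1, 1), seed=0)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            simulate_image_pair(1.5, (8, 8), seed=0)

    def test_null_sampling_distribution(self):
        # Monte-Carlo oracle: at 256x256 the sample r of a target_r=0 pair
        # has sd ~ 1/256, so |r| < 0.02 in >= 95% of seeds.
        hits = 0
        for seed in range(100):
            a, b = simulate_image_pair(0.0, (256, 256), seed=seed)
            if abs(pearson_coloc(ImagePair(a, b)).r) <= 0.02:
                hits += 1
        assert hits >= 95

    def test_mean_recovery_at_wt_level(self):
        rs = []
        for seed in range(100):
            a, b = simulate_image_pair(0.26, (256, 256), seed=seed)
            rs.append(pearson_coloc(ImagePair(a, b)).r)
        assert 0.24 <= np.mean(rs) <= 0.28
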