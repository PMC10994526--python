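"""Synthetic cohort generator: determinism, structure and fixtures."""

import numpy as np
import pytest

import eigenbrains as eb
from eigenbrains.simulate import (
    GROUP_SIZES,
    PATIENT_GROUPS,
    REFERENCE_STATS,
    SimConfig,
    generate_topic_maps,
    make_reference_cohort,
)


class TestGenerateCohort:
    def test_default_cohort_size(self, default_cohort):
        images, clinical = default_cohort["images"], default_cohort["clinical"]
        assert len(images) == 234
        assert len(clinical) == 234
        assert (clinical["group"] == "CU").sum() == 117
        counts = clinical[clinical["group"] != "CU"]["group"].value_counts()
        assert tuple(counts[g] for g in PATIENT_GROUPS) == GROUP_SIZES

    def test_same_seed_bitwise_identical(self, small_config):
        im1, t1, g1, _ = eb.generate_cohort(small_config)
        im2, t2, g2, _ = eb.generate_cohort(small_config)
        for a, b in zip(im1, im2):
            assert a.subject_id == b.subject_id
            assert np.array_equal(a.values, b.values)
        assert t1.equals(t2)
        assert np.array_equal(g1.loadings, g2.loadings)

    def test_different_seed_differs(self, small_config):
        im1, _, _, _ = eb.generate_cohort(small_config)
        other = SimConfig(**{**small_config.__dict__, "seed": small_config.seed + 1})
        im2, _, _, _ = eb.generate_cohort(other)
        assert not np.array_equal(im1[0].values, im2[0].values)

    def test_planted_patterns_orthonormal(self, small_cohort):
        _, _, truth, _ = small_cohort
        gram = truth.planted_patterns @ truth.planted_patterns.T
        assert np.max(np.abs(gram - np.eye(len(gram)))) < 1e-10

    def test_group_loading_means_recovered(self):
        """Monte-Carlo over 20 seeds: empirical group means within 3 SE."""
        cfg0 = SimConfig(seed=0)
        means = np.asarray(cfg0.loading_group_means)
        sums = np.zeros_like(means)
        counts = np.zeros(5)
        for seed in range(20):
            cfg = SimConfig(seed=seed)
            _, clinical, truth, _ = eb.generate_cohort(cfg)
            for gi, g in enumerate(PATIENT_GROUPS + ("CU",)):
                sel = (clinical["group"] == g).to_numpy()
                sums[gi] += truth.loadings[sel].sum(axis=0)
                counts[gi] += sel.sum()
        emp = sums / counts[:, None]
        se = cfg0.loading_sd / np.sqrt(counts)[:, None]
        assert np.all(np.abs(emp - means) < 3 * se)

    def test_reference_normalization_restores_signal(self, small_cohort):
        """Dividing out the reference mean undoes the global scale."""
        images, _, truth, grid = small_cohort
        for im in images[:10]:
            norm = eb.normalize_to_reference(im, grid)
            # normalized image is proportional to the unscaled generative one,
            # so the voxel-wise correlation over the mask is essentially 1
            a = grid.flatten(norm.values)
            b = grid.flatten(im.values)
            r = np.corrcoef(a, b)[0, 1]
            assert r > 0.999

    def test_ages_follow_group_parameters(self, default_cohort):
        clinical = default_cohort["clinical"]
        pat = clinical[clinical["group"] != "CU"]
        for gi, g in enumerate(PATIENT_GROUPS):
            ages = pat.loc[pat["group"] == g, "age_scan"]
            mu, sd = REFERENCE_STATS["age_scan_mean"][gi], REFERENCE_STATS["age_scan_sd"][gi]
            tol = 3.5 * max(sd, 1.5) / np.sqrt(len(ages))
            assert abs(ages.mean() - mu) < max(tol, 1.5)
        both = pat.dropna(subset=["age_onset"])
        assert (both["age_onset"] <= both["age_scan"]).all()

    def test_rank_limit_enforced(self):
        with pytest.raises(ValueError):
            cfg = SimConfig(seed=0, grid_dims=(4, 4, 4), k_true=9,
                            loading_group_means=tuple(tuple(0.0 for _ in range(9))
                                                      for _ in range(5)))
            eb.generate_cohort(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, noise_sd=-1.0)
        with pytest.raises(ValueError):
            SimConfig(seed=0, k_true=0)
        with pytest.raises(ValueError):
            SimConfig(seed=0, loading_group_means=((1.0,),) * 5)  # wrong k


class TestTopicMaps:
    def test_default_count_is_22(self, small_cohort):
        _, _, truth, grid = small_cohort
        cfg = SimConfig(seed=7, grid_dims=grid.dims)
        topics = generate_topic_maps(cfg, truth, grid=grid)
        assert len(topics) == 22
        assert len({t.label for t in topics}) == 22

    def test_exact_copy_decodes_to_r_one(self, small_cohort):
        _, _, truth, grid = small_cohort
        cfg = SimConfig(seed=7, grid_dims=grid.dims)
        topics = generate_topic_maps(cfg, truth, n_topics=5, match_r=1.0, grid=grid)
        res = eb.decode(grid.unflatten(truth.planted_patterns[0]), topics, grid)
        assert res.table.iloc[0]["r"] == pytest.approx(1.0, abs=1e-10)

    def test_matched_topics_hit_target_correlation(self, small_cohort):
        _, _, truth, grid = small_cohort
        cfg = SimConfig(seed=7, grid_dims=grid.dims)
        topics = generate_topic_maps(cfg, truth, n_topics=6, match_r=0.8, grid=grid)
        for k in range(truth.planted_patterns.shape[0]):
            r = np.corrcoef(grid.flatten(topics[k].values),
                            truth.planted_patterns[k])[0, 1]
            assert abs(r - 0.8) < 0.1

    def test_independent_topics_weakly_correlated(self, small_cohort):
        _, _, truth, grid = small_cohort
        cfg = SimConfig(seed=7, grid_dims=grid.dims)
        topics = generate_topic_maps(cfg, truth, n_topics=12, n_matched=0, grid=grid)
        rs = [abs(np.corrcoef(grid.flatten(t.values), p)[0, 1])
              for t in topics for p in truth.planted_patterns]
        assert np.mean(rs) < 0.2

    def test_invalid_arguments(self, small_cohort):
        _, _, truth, grid = small_cohort
        cfg = SimConfig(seed=7, grid_dims=grid.dims)
        with pytest.raises(ValueError):
            generate_topic_maps(cfg, truth, n_topics=0, grid=grid)
        with pytest.raises(ValueError):
            generate_topic_maps(cfg, truth, match_r=1.5, grid=grid)


class TestReferenceCohortFixture:
    def test_total_and_group_sizes(self):
        fix = make_reference_cohort()
        assert len(fix) == 117
        assert tuple(fix["group"].value_counts()[g] for g in PATIENT_GROUPS) == GROUP_SIZES

    @pytest.mark.parametrize("flag,counts", [
        ("social_disinhibition", (0, 25, 5, 1)),
        ("apathy", (14, 19, 4, 2)),
        ("lack_of_empathy", (0, 9, 3, 0)),
        ("perseverative", (0, 10, 6, 0)),
        ("hyperorality", (1, 15, 3, 0)),
        ("executive_dysfunction", (52, 30, 7, 22)),
    ])
    def test_symptom_counts_reproduced(self, flag, counts):
        fix = make_reference_cohort()
        for g, expected in zip(PATIENT_GROUPS, counts):
            assert fix.loc[fix["group"] == g, f"flag_{flag}"].sum() == expected

    def test_bvftd_social_disinhibition_fraction(self):
        fix = make_reference_cohort()
        sub = fix[fix["group"] == "bvFTD"]
        assert sub["flag_social_disinhibition"].sum() == 25
        assert len(sub) == 30
        assert round(100 * 25 / 30) == 83

    def test_sex_and_apoe_availability(self):
        fix = make_reference_cohort()
        for g, males, avail, carriers in zip(
            PATIENT_GROUPS, REFERENCE_STATS["males"], REFERENCE_STATS["apoe4_available"],
            REFERENCE_STATS["apoe4_carriers"],
        ):
            sub = fix[fix["group"] == g]
            assert (sub["sex"] == "M").sum() == males
            assert sub["apoe4"].notna().sum() == avail
            assert np.nansum(sub["apoe4"]) == carriers


class TestSerialization:
    def test_cohort_round_trip(self, tmp_path, small_config):
        images, clinical, truth, grid = eb.generate_cohort(small_config)
        eb.save_cohort(images[:3], clinical.head(3), truth, grid, small_config, tmp_path)
        from eigenbrains.images import load_image

        back = load_image(tmp_path / "images" / f"{images[0].subject_id}.nii.gz",
                          grid, subject_id=images[0].subject_id)
        assert np.allclose(back.values, images[0].values, atol=1e-5)  # float32 storage
        import pandas as pd

        tab = pd.read_csv(tmp_path / "clinical.csv")
        assert len(tab) == 3
        assert (tmp_path / "ground_truth.json").exists()
        assert (tmp_path / "sim_config.json").exists()

    def test_decomposition_round_trip(self, tmp_path, small_decomposition):
        from eigenbrains.decomposition import save_decomposition

        _, mat, dec, _, grid = small_decomposition
        from dataclasses import replace

        horn = eb.horn_parallel(mat, n_null=40, percentile=95.0, seed=0)
        dec3 = replace(dec, k_retained=3, horn=horn)
        save_decomposition(dec3, grid, tmp_path / "dec")
        import pandas as pd

        scores = pd.read_csv(tmp_path / "dec" / "scores.csv")
        assert list(scores.columns) == ["subject_id", "EB1", "EB2", "EB3"]
        assert np.allclose(scores[["EB1", "EB2", "EB3"]].to_numpy(),
                           dec.scores[:, :3], atol=1e-8)
        assert (tmp_path / "dec" / "eigenbrain_01.nii.gz").exists()
        assert (tmp_path / "dec" / "eigenbrains_4d.nii.gz").exists()
        assert (tmp_path / "dec" / "horn.json").exists()
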