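"""Synthetic-cohort generator: genotypes, planted covariance, determinism."""

import numpy as np
import pytest

from scnkit.cohort import genotype_to_group, load_cohort, load_simulation_sidecar
from scnkit.glm import build_scn
from scnkit.roi import SphereROI, extract_volumes, seed_by_name
from scnkit.simulate import (
    DEFAULT_MET_ALLELE_FREQ,
    NetworkTemplate,
    SimulationConfig,
    generate_cohort,
    sample_genotypes,
    write_cohort,
)


class TestSampleGenotypes:
    def test_boundary_frequencies(self, rng):
        assert sample_genotypes(50, 0.0, rng) == ["VV"] * 50
        assert sample_genotypes(50, 1.0, rng) == ["MM"] * 50

    def test_invalid_frequency_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_genotypes(10, 1.2, rng)

    def test_grouping_pools_met_carriers(self):
        assert genotype_to_group("MM") == "Met"
        assert genotype_to_group("MV") == "Met"
        assert genotype_to_group("VV") == "Val"
        with pytest.raises(ValueError):
            genotype_to_group("XX")

    def test_hwe_expected_counts_at_reference_frequency(self):
        """At p = 111/384 and n = 192 the expected genotype counts are
        (16.0, 78.9, 97.0); averages over repeated draws stay within
        3 binomial SDs."""
        p = DEFAULT_MET_ALLELE_FREQ
        n, n_rep = 192, 60
        probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        expected = n * probs
        np.testing.assert_allclose(expected, [16.0, 78.9, 97.0], atol=0.1)
        rng = np.random.default_rng(77)
        counts = np.zeros(3)
        for _ in range(n_rep):
            drawn = sample_genotypes(n, p, rng)
            counts += [drawn.count("MM"), drawn.count("MV"), drawn.count("VV")]
        mean_counts = counts / n_rep
        sd = np.sqrt(n * probs * (1 - probs) / n_rep)
        assert np.all(np.abs(mean_counts - expected) <= 3 * sd)


class TestGenerateCohort:
    def test_group_sizes_and_schema(self, fixture_cohort):
        _, cohort, _ = fixture_cohort
        assert cohort.n_subjects == 192
        assert (cohort.phenotypes["group"] == "Met").sum() == 91
        assert (cohort.phenotypes["group"] == "Val").sum() == 101
        # pooling rule holds row-wise
        assert all(
            genotype_to_group(g) == grp
            for g, grp in zip(cohort.phenotypes["genotype"], cohort.phenotypes["group"])
        )
        for col in ("subject_id", "age", "education", "sex", "apoe4", "MMSE"):
            assert col in cohort.phenotypes.columns

    def test_noiseless_equal_slopes_give_perfect_correlation(self):
        """noise = 0 and slope_met = slope_val: every target voxel is an
        exact linear function of the seed volume in both groups."""
        template = NetworkTemplate(
            seed_name="dorsal_caudal_putamen",
            target_blobs=(((-16, -16, 8), 10.0, 1.0),),
            slope_met=1.5, slope_val=1.5,
        )
        config = SimulationConfig(
            n_met=10, n_val=10, image_shape=(20, 20, 20),
            baseline={"kind": "box", "density": 0.6},
            templates=(template,), behavior_couplings=(),
            noise_sd=0.0, rng_seed=9,
        )
        cohort, _ = generate_cohort(config)
        seed = seed_by_name("dorsal_caudal_putamen")
        vols = extract_volumes(
            cohort, [SphereROI(seed.name, seed.mni_xyz, 4.0)]
        )[seed.name].to_numpy()
        from scnkit.simulate import template_fields

        _, target_field, support = template_fields(config, template)
        for vox in np.argwhere(support)[::50]:
            y = cohort.data[:, vox[0], vox[1], vox[2]]
            r = np.corrcoef(vols, y)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_seed_volume_reads_latent_score(self, fixture_cohort):
        """Extracted seed volume is a near-noiseless linear readout of the
        generator's latent score (unit gain)."""
        config, cohort, truth = fixture_cohort
        seed = seed_by_name("dorsal_caudal_putamen")
        vols = extract_volumes(
            cohort, [SphereROI(seed.name, seed.mni_xyz, 4.0)]
        )[seed.name].to_numpy()
        latent = np.asarray(truth["latents"]["dorsal_caudal_putamen"])
        r = np.corrcoef(vols, latent)[0, 1]
        assert r > 0.9
        gain = np.polyfit(latent, vols, 1)[0]
        assert gain == pytest.approx(1.0, abs=0.1)

    def test_covariance_strength_monotone_in_slope_noise_ratio(self):
        """Seed-target correlation increases with the slope/noise ratio."""
        rs = []
        for slope, noise in [(0.5, 0.05), (1.0, 0.03), (2.0, 0.01)]:
            template = NetworkTemplate(
                seed_name="dorsal_caudal_putamen",
                target_blobs=(((-16, -16, 8), 10.0, 1.0),),
                slope_met=slope, slope_val=slope,
            )
            config = SimulationConfig(
                n_met=30, n_val=30, image_shape=(20, 20, 20),
                baseline={"kind": "box", "density": 0.6},
                templates=(template,), behavior_couplings=(),
                noise_sd=noise, rng_seed=13,
            )
            cohort, truth = generate_cohort(config)
            seed = seed_by_name("dorsal_caudal_putamen")
            vols = extract_volumes(
                cohort, [SphereROI(seed.name, seed.mni_xyz, 4.0)]
            )[seed.name].to_numpy()
            from scnkit.simulate import template_fields

            _, tf, _ = template_fields(config, template)
            vox = np.unravel_index(np.argmax(tf), tf.shape)
            rs.append(np.corrcoef(vols, cohort.data[:, vox[0], vox[1], vox[2]])[0, 1])
        assert rs[0] < rs[1] < rs[2]

    def test_behavior_scores_coupled_to_seed_volume(self, fixture_cohort):
        config, cohort, _ = fixture_cohort
        seed = seed_by_name("dorsal_caudal_putamen")
        vols = extract_volumes(
            cohort, [SphereROI(seed.name, seed.mni_xyz, 4.0)]
        )[seed.name].to_numpy()
        r = np.corrcoef(vols, cohort.phenotypes["MMSE"])[0, 1]
        assert r > 0.05  # positive coupling at the planted (weak) strength

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimulationConfig(n_met=0, n_val=0, templates=(),
                                             behavior_couplings=()))

    def test_blob_outside_fov_rejected(self):
        template = NetworkTemplate("dorsal_caudal_putamen",
                                   (((500, 0, 0), 10.0, 1.0),), 1.0, 1.0)
        config = SimulationConfig(n_met=3, n_val=3, image_shape=(16, 16, 16),
                                  templates=(template,), behavior_couplings=(),
                                  baseline={"kind": "box", "density": 0.6})
        with pytest.raises(ValueError, match="field of view"):
            generate_cohort(config)


class TestDeterminismAndRoundTrip:
    def test_same_seed_reproduces_every_byte(self, small_cohort):
        config, cohort, truth = small_cohort
        again, truth2 = generate_cohort(SimulationConfig(**{
            k: v for k, v in config.to_dict().items()
        }))
        np.testing.assert_array_equal(cohort.data, again.data)
        assert cohort.phenotypes.equals(again.phenotypes)
        assert truth["latents"] == truth2["latents"]

    def test_write_reload_roundtrip(self, small_cohort, tmp_path):
        config, cohort, truth = small_cohort
        write_cohort(cohort, truth, tmp_path)
        back = load_cohort(tmp_path)
        assert back.phenotypes.equals(cohort.phenotypes)
        sidecar = load_simulation_sidecar(tmp_path)
        assert sidecar["config"]["templates"] == config.to_dict()["templates"]
        assert SimulationConfig.from_dict(sidecar["config"]) == config

    def test_reloaded_cohort_gives_identical_scn_maps(self, small_cohort, tmp_path):
        """Loading the same files twice yields bit-identical SCN outputs."""
        _, cohort, truth = small_cohort
        write_cohort(cohort, truth, tmp_path)
        m1, c1 = build_scn(load_cohort(tmp_path), "dorsal_caudal_putamen")
        m2, c2 = build_scn(load_cohort(tmp_path), "dorsal_caudal_putamen")
        np.testing.assert_array_equal(m1.tstat, m2.tstat)
        np.testing.assert_array_equal(m1.q_mask, m2.q_mask)
        assert [c.peak_index for c in c1] == [c.peak_index for c in c2]
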