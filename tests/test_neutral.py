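import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.special import expit, logit

from ecmassembly.io import AsvTable
from ecmassembly.neutral import (
    GroupProfile,
    NeutralOccupancyGAM,
    fit_all_groups,
    migration_rate,
    occurrence_frequency,
)


def logistic_profile(n_asvs=200, n_samples=10_000, noise_rng=None, seed=0):
    """Profile whose occupancy follows an exact logistic curve of abundance."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(-5, -1, n_asvs))
    f = expit(2.5 * x + 7.0)
    if noise_rng is None:
        successes = np.rint(f * n_samples)
    else:
        successes = noise_rng.binomial(n_samples, f)
    return GroupProfile(
        [f"A{i}" for i in range(n_asvs)], successes / n_samples, x, n_samples
    )


class TestOccurrenceFrequency:
    def test_counting(self):
        counts = np.zeros((2, 10), int)
        counts[0, :3] = 5
        counts[1, :] = 2
        t = AsvTable(counts, ["a", "b"], [f"s{i}" for i in range(10)])
        prof = occurrence_frequency(t, t.sample_ids)
        assert dict(zip(prof.asv_ids, prof.f_obs)) == {"a": 0.3, "b": 1.0}

    def test_mean_log_abundance_hand_value(self):
        # rel abundances 0.01 and 0.001 over two samples -> log10(0.0055)
        counts = np.array([[10, 1], [990, 999]])
        t = AsvTable(counts, ["rare", "dominant"], ["s1", "s2"])
        prof = occurrence_frequency(t, ["s1", "s2"])
        i = prof.asv_ids.index("rare")
        assert prof.mean_log_abund[i] == pytest.approx(np.log10(0.0055), abs=1e-12)
        assert prof.mean_log_abund[i] == pytest.approx(-2.2596, abs=5e-5)

    def test_absent_asvs_excluded_and_empty_group(self, toy_table):
        prof = occurrence_frequency(toy_table, ["S2", "S3"])
        assert "ASV_a" not in prof.asv_ids
        with pytest.raises(ValueError):
            occurrence_frequency(toy_table, [])


class TestMigrationRate:
    def test_identity_gives_one(self):
        f = np.array([0.2, 0.5, 0.8])
        assert migration_rate(f, f) == 1.0

    def test_zero_numerator(self):
        assert migration_rate([0, 1, 1], [0.5, 0.5, 0.5]) == 0.0

    def test_hand_example(self):
        # (0.21 + 0.24) / (0.24 + 0.25) = 0.45 / 0.49
        m = migration_rate([0.3, 0.6], [0.4, 0.5])
        assert m == pytest.approx(0.45 / 0.49, abs=1e-15)
        assert m == pytest.approx(0.9184, abs=5e-5)

    def test_matches_bruteforce_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 40)
            fo, fp = rng.random(n), rng.random(n)
            brute = sum(a * (1 - a) for a in fo) / sum(b * (1 - b) for b in fp)
            assert migration_rate(fo, fp) == pytest.approx(brute, abs=1e-12)
            perm = rng.permutation(n)
            assert migration_rate(fo[perm], fp[perm]) == pytest.approx(
                migration_rate(fo, fp), abs=1e-12
            )

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            migration_rate([0.5, 0.5], [0.0, 1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        f=hnp.arrays(
            float,
            st.integers(2, 30),
            elements=st.floats(0.01, 0.99),
        )
    )
    def test_property_identity_and_nonnegativity(self, f):
        assert migration_rate(f, f) == 1.0
        rng = np.random.default_rng(0)
        g = rng.uniform(0.01, 0.99, len(f))
        assert migration_rate(f, g) >= 0.0


class TestNeutralOccupancyGAM:
    def test_noise_free_logistic_r2_near_one(self):
        res = NeutralOccupancyGAM(logistic_profile()).fit()
        assert res.pseudo_r2 >= 0.99
        np.testing.assert_allclose(
            logit(np.clip(res.f_pred, 1e-12, 1 - 1e-12)),
            2.5 * res.profile.mean_log_abund + 7.0,
            atol=0.2,
        )

    def test_flat_occupancy_r2_near_zero(self):
        rng = np.random.default_rng(4)
        prof = GroupProfile(
            [f"A{i}" for i in range(100)],
            np.full(100, 0.6),
            rng.uniform(-5, -1, 100),
            10,
        )
        res = NeutralOccupancyGAM(prof).fit()
        assert abs(res.pseudo_r2) <= 0.02

    def test_fitted_values_bounded_and_band_ordered(self):
        rng = np.random.default_rng(10)
        prof = GroupProfile(
            [f"A{i}" for i in range(60)],
            rng.integers(0, 11, 60) / 10,
            rng.uniform(-6, -1, 60),
            10,
        )
        res = NeutralOccupancyGAM(prof).fit()
        assert (res.f_pred >= 0).all() and (res.f_pred <= 1).all()
        assert (res.band_lower <= res.band_upper + 1e-12).all()
        assert (res.band_lower >= 0).all() and (res.band_upper <= 1).all()

    def test_migration_rate_consistency(self):
        res = NeutralOccupancyGAM(logistic_profile(seed=2)).fit()
        assert res.m == pytest.approx(
            migration_rate(res.profile.f_obs, res.f_pred), abs=1e-12
        )

    def test_too_few_asvs_rejected(self):
        prof = GroupProfile(["a", "b"], [0.1, 0.9], [-3.0, -1.0], 10)
        with pytest.raises(ValueError, match="insufficient"):
            NeutralOccupancyGAM(prof)

    def test_basis_reduced_for_few_unique_abundances(self):
        f = np.tile([0.2, 0.5, 0.7, 0.9, 1.0], 4)
        x = np.tile([-5.0, -4.0, -3.0, -2.0, -1.0], 4)
        prof = GroupProfile([f"A{i}" for i in range(20)], f, x, 10)
        with pytest.warns(UserWarning, match="reducing spline basis"):
            model = NeutralOccupancyGAM(prof, k=10)
        assert model.k == 4

    def test_summary_mentions_key_stats(self):
        res = NeutralOccupancyGAM(logistic_profile(seed=3)).fit()
        text = res.summary()
        assert "pseudo R2" in text and "migration rate" in text


class TestFitAllGroups:
    def test_four_groups_and_error_isolation(self, small_study):
        _, table, metadata, _, _ = small_study
        fits = fit_all_groups(table, metadata)
        assert set(fits) == {
            "broadleaf-adult",
            "broadleaf-juvenile",
            "conifer-adult",
            "conifer-juvenile",
        }
        for res in fits.values():
            assert not isinstance(res, Exception)
            assert 0 <= res.pseudo_r2 <= 1 and res.m >= 0

    def test_determinism_across_duplicate_groups(self, small_study):
        _, table, metadata, _, _ = small_study
        f1 = fit_all_groups(table, metadata)
        f2 = fit_all_groups(table, metadata)
        for k in f1:
            assert f1[k].pseudo_r2 == f2[k].pseudo_r2
            assert f1[k].m == f2[k].m

    def test_small_group_flagged_failed_others_survive(self, small_study):
        _, table, metadata, _, _ = small_study
        # drop every sample of one group; its fit fails, the rest proceed
        meta = metadata.copy()
        juv_con = meta[(meta.stage == "juvenile") & (meta.host_type == "conifer")]
        keep = [s for s in table.sample_ids if s not in set(juv_con["sample_id"])]
        sub = table.select_samples(keep)
        sub = sub.select_asvs((sub.counts > 0).any(axis=1))
        fits = fit_all_groups(sub, meta)
        assert isinstance(fits["conifer-juvenile"], Exception)
        assert not isinstance(fits["conifer-adult"], Exception)
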