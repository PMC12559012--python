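"""Generator contracts: determinism, marginal structure, ground-truth flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import denomweight as dw
from denomweight.cohort import EVENT_COLUMNS


def in_window_any(registry, window):
    start, end = pd.Timestamp(window.start), pd.Timestamp(window.index_date)
    mask = np.zeros(len(registry), dtype=bool)
    for col in EVENT_COLUMNS:
        mask |= registry[col].between(start, end).to_numpy()
    return mask


class TestReference:
    def test_total_and_stratum_grid(self, small_config, small_tables):
        reference, _, _ = small_tables
        assert reference["count"].sum() == small_config.n_reference_adults
        assert len(reference) == 73 * 2 * 7
        assert (reference["count"] >= 0).all()
        assert set(reference["sex"]) == set(dw.SEXES)
        assert set(reference["region"]) == set(dw.REGIONS)
        assert set(reference["age_year"]) == set(dw.STRATUM_AGE_LABELS)

    def test_empty_population(self):
        cfg = dw.GeneratorConfig(n_reference_adults=0, seed=1)
        reference = dw.generate_reference(cfg)
        assert (reference["count"] == 0).all()

    def test_same_seed_identical(self, small_config):
        a = dw.generate_reference(small_config)
        b = dw.generate_reference(small_config)
        pd.testing.assert_frame_equal(a, b)


class TestRegistry:
    def test_determinism_byte_identical(self, small_config, small_tables, tmp_path):
        reference, registry, truth = small_tables
        reg2, truth2 = dw.generate_registry(small_config, reference)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        dw.write_registry(registry, p1)
        dw.write_registry(reg2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(truth, truth2)

    def test_marginal_fidelity_without_noise(self):
        cfg = dw.GeneratorConfig(
            n_reference_adults=20_000,
            seed=5,
            overrep_factor=1.0,
            underrep_factor=1.0,
            count_noise=False,
            duplicate_fraction=0.0,
            missing_demo_fraction=0.0,
        )
        reference = dw.generate_reference(cfg)
        registry, _ = dw.generate_registry(cfg, reference)
        counts = (
            registry.assign(
                age_year=np.where(
                    registry["age_years"] >= 90, "90+",
                    registry["age_years"].astype(int).astype(str),
                )
            )
            .groupby(["age_year", "sex", "region"])
            .size()
        )
        ref = reference.set_index(["age_year", "sex", "region"])["count"]
        aligned = counts.reindex(ref.index, fill_value=0)
        assert (aligned == ref).all()

    def test_scaling_factors_shift_expected_counts(self):
        cfg = dw.GeneratorConfig(
            n_reference_adults=50_000, seed=7, count_noise=False,
            duplicate_fraction=0.0, missing_demo_fraction=0.0,
            overrep_factor=1.5, underrep_factor=0.5,
        )
        reference = dw.generate_reference(cfg)
        registry, _ = dw.generate_registry(cfg, reference)
        ages = registry["age_years"].astype(int)
        ref_over = reference[
            reference["age_year"].isin([str(a) for a in range(30, 46)])
        ]["count"].sum()
        ref_under = reference[
            reference["age_year"].isin([str(a) for a in range(65, 76)])
        ]["count"].sum()
        n_over = ((ages >= 30) & (ages <= 45)).sum()
        n_under = ((ages >= 65) & (ages <= 75)).sum()
        # rounding per stratum keeps totals within half a count per stratum
        assert n_over == pytest.approx(1.5 * ref_over, rel=0.01)
        assert n_under == pytest.approx(0.5 * ref_under, rel=0.02)

    def test_degenerate_config_is_clean(self, window):
        cfg = dw.GeneratorConfig(
            n_reference_adults=10_000, seed=2,
            inactive_fraction=0.0, duplicate_fraction=0.0,
            missing_demo_fraction=0.0,
        )
        reference = dw.generate_reference(cfg)
        registry, truth = dw.generate_registry(cfg, reference)
        assert registry["pseudo_id"].is_unique
        assert registry["age_years"].notna().all()
        assert registry["sex"].notna().all()
        assert (truth["truly_active"] == 1).all()
        assert in_window_any(registry, window).all()

    def test_inactive_count_within_binomial_interval(self, default_tables):
        _, registry, truth = default_tables
        base = truth["is_duplicate_of"].isna()
        n = int(base.sum())
        k = int((truth.loc[base, "truly_active"] == 0).sum())
        lo, hi = stats.binom.interval(0.99, n, 0.024)
        assert lo <= k <= hi

    def test_inactive_rows_unvaccinated_and_eventless(self, default_tables, window):
        _, registry, truth = default_tables
        merged = registry.merge(truth, on="record_row_id")
        inactive = merged["truly_active"] == 0
        assert (merged.loc[inactive, "vaccinated"] == 0).all()
        assert not in_window_any(registry, window)[inactive.to_numpy()].any()

    def test_inactivity_concentrated_in_target_ages(self, default_tables):
        _, registry, truth = default_tables
        merged = registry.merge(truth, on="record_row_id")
        merged = merged[merged["age_years"].notna() & merged["is_duplicate_of"].isna()]
        in_range = merged["age_years"].between(30, 45)
        rate_in = 1 - merged.loc[in_range, "truly_active"].mean()
        rate_out = 1 - merged.loc[~in_range, "truly_active"].mean()
        assert rate_in > 2 * rate_out

    def test_vaccination_coverage_among_active(self, default_config, default_tables):
        _, registry, truth = default_tables
        merged = registry.merge(truth, on="record_row_id")
        active = merged[(merged["truly_active"] == 1) & merged["is_duplicate_of"].isna()]
        p = default_config.vaccination_coverage
        se = np.sqrt(p * (1 - p) / len(active))
        assert abs(active["vaccinated"].mean() - p) < 3 * se

    def test_duplicates_reference_existing_rows(self, small_config, small_tables):
        _, registry, truth = small_tables
        dup = truth[truth["is_duplicate_of"].notna()]
        n_base = int(truth["is_duplicate_of"].isna().sum())
        assert len(dup) == round(small_config.duplicate_fraction * n_base)
        assert dup["is_duplicate_of"].isin(truth["record_row_id"]).all()
        # each duplicated pseudo_id appears on at least two rows
        dup_ids = registry.loc[registry["record_row_id"].isin(dup["record_row_id"]), "pseudo_id"]
        counts = registry["pseudo_id"].value_counts()
        assert (counts.loc[dup_ids.unique()] >= 2).all()

    def test_missing_demographics_share(self, small_config, small_tables):
        _, registry, truth = small_tables
        base = registry[truth["is_duplicate_of"].isna().to_numpy()]
        miss = (base["age_years"].isna() | base["sex"].isna()).mean()
        p = small_config.missing_demo_fraction
        se = np.sqrt(p * (1 - p) / len(base))
        assert abs(miss - p) < 4 * se

    def test_csv_roundtrip(self, small_tables, tmp_path):
        reference, registry, truth = small_tables
        dw.write_reference(reference, tmp_path / "ref.csv")
        dw.write_registry(registry, tmp_path / "reg.csv")
        dw.write_truth(truth, tmp_path / "truth.csv")
        ref2 = dw.read_reference(tmp_path / "ref.csv")
        reg2 = dw.read_registry(tmp_path / "reg.csv")
        truth2 = dw.read_truth(tmp_path / "truth.csv")
        pd.testing.assert_frame_equal(reference, ref2)
        assert len(reg2) == len(registry)
        assert (reg2["pseudo_id"] == registry["pseudo_id"]).all()
        pd.testing.assert_frame_equal(truth, truth2)


class TestUnvaccinatedProfile:
    def test_counts_exclude_inactive_and_duplicates(self, small_tables):
        _, registry, truth = small_tables
        profile = dw.true_unvaccinated_profile(registry, truth)
        assert set(profile["age_band"]) <= set(dw.AGE_BAND_LABELS)
        merged = registry.merge(truth, on="record_row_id")
        expected = (
            (merged["truly_active"] == 1)
            & merged["is_duplicate_of"].isna()
            & (merged["vaccinated"] == 0)
            & merged["age_years"].notna()
            & merged["sex"].notna()
        ).sum()
        assert profile["count"].sum() == expected


@pytest.mark.parametrize(
    ("field", "value"),
    [
        ("inactive_fraction", -0.1),
        ("inactive_fraction", 1.0),
        ("duplicate_fraction", 1.5),
        ("missing_demo_fraction", -0.01),
        ("vaccination_coverage", 1.2),
        ("overrep_factor", 0.9),
        ("underrep_factor", 0.0),
        ("underrep_factor", 1.2),
        ("inactive_rate_ratio", -1.0),
        ("n_reference_adults", -5),
    ],
)
def test_invalid_config_names_field(field, value):
    with pytest.raises(ValueError, match=field):
        dw.GeneratorConfig(**{field: value})


def test_window_must_precede_index_date():
    from datetime import date

    with pytest.raises(ValueError, match="index_date"):
        dw.GeneratorConfig(
            engagement_window_start=date(2022, 1, 1), index_date=date(2021, 1, 1)
        )
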