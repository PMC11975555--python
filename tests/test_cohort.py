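"""Synthetic registry: published moments, exclusion semantics, reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from tegcoag import cohort
from tegcoag.cohort import (
    Cohort,
    CohortConfig,
    ConfigurationError,
    PatientRecord,
    VariableSpec,
    apply_exclusions,
    compute_ci_composite,
    default_config,
    generate_cohort,
)


class TestDefaultConfig:
    @pytest.mark.parametrize(
        "variable, group, expected",
        [
            ("CI", "g_high", (2.267, 1.319)),
            ("R", "malignant", (4.309, 0.952)),
            ("R", "benign", (4.828, 1.126)),
            ("R", "tnm_early", (4.480, 0.927)),
            ("K", "g_low", (1.692, 0.553)),
            ("Angle", "g_high", (71.357, 4.195)),
            ("MA", "tnm_late", (62.327, 5.953)),
            ("FIB", "tnm_early", (7.468, 6.703)),
            ("Hemoglobin", "benign", (127.982, 20.977)),
        ],
    )
    def test_printed_gaussian_moments(self, default_cfg, variable, group, expected):
        assert default_cfg.variables[variable].per_group_params[group] == expected

    def test_printed_group_sizes(self, default_cfg):
        gs = default_cfg.group_sizes
        assert gs["benign"] == 109
        assert gs["malignant"] == 158
        assert gs["tnm_early"] + gs["tnm_late"] == gs["malignant"]
        assert gs["g_low"] + gs["g_high"] == gs["malignant"]
        assert (gs["tnm_early"], gs["tnm_late"]) == (84, 74)
        assert (gs["g_low"], gs["g_high"]) == (91, 67)

    def test_exclusion_counts(self, default_cfg):
        assert default_cfg.exclusion_counts == {
            "other_site_tumor": 10, "neoadjuvant": 13, "anticoagulant": 10,
        }

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            VariableSpec("x", "gaussian", {"benign": (1.0, 0.0)})
        with pytest.raises(ConfigurationError):
            VariableSpec("x", "bernoulli", {"benign": 1.5})
        with pytest.raises(ConfigurationError):
            VariableSpec("x", "gaussian", {"nonsense": (1.0, 1.0)})

    def test_partition_violation_rejected(self, default_cfg):
        bad = dict(default_cfg.group_sizes, tnm_early=90)
        with pytest.raises(ConfigurationError):
            dataclasses.replace(default_cfg, group_sizes=bad)


class TestGenerateCohort:
    def test_exact_group_counts_and_analysis_size(self, default_registry):
        eligible, report = apply_exclusions(default_registry)
        assert len(default_registry) == 300
        assert report.retained == 267
        labels = [r.labels["malignancy"] for r in eligible.records]
        assert labels.count("malignant") == 158
        assert labels.count("benign") == 109
        tnm = [r.labels["tnm_binary"] for r in eligible.records
               if r.labels["malignancy"] == "malignant"]
        g = [r.labels["g_binary"] for r in eligible.records
             if r.labels["malignancy"] == "malignant"]
        assert (tnm.count("tnm_early"), tnm.count("tnm_late")) == (84, 74)
        assert (g.count("g_low"), g.count("g_high")) == (91, 67)

    def test_reproducible_given_config_and_seed(self, default_cfg):
        a = generate_cohort(default_cfg, seed=11)
        b = generate_cohort(default_cfg, seed=11)
        c = generate_cohort(default_cfg, seed=12)
        assert a.to_dataframe().equals(b.to_dataframe())
        assert not a.to_dataframe().equals(c.to_dataframe())

    def test_empty_config_gives_empty_cohort(self, default_cfg):
        empty = dataclasses.replace(
            default_cfg,
            group_sizes={g: 0 for g in cohort.GROUP_LABELS},
            exclusion_counts={f: 0 for f in cohort.EXCLUSION_FLAGS},
        )
        assert len(generate_cohort(empty, seed=0)) == 0

    def test_sample_mean_clt_bound(self, default_cfg):
        # n=10,000 malignant draws of R: mean within 3*sd/sqrt(n) of 4.309
        big = dataclasses.replace(
            default_cfg,
            group_sizes={"malignant": 10_000, "benign": 0, "tnm_early": 5_000,
                         "tnm_late": 5_000, "g_low": 5_000, "g_high": 5_000},
            exclusion_counts={f: 0 for f in cohort.EXCLUSION_FLAGS},
        )
        coh = generate_cohort(big, seed=5, stratify_by="malignancy")
        r = np.array([rec.values["R"] for rec in coh.records])
        assert abs(r.mean() - 4.309) < 3 * 0.952 / np.sqrt(10_000)

    def test_marginal_fidelity_ks(self, default_cfg):
        # KS distance of a 5,000-draw gaussian marginal vs its spec < 0.03
        big = dataclasses.replace(
            default_cfg,
            group_sizes={"malignant": 0, "benign": 5_000, "tnm_early": 0,
                         "tnm_late": 0, "g_low": 0, "g_high": 0},
            exclusion_counts={f: 0 for f in cohort.EXCLUSION_FLAGS},
        )
        coh = generate_cohort(big, seed=9)
        for var in ("R", "CI", "Hemoglobin"):
            mean, sd = default_cfg.variables[var].per_group_params["benign"]
            x = np.array([rec.values[var] for rec in coh.records])
            ks = stats.kstest(x, "norm", args=(mean, sd)).statistic
            assert ks < 0.03, var

    def test_g_stratified_moments_drive_malignant_sampling(self, eligible_cohort_df):
        df = eligible_cohort_df
        g_high = df[df["g_binary"] == "g_high"]
        assert abs(g_high["CI"].mean() - 2.267) < 3 * 1.319 / np.sqrt(len(g_high))

    def test_correlation_block_is_honored(self, default_cfg):
        names = ["R", "K"]
        mat = np.array([[1.0, 0.7], [0.7, 1.0]])
        cfg = dataclasses.replace(
            default_cfg, correlation=(names, mat),
            group_sizes={"malignant": 0, "benign": 4000, "tnm_early": 0,
                         "tnm_late": 0, "g_low": 0, "g_high": 0},
            exclusion_counts={f: 0 for f in cohort.EXCLUSION_FLAGS},
        )
        df = generate_cohort(cfg, seed=3).to_dataframe()
        assert abs(np.corrcoef(df["R"], df["K"])[0, 1] - 0.7) < 0.05

    def test_invalid_correlation_rejected(self, default_cfg):
        mat = np.array([[1.0, 1.2], [1.2, 1.0]])  # not positive-definite
        with pytest.raises(ConfigurationError):
            dataclasses.replace(default_cfg, correlation=(["R", "K"], mat))

    def test_structural_ci_mode_links_ci_to_teg(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, ci_mode="structural",
                                  ci_noise_sd=0.3)
        df = generate_cohort(cfg, seed=4).to_dataframe()
        predicted = compute_ci_composite(df["R"], df["K"], df["Angle"], df["MA"])
        resid = df["CI"] - predicted
        assert resid.std() < 0.5  # only the injected noise remains
        assert np.corrcoef(df["CI"], predicted)[0, 1] > 0.9


class TestExclusions:
    def test_printed_disjoint_flag_arithmetic(self, default_registry):
        _, report = apply_exclusions(default_registry)
        assert report.per_flag == {
            "other_site_tumor": 10, "neoadjuvant": 13, "anticoagulant": 10,
        }
        assert report.total_removed == 33
        assert report.retained == 267

    def test_multiflag_records_counted_once(self):
        records = [
            PatientRecord(
                id=f"P{i}", values={"R": 4.0},
                flags={f: True for f in cohort.EXCLUSION_FLAGS},
                labels={"malignancy": "benign", "tnm_binary": None,
                        "g_binary": None},
            )
            for i in range(5)
        ]
        kept, report = apply_exclusions(Cohort(records=records))
        assert len(kept) == 0
        assert report.total_removed == 5  # union, not 15
        assert all(v == 5 for v in report.per_flag.values())

    def test_empty_registry(self):
        kept, report = apply_exclusions(Cohort(records=[]))
        assert len(kept) == 0 and report.total_removed == 0
        assert all(v == 0 for v in report.per_flag.values())

    def test_idempotent(self, default_registry):
        once, r1 = apply_exclusions(default_registry)
        twice, r2 = apply_exclusions(once)
        assert r2.total_removed == 0
        assert [r.id for r in twice.records] == [r.id for r in once.records]


class TestCiComposite:
    def test_intercept_only(self):
        assert compute_ci_composite(1, 2, 3, 4, (0, 0, 0, 0, 1.7)) == 1.7

    def test_default_coefficients_hand_arithmetic(self):
        assert compute_ci_composite(4.3, 1.5, 68, 60) == pytest.approx(1.345, abs=5e-4)

    def test_affine_in_each_argument(self, rng):
        base = compute_ci_composite(4.3, 1.5, 68, 60)
        beta_ma = cohort.DEFAULT_CI_COEFFICIENTS[3]
        doubled = compute_ci_composite(4.3, 1.5, 68, 120)
        assert doubled - base == pytest.approx(beta_ma * 60, rel=1e-12)


class TestSerialization:
    def test_cohort_csv_round_trip(self, default_registry, tmp_path):
        path = tmp_path / "cohort.csv"
        cohort.write_cohort_csv(default_registry, path)
        df = cohort.read_cohort_csv(path)
        orig = default_registry.to_dataframe()
        assert list(df.columns) == list(orig.columns)
        num = orig.select_dtypes("number").columns
        assert np.allclose(df[num].to_numpy(), orig[num].to_numpy(),
                           atol=1e-12, rtol=0)
        assert (df["malignancy"] == orig["malignancy"]).all()

    def test_config_yaml_round_trip(self, default_cfg, tmp_path):
        path = tmp_path / "config.yaml"
        cohort.write_config_yaml(default_cfg, path)
        back = cohort.read_config_yaml(path)
        assert back.group_sizes == default_cfg.group_sizes
        assert back.config_hash() == default_cfg.config_hash()
        for name, spec in default_cfg.variables.items():
            assert back.variables[name].per_group_params == spec.per_group_params
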