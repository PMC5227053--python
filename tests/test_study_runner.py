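"""Study orchestration: grids, pairing, determinism, resumability, comparisons."""

import numpy as np
import pandas as pd
import pytest

from ar1bench import StudyConfig, compare_methods, run_prior_sensitivity, run_study


class TestConfig:
    def test_study1_defaults(self):
        cfg = StudyConfig.study1()
        assert len(cfg.phi_grid) == 19
        assert cfg.T_grid == [10, 25, 40, 50, 100]
        assert cfg.theta_grid == [0.0]
        assert sum(1 for _ in cfg.conditions()) == 95
        assert cfg.n_reps == 2000

    def test_study2_defaults(self):
        cfg = StudyConfig.study2()
        assert len(cfg.phi_grid) == 13 and len(cfg.theta_grid) == 13
        assert cfg.T_grid == [25, 50]
        assert sum(1 for _ in cfg.conditions()) == 338
        assert cfg.methods == ("mle", "bayes_sr")

    def test_prior_sensitivity_defaults(self):
        cfg = StudyConfig.prior_sensitivity()
        assert cfg.T_grid == [10] and cfg.phi_grid == [-0.5, 0.0, 0.5]
        assert cfg.n_reps == 1000

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(phi_grid=[0.5, 1.0])
        with pytest.raises(ValueError):
            StudyConfig(methods=("r1", "burg"))
        with pytest.raises(ValueError):
            StudyConfig(methods=())


@pytest.fixture(scope="module")
def tiny_config():
    return dict(
        T_grid=[10], phi_grid=[-0.5, 0.0, 0.5], n_reps=150,
        methods=("r1", "c_stat", "ols"), master_seed=5,
    )


class TestRunStudy:
    def test_method_expansion_and_shape(self, tiny_config):
        table = run_study(StudyConfig.study1(**tiny_config))
        # ols expands to ols_a and ols_s
        assert set(table["method"]) == {"r1", "c_stat", "ols_a", "ols_s"}
        assert len(table) == 4 * 3
        assert (table["n_reps"] <= 150).all() and (table["n_reps"] >= 140).all()

    def test_rerun_is_bit_identical(self, tiny_config):
        a = run_study(StudyConfig.study1(**tiny_config))
        b = run_study(StudyConfig.study1(**tiny_config))
        pd.testing.assert_frame_equal(a, b)

    def test_incremental_output_and_resume(self, tiny_config, tmp_path):
        cfg = StudyConfig.study1(output_dir=str(tmp_path), **tiny_config)
        first = run_study(cfg)
        assert (tmp_path / "results_long.csv").exists()
        assert (tmp_path / "config.json").exists()
        assert (tmp_path / "study1_r1.csv").exists()
        # a second run must skip the finished conditions and reproduce the table
        again = run_study(StudyConfig.study1(output_dir=str(tmp_path), **tiny_config))
        pd.testing.assert_frame_equal(
            first.sort_values(["method", "phi"]).reset_index(drop=True),
            again.sort_values(["method", "phi"]).reset_index(drop=True),
            check_dtype=False,
        )

    def test_study2_theta_zero_matches_study1(self):
        """With theta = 0 the misspecification study reduces to correct AR(1)."""
        common = dict(T_grid=[25], phi_grid=[0.3], n_reps=600, methods=("mle",))
        s1 = run_study(StudyConfig.study1(master_seed=8, **common))
        s2 = run_study(StudyConfig.study2(theta_grid=[0.0], master_seed=9, **common))
        mc2se = 2 * s1["sd_emp"].iloc[0] / np.sqrt(600)
        assert abs(s1["bias"].iloc[0] - s2["bias"].iloc[0]) < 2 * mc2se


class TestCompareMethods:
    def _table(self, bias):
        return pd.DataFrame(
            {
                "T": [25, 25], "phi": [0.3, 0.6], "theta": [0.0, 0.0],
                "bias": bias, "sd_emp": [0.2, 0.25], "epr": [0.3, 0.8],
            }
        )

    def test_self_difference_is_zero(self):
        t = self._table([0.1, -0.05])
        diff = compare_methods(t, t)
        cond = diff[diff["row"] == "condition"]
        assert (cond[["d_bias", "d_sd_emp", "d_epr"]].to_numpy() == 0).all()

    def test_max_abs_row_equals_scan(self):
        a = self._table([0.10, -0.05])
        b = self._table([0.02, 0.06])
        diff = compare_methods(a, b)
        cond = diff[diff["row"] == "condition"]
        top = diff[diff["row"] == "max_abs"].iloc[0]
        assert top["d_bias"] == pytest.approx(cond["d_bias"].abs().max())
        assert top["d_epr"] == pytest.approx(cond["d_epr"].abs().max())

    def test_key_mismatch_raises(self):
        a = self._table([0.1, 0.2])
        b = self._table([0.1, 0.2]).assign(phi=[0.3, 0.9])
        with pytest.raises(ValueError, match="do not match"):
            compare_methods(a, b)


class TestPriorSensitivity:
    def test_structure_and_symmetry(self):
        cfg = StudyConfig.prior_sensitivity(
            phi_grid=[0.0], n_reps=40, n_iter=600, master_seed=12
        )
        table = run_prior_sensitivity(cfg)
        # 7 tests x 2 priors x 3 parameters
        assert len(table) == 7 * 2 * 3
        assert set(table["prior"]) == {"bayes_flat", "bayes_sr"}
        # symmetric mu priors (tests 1, 5, 6, 7) recover mu ~ 0 at phi_true = 0
        sym = table[(table["parameter"] == "mu") & table["test"].isin([1, 5, 6, 7])]
        assert (sym["mean"].abs() < 0.25).all()
        # sigma_e posterior means are positive and near 1
        sig = table[table["parameter"] == "sigma_e"]
        assert ((sig["mean"] > 0.5) & (sig["mean"] < 2.0)).all()
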