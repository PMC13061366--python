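"""End-to-end fit functions, summaries, file round-trips, and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import ltnflow as lf
from ltnflow.cli import main as cli_main


@pytest.fixture(scope="module")
def scenario():
    return lf.simulate_pibble_data(N=15, D=4, Q=2, seed=11, n_total=300)


@pytest.fixture(scope="module")
def pibble_draws(scenario):
    return lf.fit_pibble(scenario.Y, scenario.X, S=400, seed=3)


class TestFitPibble:
    def test_prior_only_mode_recovers_prior_moments(self):
        P, Q = 2, 2
        prior = lf.GMCLPrior(
            Theta=np.array([[1.0, -0.5], [0.3, 2.0]]),
            Gamma=np.eye(Q), Xi=np.eye(P), v=P + 8,
        )
        X = np.random.default_rng(0).standard_normal((Q, 6))
        dr = lf.fit_pibble(None, X, prior, S=4000, seed=9)
        assert np.max(np.abs(dr.Lambda.mean(0) - prior.Theta)) < 0.08
        sig_expected = prior.Xi / (prior.v - P - 1)
        assert np.max(np.abs(dr.Sigma.mean(0) - sig_expected)) < 0.05

    def test_seed_determinism_bit_identical(self, scenario):
        a = lf.fit_pibble(scenario.Y, scenario.X, S=50, seed=21)
        b = lf.fit_pibble(scenario.Y, scenario.X, S=50, seed=21)
        for name in ("eta", "Lambda", "Sigma", "pi"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_pi_draws_are_valid_compositions(self, pibble_draws):
        pi = pibble_draws.pi
        assert np.all(pi > 0)
        np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-10)

    def test_rejects_mismatched_prior(self, scenario):
        bad = lf.default_gmcl_prior(D=7, Q=2)
        with pytest.raises(ValueError, match="P="):
            lf.fit_pibble(scenario.Y, scenario.X, bad, S=10)


class TestFitGMDLM:
    @staticmethod
    def _spec(T, P, W=0.1):
        return lf.GMDLMSpec(
            F=[np.ones(1)] * T, G=[np.eye(1)] * T,
            W=[np.array([[W]])] * T, gamma=[1.0] * T,
            M0=np.zeros((1, P)), C0=np.eye(1), Xi=np.eye(P), v=P + 6,
        )

    def test_random_walk_end_to_end(self, rng):
        T, D = 8, 3
        Y = lf.CountMatrix(
            Y=rng.multinomial(200, [0.5, 0.3, 0.2], size=T).T
        )
        dr = lf.fit_gmdlm(Y, self._spec(T, D - 1), S=80, seed=4)
        assert dr.Theta_path.shape == (80, T + 1, 1, D - 1)
        assert np.all(np.isfinite(dr.Theta_path))

    def test_no_evolution_matches_pibble_means(self, rng):
        T, D = 8, 3
        Y = lf.CountMatrix(
            Y=rng.multinomial(500, [0.5, 0.3, 0.2], size=T).T
        )
        spec = self._spec(T, D - 1, W=0.0)
        dyn = lf.fit_gmdlm(Y, spec, S=1500, seed=4)
        prior = lf.GMCLPrior(
            Theta=np.zeros((D - 1, 1)), Gamma=np.eye(1),
            Xi=np.eye(D - 1), v=D - 1 + 6,
        )
        stat = lf.fit_pibble(Y, np.ones((1, T)), prior, S=1500, seed=4)
        lam_dyn = dyn.Theta_path[:, -1, 0, :]        # shared state, P-vector
        lam_stat = stat.Lambda[:, :, 0]
        assert np.max(np.abs(lam_dyn.mean(0) - lam_stat.mean(0))) < 0.1

    def test_seed_determinism(self, rng):
        Y = lf.CountMatrix(Y=rng.multinomial(100, [0.6, 0.4], size=5).T)
        a = lf.fit_gmdlm(Y, self._spec(5, 1), S=20, seed=8)
        b = lf.fit_gmdlm(Y, self._spec(5, 1), S=20, seed=8)
        np.testing.assert_array_equal(a.Theta_path, b.Theta_path)


class TestFitBasset:
    def test_constant_kernel_matches_intercept_only_pibble(self, rng):
        """A constant kernel Γ≡c is the intercept-only linear model with
        Γ=[[c]]: the collapsed forms coincide, so eta posteriors agree."""
        D, N = 3, 12
        Y = lf.CountMatrix(Y=rng.multinomial(300, [0.5, 0.3, 0.2], size=N).T)
        c = 0.8
        P = D - 1
        spec = lf.GMGPSpec(
            mean_fn=lambda ls: np.zeros((P, len(ls))),
            kernel_fn=lambda a, b: c,
            Xi=np.eye(P), v=D + 10,
        )
        locs = [float(t) for t in range(N)]
        gp = lf.fit_basset(Y, locs, spec, S=1500, seed=6)
        prior = lf.GMCLPrior(
            Theta=np.zeros((P, 1)), Gamma=np.array([[c]]),
            Xi=np.eye(P), v=D + 10,
        )
        lin = lf.fit_pibble(Y, np.ones((1, N)), prior, S=1500, seed=6)
        np.testing.assert_array_equal(gp.eta, lin.eta)  # identical collapse
        assert np.max(np.abs(gp.Lambda.mean(0).mean(axis=1)
                             - lin.Lambda.mean(0)[:, 0])) < 0.1

    def test_predictions_track_smoothed_eta(self, rng):
        D, N = 3, 10
        Y = lf.CountMatrix(Y=rng.multinomial(400, [0.5, 0.3, 0.2], size=N).T)
        P = D - 1
        spec = lf.GMGPSpec(
            mean_fn=lambda ls: np.zeros((P, len(ls))),
            kernel_fn=lambda a, b: lf.kernel_se(a, b, 2.0, 5.0),
            Xi=np.eye(P), v=D + 10,
        )
        locs = [float(t) for t in range(N)]
        dr = lf.fit_basset(Y, locs, spec, S=400, seed=6)
        resid = dr.Lambda.mean(0) - dr.eta.mean(0)
        assert np.max(np.abs(resid)) < 0.5

    def test_seed_determinism(self, rng):
        Y = lf.CountMatrix(Y=rng.multinomial(100, [0.6, 0.4], size=4).T)
        spec = lf.GMGPSpec(
            mean_fn=lambda ls: np.zeros((1, len(ls))),
            kernel_fn=lambda a, b: lf.kernel_se(a, b, 1.0, 1.0),
            Xi=np.eye(1), v=5,
        )
        locs = [0.0, 1.0, 2.0, 3.0]
        a = lf.fit_basset(Y, locs, spec, S=30, seed=1)
        b = lf.fit_basset(Y, locs, spec, S=30, seed=1)
        np.testing.assert_array_equal(a.Lambda, b.Lambda)


class TestSummarize:
    def test_mean_inside_interval_and_clr_centering(self, pibble_draws):
        tab = lf.summarize(pibble_draws, levels=(0.5, 0.95), coord="clr")
        assert np.all(tab["lower_95"] <= tab["mean"])
        assert np.all(tab["mean"] <= tab["upper_95"])
        per_cov = tab.groupby("covariate")["mean"].sum()
        np.testing.assert_allclose(per_cov.to_numpy(), 0.0, atol=1e-8)

    def test_excludes_zero_flag(self):
        eta = np.zeros((5, 1, 1))
        lam = np.linspace(1.0, 2.0, 5).reshape(5, 1, 1)
        draws = lf.PosteriorDraws(
            eta=eta, Sigma=np.ones((5, 1, 1)), Lambda=lam,
            coord_system="alr", alr_ref_index=1,
        )
        tab = lf.summarize(draws, levels=(0.95,), coord="alr")
        assert bool(tab["excludes_zero_95"].iloc[0])

    def test_invariant_to_draw_order(self, pibble_draws, rng):
        perm = rng.permutation(pibble_draws.S)
        shuffled = lf.PosteriorDraws(
            eta=pibble_draws.eta[perm],
            Sigma=pibble_draws.Sigma[perm],
            Lambda=pibble_draws.Lambda[perm],
            coord_system="alr", alr_ref_index=pibble_draws.alr_ref_index,
        )
        pd.testing.assert_frame_equal(
            lf.summarize(pibble_draws), lf.summarize(shuffled)
        )


class TestIO:
    def test_count_table_round_trip(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("taxon\ts1\ts2\nA\t3\t0\nB\t1\t2\nC\t0\t5\n")
        Y = lf.read_counts(path)
        np.testing.assert_array_equal(Y.Y, [[3, 0], [1, 2], [0, 5]])
        assert Y.row_labels == ("A", "B", "C")
        assert Y.col_labels == ("s1", "s2")

    def test_negative_count_rejected_with_position(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("taxon\ts1\nA\t3\nB\t-1\n")
        with pytest.raises(ValueError, match="line 3"):
            lf.read_counts(path)

    def test_duplicate_labels_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("taxon\ts1\ts1\nA\t3\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            lf.read_counts(path)

    def test_covariate_label_mismatch_names_offenders(self, tmp_path):
        cpath = tmp_path / "counts.tsv"
        cpath.write_text("taxon\ts1\ts2\nA\t3\t1\nB\t1\t2\n")
        xpath = tmp_path / "X.tsv"
        xpath.write_text("cov\ts1\ts3\nx1\t0.1\t0.2\n")
        Y = lf.read_counts(cpath)
        with pytest.raises(ValueError, match="s3"):
            lf.read_covariates(xpath, counts=Y)

    def test_draws_round_trip_exact(self, tmp_path, pibble_draws):
        lf.write_draws(pibble_draws, tmp_path / "run")
        back = lf.read_draws(tmp_path / "run")
        for name in ("eta", "Lambda", "Sigma", "pi"):
            np.testing.assert_array_equal(
                getattr(back, name), getattr(pibble_draws, name)
            )
        assert back.coord_system == pibble_draws.coord_system
        assert back.alr_ref_index == pibble_draws.alr_ref_index

    def test_missing_sidecar_fails_loudly(self, tmp_path, pibble_draws):
        lf.write_draws(pibble_draws, tmp_path / "run")
        (tmp_path / "run" / "meta.json").unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            lf.read_draws(tmp_path / "run")


class TestCLI:
    def test_simulate_fit_summarize_pipeline(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "--N", "8", "--D", "3", "--Q", "2",
            "--seed", "5", "--n-total", "200", "--out", str(sim),
        ])
        assert r.exit_code == 0, r.output
        run = tmp_path / "run"
        r = runner.invoke(cli_main, [
            "fit-pibble", "--counts", str(sim / "counts.tsv"),
            "--covariates", str(sim / "X.tsv"),
            "--draws", "60", "--seed", "1", "--out", str(run),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "summarize", "--draws", str(run), "--level", "0.95",
            "--out", str(tmp_path / "summary.tsv"),
        ])
        assert r.exit_code == 0, r.output
        tab = pd.read_csv(tmp_path / "summary.tsv", sep="\t")
        assert {"coordinate", "covariate", "mean"} <= set(tab.columns)

    def test_validation_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("taxon\ts1\nA\t-3\n")
        x = tmp_path / "x.tsv"
        x.write_text("cov\ts1\nx1\t1.0\n")
        r = CliRunner().invoke(cli_main, [
            "fit-pibble", "--counts", str(bad), "--covariates", str(x),
            "--out", str(tmp_path / "o"),
        ])
        assert r.exit_code == 2
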