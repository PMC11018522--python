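"""Multivariate shrinkage: EM, covariance library, posteriors, LFSR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sceqtl import shrinkage
from sceqtl.shrinkage import (
    EffectPanel,
    MashFit,
    build_covariances,
    canonical_covariances,
    default_omega_grid,
    estimate_null_correlation,
    fit_mixture,
    panel_from_assoc,
    posterior,
    select_strong,
    univariate_lfsr,
)


def _panel(bhat, shat):
    bhat = np.atleast_2d(np.asarray(bhat, float))
    shat = np.broadcast_to(np.asarray(shat, float), bhat.shape).copy()
    ids = pd.DataFrame({"gene": [f"g{i}" for i in range(bhat.shape[0])], "snp": "s"})
    return EffectPanel(bhat=bhat, shat=shat, ids=ids,
                       conditions=[f"c{r}" for r in range(bhat.shape[1])])


class TestPanelConstruction:
    def test_missing_entries_get_huge_se(self):
        tab = pd.DataFrame(
            {
                "cell_type": ["a", "a", "b"],
                "gene": ["g1", "g2", "g1"],
                "snp": ["s", "s", "s"],
                "beta": [1.0, 2.0, 3.0],
                "se": [0.1, 0.1, 0.1],
            }
        )
        panel = panel_from_assoc(tab)
        assert panel.bhat.shape == (2, 2)
        obs = panel.observed()
        assert obs.sum() == 3
        assert (panel.shat[~obs] > 1e5).all()

    def test_dof_column_inflates_tail_ses(self):
        tab = pd.DataFrame(
            {
                "cell_type": ["a", "a"],
                "gene": ["g1", "g2"],
                "snp": ["s", "s"],
                "beta": [5.0, 0.05],
                "se": [1.0, 1.0],
                "dof": [10, 10],
            }
        )
        panel = panel_from_assoc(tab)
        # |t| = 5 at 10 dof is much less surprising than |z| = 5
        assert panel.shat[panel.ids["gene"] == "g1"][0, 0] > 1.0
        # near-null entries are essentially unchanged
        assert panel.shat[panel.ids["gene"] == "g2"][0, 0] == pytest.approx(1.0, rel=0.05)


class TestMixtureFit:
    def test_single_component_gets_all_weight(self, rng):
        bhat = rng.standard_normal((200, 2))
        panel = _panel(bhat, 0.5)
        fit = fit_mixture(panel, {"equal": np.ones((2, 2))}, omega_grid=np.array([1.0]))
        assert fit.pi.sum() == pytest.approx(1.0)
        assert (fit.pi >= 0).all()

    def test_em_loglik_nondecreasing(self, rng):
        bhat = rng.standard_normal((300, 3))
        panel = _panel(bhat, 0.4)
        lib = canonical_covariances(3)
        comps = [(-1, 0.0)] + [(i, w) for i in range(len(lib)) for w in (0.5, 2.0)]
        ll = shrinkage._loglik_matrix(panel, comps, list(lib.values()), np.eye(3))
        k = ll.shape[1]
        pi = np.full(k, 1.0 / k)
        prev = -np.inf
        for _ in range(25):
            logw = ll + np.log(pi)
            m = logw.max(axis=1, keepdims=True)
            w = np.exp(logw - m)
            tot = w.sum(axis=1, keepdims=True)
            cur = float((np.log(tot) + m).sum())
            assert cur >= prev - 1e-9
            prev = cur
            pi = (w / tot).mean(axis=0)

    def test_two_component_weight_recovery(self, rng):
        """pi recovered within 0.05 for a 0.7 null + 0.3 equal-effects mix."""
        t, r = 4000, 3
        sig = rng.random(t) < 0.3
        b = np.zeros((t, r))
        b[sig] = rng.standard_normal(sig.sum())[:, None]
        s = 0.25
        bhat = b + s * rng.standard_normal((t, r))
        panel = _panel(bhat, s)
        fit = fit_mixture(panel, {"equal": np.ones((r, r))}, seed=1)
        assert fit.pi[0] == pytest.approx(0.7, abs=0.05)


class TestCovarianceLibrary:
    def test_single_condition_collapses_to_scalar(self):
        lib = build_covariances(np.random.default_rng(0).standard_normal((20, 1)))
        assert list(lib) == ["equal"]
        assert lib["equal"].shape == (1, 1)

    def test_recovers_planted_shared_covariance(self, rng):
        """Leading data-driven matrix aligns with the generating covariance."""
        r = 4
        u_true = np.ones((r, r)) + 0.5 * np.eye(r)
        chol = np.linalg.cholesky(u_true)
        b = (chol @ rng.standard_normal((r, 400))).T
        s = np.full((400, r), 0.1)
        bhat = b + s * rng.standard_normal((400, r))
        lib = build_covariances(bhat, s, n_pcs=2, ed_iters=20)
        lead = lib["ed_rank"]
        cos = np.sum(lead * u_true) / (np.linalg.norm(lead) * np.linalg.norm(u_true))
        assert cos >= 0.9

    def test_all_outputs_symmetric_psd(self, rng):
        bhat = rng.standard_normal((100, 5)) * 2
        s = np.full((100, 5), 0.3)
        lib = build_covariances(bhat, s, n_pcs=3, ed_iters=10)
        for name, u in lib.items():
            np.testing.assert_allclose(u, u.T, atol=1e-10, err_msg=name)
            w = np.linalg.eigvalsh(u)
            assert w.min() >= -1e-8, name


class TestNullCorrelation:
    def test_independent_columns_give_identity(self, rng):
        panel = _panel(rng.standard_normal((500, 4)) * 0.3, 1.0)
        v = estimate_null_correlation(panel)
        assert np.abs(v - np.eye(4)).max() < 0.15

    def test_duplicated_columns_detected(self, rng):
        z = rng.standard_normal(500) * 0.5
        panel = _panel(np.column_stack([z, z]), 1.0)
        v = estimate_null_correlation(panel)
        assert v[0, 1] > 0.95

    def test_too_few_nulls_returns_identity(self, rng):
        panel = _panel(rng.standard_normal((5, 4)) * 50, 1.0)
        np.testing.assert_array_equal(estimate_null_correlation(panel), np.eye(4))


class TestSelectStrong:
    def test_overwhelming_signals_selected(self, rng):
        bhat = rng.standard_normal((300, 2)) * 0.1
        strong_rows = np.arange(10)
        bhat[strong_rows, 0] = 8.0
        panel = _panel(bhat, 1.0)
        idx = select_strong(panel, lfsr_threshold=0.1)
        assert set(strong_rows).issubset(set(idx))

    def test_null_panel_raises(self, rng):
        panel = _panel(rng.standard_normal((200, 2)) * 0.05, 1.0)
        with pytest.raises(ValueError):
            select_strong(panel, lfsr_threshold=0.01)

    def test_matches_quadrature_oracle_on_toy_panel(self, rng):
        """Univariate LFSR agrees with direct numerical integration of the
        fitted mixture posterior on a 50-test panel."""
        bhat = np.concatenate([rng.standard_normal(40) * 0.2, rng.standard_normal(10) * 4])
        s = 0.5
        lfsr = univariate_lfsr(bhat, np.full(50, s))
        # rebuild the same mixture fit, then integrate the posterior per test
        panel = _panel(bhat[:, None], s)
        grid = default_omega_grid(panel)
        one = np.ones((1, 1))
        comps = [(-1, 0.0)] + [(0, float(w)) for w in grid]
        ll = shrinkage._loglik_matrix(panel, comps, [one], np.eye(1))
        pi, _ = shrinkage._em_weights(ll)
        for t in range(50):
            logw = ll[t] + np.log(np.maximum(pi, 1e-300))
            w = np.exp(logw - logw.max())
            w /= w.sum()
            p_neg = p_zero = 0.0
            for (ui, om), wt in zip(comps, w):
                if ui < 0:
                    p_zero += wt
                    continue
                post_var = 1.0 / (1.0 / om + 1.0 / s**2)
                post_mean = post_var * bhat[t] / s**2
                xs = np.linspace(post_mean - 10 * np.sqrt(post_var), 0, 4001)
                dens = stats.norm.pdf(xs, post_mean, np.sqrt(post_var))
                p_neg += wt * np.trapezoid(dens, xs)
            want = min(p_neg + p_zero, 1 - p_neg)
            assert lfsr[t] == pytest.approx(want, abs=1e-3)


class TestPosterior:
    def test_zero_observation_gives_maximal_sign_uncertainty(self):
        panel = _panel(np.zeros((5, 2)), 0.5)
        lib = {"equal": np.ones((2, 2))}
        fit = fit_mixture(panel, lib, omega_grid=np.array([1.0]))
        mean, sd, lfsr = posterior(panel, fit)
        np.testing.assert_allclose(mean, 0.0, atol=1e-8)
        # sign is maximally uncertain: such tests can never be called
        assert (lfsr >= 0.5 - 1e-9).all()

    def test_single_component_closed_form(self):
        """One condition, one prior N(0, w): posterior mean b*w/(w+s^2) and
        lfsr = Phi(-|mean|/sd)."""
        b, s, om = 1.2, 0.5, 2.0
        panel = _panel([[b]], s)
        fit = MashFit(
            u_names=["one"], u_list=[np.ones((1, 1))], omega_grid=np.array([om]),
            components=[(0, om)], pi=np.array([1.0]), v=np.eye(1), loglik=0.0,
            conditions=["c0"],
        )
        mean, sd, lfsr = posterior(panel, fit)
        want_mean = b * om / (om + s**2)
        want_var = om * s**2 / (om + s**2)
        assert mean[0, 0] == pytest.approx(want_mean, abs=1e-10)
        assert sd[0, 0] == pytest.approx(np.sqrt(want_var), abs=1e-10)
        assert lfsr[0, 0] == pytest.approx(stats.norm.cdf(-want_mean / np.sqrt(want_var)), abs=1e-10)

    def test_posterior_shrinks_toward_zero(self, rng):
        bhat = rng.standard_normal((100, 1)) * 2
        panel = _panel(bhat, 0.7)
        lib = {"equal": np.ones((1, 1))}
        fit = fit_mixture(panel, lib, seed=0)
        mean, _, _ = posterior(panel, fit)
        assert (np.abs(mean[:, 0]) <= np.abs(bhat[:, 0]) + 1e-12).all()

    def test_forced_null_weight(self, rng):
        panel = _panel(rng.standard_normal((20, 3)), 0.5)
        lib = canonical_covariances(3)
        fit = fit_mixture(panel, lib, seed=0)
        fit.pi = np.zeros_like(fit.pi)
        fit.pi[0] = 1.0  # all mass on the null component
        mean, sd, lfsr = posterior(panel, fit)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)
        assert (lfsr >= 0.5 - 1e-12).all()

    def test_lfsr_within_unit_interval(self, rng):
        bhat = rng.standard_normal((200, 4)) * 3
        panel = _panel(bhat, 0.5)
        fit, mean, sd, lfsr = shrinkage.mash_pipeline(panel, ed_iters=5, seed=0)
        assert (lfsr >= 0).all() and (lfsr <= 1).all()
        assert (fit.pi >= 0).all()
        assert fit.pi.sum() == pytest.approx(1.0)
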