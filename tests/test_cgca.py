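"""Conditional Granger causality: VAR fitting, order selection, influence terms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsncausal import cgca
from rsncausal import synthetic as syn


def _var1(A, T, noise_sd=1.0, seed=0, burn=100):
    rng = np.random.default_rng(seed)
    d = A.shape[0]
    x = np.zeros((T + burn, d))
    eps = rng.normal(scale=noise_sd, size=(T + burn, d))
    x[0] = eps[0]
    for t in range(1, T + burn):
        x[t] = A @ x[t - 1] + eps[t]
    out = x[burn:]
    return out - out.mean(axis=0)


class TestFitVar:
    def test_noiseless_var1_recovered_exactly(self):
        # rotation-like dynamics keep the design well conditioned while the
        # recursion x_t = A x_{t-1} holds exactly, so OLS must return A
        rng = np.random.default_rng(0)
        A = np.array([[0.9, 0.2], [-0.3, 0.8]])
        x = np.zeros((14, 2))
        x[0] = rng.standard_normal(2)
        for t in range(1, 14):
            x[t] = A @ x[t - 1]
        fit = cgca.fit_var(x, 1)
        assert np.allclose(fit.coefficients[0], A, atol=1e-8)
        assert np.allclose(fit.residual_cov, 0.0, atol=1e-12)

    def test_white_noise_coefficients_vanish(self):
        x = np.random.default_rng(1).standard_normal((2000, 2))
        fit = cgca.fit_var(x - x.mean(0), 1)
        assert np.abs(fit.coefficients).max() < 0.1

    def test_matches_explicit_normal_equations(self):
        # oracle: (X^T X)^{-1} X^T Y on a 12-point bivariate series
        rng = np.random.default_rng(2)
        ts = rng.standard_normal((12, 2))
        fit = cgca.fit_var(ts, 1)
        Y = ts[1:]
        X = ts[:-1]
        coef = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(fit.coefficients[0], coef.T, atol=1e-10)
        resid = Y - X @ coef
        assert np.allclose(fit.residual_cov, resid.T @ resid / 11, atol=1e-10)
        assert fit.n_effective == 11

    def test_ill_conditioned_design_rejected(self):
        t = np.linspace(0, 1, 50)
        ts = np.column_stack([t, 2 * t])  # collinear columns
        with pytest.raises(np.linalg.LinAlgError, match="ill-conditioned"):
            cgca.fit_var(ts, 1)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            cgca.fit_var(np.zeros((5, 4)), 1)


class TestSelectOrderSc:
    def test_var1_data_selects_order_one(self):
        spec = syn.CouplingSpec()
        hits = 0
        for seed in range(10):
            ts = syn.simulate_network_timecourses(spec, 50.0, 250, seed=seed)
            hits += cgca.select_order_sc(ts - ts.mean(0), 5) == 1
        assert hits >= 9

    def test_var2_data_selects_order_two(self):
        A1 = np.array([[0.2, 0.0], [0.3, 0.2]])
        A2 = np.array([[0.5, 0.0], [0.0, 0.5]])
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.zeros((1100, 2))
            eps = rng.standard_normal((1100, 2))
            x[:2] = eps[:2]
            for t in range(2, 1100):
                x[t] = A1 @ x[t - 1] + A2 @ x[t - 2] + eps[t]
            hits += cgca.select_order_sc(x[100:] - x[100:].mean(0), 4) == 2
        assert hits >= 9

    def test_sc_tie_breaks_to_smaller_order(self, monkeypatch):
        # force identical criterion values for every order
        def fake_fit(ts, order, presample=None):
            return cgca.VARFit(order=order, coefficients=np.zeros((order, 2, 2)),
                               residual_cov=np.eye(2), n_effective=10, sc=1.0)
        monkeypatch.setattr(cgca, "fit_var", fake_fit)
        assert cgca.select_order_sc(np.zeros((50, 2)), 4) == 1


class TestConditionalGC:
    def test_independent_target_has_no_influence(self):
        x = np.random.default_rng(3).standard_normal((2000, 3))
        F = cgca.conditional_gc(x - x.mean(0), 0, 1, [2], 1)
        assert F < 2 * 3 * 1 / 2000  # parameter-count envelope

    def test_conditioning_removes_mediated_influence(self):
        # chain Z -> Y -> X: pairwise GC sees Z -> X, conditional does not
        rng = np.random.default_rng(5)
        T = 50_000
        e = rng.standard_normal((T, 3))
        x = np.zeros((T, 3))  # columns: Z, Y, X
        for t in range(1, T):
            x[t, 0] = 0.3 * x[t - 1, 0] + e[t, 0]
            x[t, 1] = 0.3 * x[t - 1, 1] + 0.6 * x[t - 1, 0] + e[t, 1]
            x[t, 2] = 0.3 * x[t - 1, 2] + 0.6 * x[t - 1, 1] + e[t, 2]
        x = x - x.mean(0)
        F_cond = cgca.conditional_gc(x, 0, 2, [1], 1)
        F_pair = cgca.conditional_gc(x, 0, 2, [], 1)
        assert F_pair > 0.005
        assert F_cond < 0.1 * F_pair

    def test_planted_coupling_detected_across_seeds(self):
        # independent oracle: two separate explicit OLS regressions
        def oracle_gc(ts, src, tgt, cond, m=1):
            cols_r = [tgt] + cond
            cols_f = [tgt] + cond + [src]
            out = []
            for cols in (cols_r, cols_f):
                sub = ts[:, cols]
                Y = sub[m:, 0]
                X = np.hstack([sub[m - l - 1: len(sub) - l - 1] for l in range(m)])
                beta = np.linalg.solve(X.T @ X, X.T @ Y)
                r = Y - X @ beta
                out.append(r @ r / len(Y))
            return np.log(out[0] / out[1])

        spec = syn.CouplingSpec()
        Fs = []
        for seed in range(20):
            ts = syn.simulate_network_timecourses(spec, 47.0, 250, seed=seed)
            ts = ts - ts.mean(0)
            F = cgca.conditional_gc(ts, 2, 3, [0, 1], 1)  # AfN -> VN
            assert F == pytest.approx(oracle_gc(ts, 2, 3, [0, 1]), abs=1e-10)
            Fs.append(F)
        t = stats.ttest_1samp(Fs, 0.0, alternative="greater")
        assert t.pvalue < 0.01

    def test_overlapping_sets_rejected(self):
        x = np.zeros((50, 3))
        with pytest.raises(ValueError, match="disjoint"):
            cgca.conditional_gc(x, 0, 0, [1], 1)

    def test_scale_invariance(self):
        spec = syn.CouplingSpec()
        ts = syn.simulate_network_timecourses(spec, 50.0, 250, seed=8)
        ts = ts - ts.mean(0)
        F0 = cgca.conditional_gc(ts, 2, 3, [0, 1], 1)
        ts2 = ts.copy()
        ts2[:, 2] *= 1234.5
        F1 = cgca.conditional_gc(ts2, 2, 3, [0, 1], 1)
        assert abs(F0 - F1) < 1e-10


class TestGcAllPairs:
    def test_twelve_entries_no_diagonal(self):
        x = np.random.default_rng(0).standard_normal((300, 4))
        gm = cgca.gc_all_pairs(x, 1)
        assert np.isnan(np.diag(gm.F)).all()
        off = gm.F[~np.eye(4, dtype=bool)]
        assert len(off) == 12
        assert np.isfinite(off).all()
        assert (off >= 0).all()
        assert len(gm.to_frame()) == 12

    def test_global_null_envelope(self):
        x = np.random.default_rng(1).standard_normal((2000, 4))
        gm = cgca.gc_all_pairs(x - x.mean(0), 1)
        off = gm.F[~np.eye(4, dtype=bool)]
        # T*F ~ chi2(1) under the null; Bonferroni envelope over 12 edges
        assert (off < stats.chi2.ppf(1 - 0.01 / 12, 1) / 2000).all()

    def test_planted_edges_have_largest_mean_influence(self):
        spec = syn.CouplingSpec()
        names = spec.names
        Fsum = np.zeros((4, 4))
        for seed in range(20):
            ts = syn.simulate_network_timecourses(spec, 50.0, 250, seed=100 + seed)
            Fsum += np.nan_to_num(cgca.gc_all_pairs(ts, 1, names).F)
        mean_F = Fsum / 20
        planted = [("AfN", "VN"), ("DAN", "VAN"), ("AfN", "VAN"), ("DAN", "VN")]
        planted_idx = {(names.index(t), names.index(s)) for s, t in planted}
        order = np.argsort(mean_F, axis=None)[::-1][:4]
        top4 = {tuple(np.unravel_index(i, (4, 4))) for i in order}
        assert top4 == planted_idx


class TestGcNormalize:
    def test_strong_edge_z_large(self):
        spec = syn.CouplingSpec()
        ts = syn.simulate_network_timecourses(spec, 25.0, 250, seed=3)
        ts = ts - ts.mean(0)
        F = cgca.conditional_gc(ts, 2, 3, [0, 1], 1)
        z = cgca.gc_normalize(F, ts, 2, 3, [0, 1], 1, n_surrogates=99, seed=0)
        assert z > 3

    def test_null_edge_z_centered(self):
        zs = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((250, 3))
            x = x - x.mean(0)
            F = cgca.conditional_gc(x, 0, 1, [2], 1)
            zs.append(cgca.gc_normalize(F, x, 0, 1, [2], 1,
                                        n_surrogates=49, seed=seed))
        assert abs(np.mean(zs)) < 0.5

    def test_deterministic_for_seed(self):
        spec = syn.CouplingSpec()
        ts = syn.simulate_network_timecourses(spec, 50.0, 250, seed=4)
        ts = ts - ts.mean(0)
        F = cgca.conditional_gc(ts, 2, 3, [0, 1], 1)
        a = cgca.gc_normalize(F, ts, 2, 3, [0, 1], 1, 49, seed=7)
        b = cgca.gc_normalize(F, ts, 2, 3, [0, 1], 1, 49, seed=7)
        assert a == b

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            cgca.gc_normalize(0.1, np.zeros((100, 3)), 0, 1, [2], 1,
                              n_surrogates=5, seed=0)


class TestGroupGcTest:
    @staticmethod
    def _table(zmat, names=("A", "B", "C")):
        rows = []
        for s, z in enumerate(zmat):
            k = 0
            for i, tgt in enumerate(names):
                for j, src in enumerate(names):
                    if i == j:
                        continue
                    rows.append({"subject_id": f"s{s}", "source": src,
                                 "target": tgt, "z": z[k]})
                    k += 1
        return pd.DataFrame(rows)

    def test_null_cohort_fdr_controlled(self):
        n_sig = []
        for run in range(50):
            rng = np.random.default_rng(run)
            tab = self._table(rng.standard_normal((12, 6)))
            out = cgca.group_gc_test(tab, q=0.05)
            n_sig.append(out.significant.sum())
        assert np.mean(n_sig) <= 0.05 * 6

    def test_single_strong_edge_detected(self):
        hits = 0
        for run in range(20):
            rng = np.random.default_rng(100 + run)
            z = rng.standard_normal((12, 6))
            z[:, 0] += 4.0  # one strongly positive edge
            out = cgca.group_gc_test(self._table(z), q=0.05)
            sig = out[out.significant]
            hits += len(sig) == 1 and sig.iloc[0]["mean_z"] > 2
        assert hits >= 18  # >= 90% of seeds

    def test_planted_cohort_edges_recovered(self):
        spec = syn.CouplingSpec()
        frames = []
        rng = np.random.default_rng(0)
        for s in range(10):
            score = float(rng.integers(46, 66))
            ts = syn.simulate_network_timecourses(spec, score, 250,
                                                  seed=int(rng.integers(2**31)))
            gm = cgca.gc_all_pairs_normalized(ts, 1, n_surrogates=49, seed=s)
            frames.append(gm.to_frame(subject_id=f"s{s}"))
        out = cgca.group_gc_test(pd.concat(frames, ignore_index=True), q=0.05)
        sig = {(r.source, r.target) for r in out[out.significant].itertuples()
               if r.mean_z > 0}
        assert {("AfN", "VAN"), ("AfN", "VN"), ("DAN", "VN"),
                ("DAN", "VAN")} <= sig
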