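"""CWRES bias-model tests: base/extended ML fits and the Delta-OFV test.

Oracle: a brute-force likelihood evaluation with explicit per-subject
compound-symmetry covariance matrices, minimised by dense grid refinement —
fully independent of the profiled/Woodbury implementation.
"""

import numpy as np
import pytest
from scipy.stats import chi2

from cwresqa.biasmodel import BiasFit, CWRESGrouped, bias_test, fit_base, fit_extended
from cwresqa.binning import BinSpec, density_bins


def make_grouped(values_per_subject, idv_per_subject, dv="glucose", idv_name="TIME"):
    n = len(values_per_subject)
    return CWRESGrouped(
        dv_label=dv,
        idv_name=idv_name,
        subject_ids=tuple(range(1, n + 1)),
        values=tuple(values_per_subject),
        idv=tuple(idv_per_subject),
        obs_index=tuple(np.arange(len(v)) for v in values_per_subject),
    )


def simulate_grouped(rng, n_subj, n_obs, theta=0.0, w2=0.0, s2=1.0, bin_shift=None):
    """CWRES-like data from the compound-symmetry model itself."""
    idv = np.arange(n_obs, dtype=float)
    values, idvs = [], []
    for _ in range(n_subj):
        y = theta + rng.normal(0, np.sqrt(w2)) + rng.normal(0, np.sqrt(s2), n_obs)
        if bin_shift is not None:
            cut, shift = bin_shift
            y = y + np.where(idv < cut, shift, 0.0)
        values.append(y)
        idvs.append(idv.copy())
    return make_grouped(values, idvs)


def brute_force_ofv(grouped, bins, theta_vec, w2, s2):
    """Direct -2LL with explicit covariance matrices (2*pi dropped)."""
    total = 0.0
    for v, x in zip(grouped.values, grouped.idv):
        n = v.size
        mu = (
            np.full(n, theta_vec[0])
            if bins is None
            else np.asarray(theta_vec)[bins.assign(x)]
        )
        V = w2 * np.ones((n, n)) + s2 * np.eye(n)
        r = v - mu
        _, logdet = np.linalg.slogdet(V)
        total += logdet + r @ np.linalg.solve(V, r)
    return total


class TestFitBase:
    def test_null_cwres_recovers_standard_normal(self):
        rng = np.random.default_rng(21)
        grouped = simulate_grouped(rng, 100, 32)
        fit = fit_base(grouped)
        assert fit.means[0] == pytest.approx(0.0, abs=0.05)
        assert fit.omega <= 0.05
        assert 0.9 <= fit.sigma <= 1.1

    def test_degenerate_all_equal_hits_boundary(self):
        grouped = make_grouped(
            [np.full(4, 0.7)] * 3, [np.arange(4.0)] * 3
        )
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_base(grouped)
        assert fit.means[0] == pytest.approx(0.7, abs=1e-6)
        assert fit.boundary  # at least one variance pinned at the floor

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(22)
        grouped = simulate_grouped(rng, 10, 6, theta=0.5, w2=0.2, s2=1.0)
        fit = fit_base(grouped)
        # dense grid around plausible values, refined once
        best = np.inf
        center = (fit.means[0], max(fit.omega, 1e-4), fit.sigma)
        for scale in (0.5, 0.1, 0.02):
            th_g = np.linspace(center[0] - scale, center[0] + scale, 11)
            w_g = np.linspace(max(center[1] - scale, 1e-8), center[1] + scale, 11)
            s_g = np.linspace(max(center[2] - scale, 1e-3), center[2] + scale, 11)
            for th in th_g:
                for w in w_g:
                    for s in s_g:
                        val = brute_force_ofv(grouped, None, [th], w, s)
                        if val < best:
                            best, center = val, (th, w, s)
        assert fit.ofv == pytest.approx(best, abs=1e-3)

    def test_requires_two_subjects(self):
        grouped = make_grouped([np.arange(3.0)], [np.arange(3.0)])
        with pytest.raises(ValueError, match="2 subjects"):
            fit_base(grouped)


class TestFitExtended:
    def test_single_bin_identical_to_base(self):
        rng = np.random.default_rng(23)
        grouped = simulate_grouped(rng, 20, 8, w2=0.1)
        bins = BinSpec(idv_name="TIME", boundaries=np.array([]), n_bins=1, min_per_bin=1)
        base = fit_base(grouped)
        ext = fit_extended(grouped, bins)
        assert ext.ofv == pytest.approx(base.ofv, abs=1e-6)
        assert ext.means[0] == pytest.approx(base.means[0], abs=1e-6)

    def test_recovers_injected_bin_bias(self):
        rng = np.random.default_rng(24)
        grouped = simulate_grouped(rng, 200, 10, bin_shift=(2.0, 0.5))
        bins = BinSpec(
            idv_name="TIME", boundaries=np.array([1.5, 4.5, 7.5]),
            n_bins=4, min_per_bin=1,
        )
        ext = fit_extended(grouped, bins)
        assert ext.means[0] == pytest.approx(0.5, abs=0.12)
        np.testing.assert_allclose(ext.means[1:], 0.0, atol=0.12)

    def test_nested_ofv_never_worse(self):
        rng = np.random.default_rng(25)
        for trial in range(5):
            grouped = simulate_grouped(rng, 15, 12, w2=0.3)
            bins = density_bins(grouped.all_idv, 3, min_per_bin=2, idv_name="TIME")
            assert fit_extended(grouped, bins).ofv <= fit_base(grouped).ofv + 1e-3

    def test_empty_bin_is_an_error(self):
        grouped = simulate_grouped(np.random.default_rng(26), 5, 4)
        bins = BinSpec(
            idv_name="TIME", boundaries=np.array([0.5, 0.6]), n_bins=3, min_per_bin=1
        )
        with pytest.raises(ValueError, match="empty IDV bin"):
            fit_extended(grouped, bins)

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(27)
        grouped = simulate_grouped(rng, 10, 6, w2=0.1, bin_shift=(3.0, 0.6))
        bins = BinSpec(idv_name="TIME", boundaries=np.array([2.5]), n_bins=2, min_per_bin=1)
        ext = fit_extended(grouped, bins)
        best = np.inf
        center = (ext.means[0], ext.means[1], max(ext.omega, 1e-4), ext.sigma)
        for scale in (0.3, 0.06, 0.012):
            grids = [np.linspace(c - scale, c + scale, 9) for c in center[:2]]
            grids.append(np.linspace(max(center[2] - scale, 1e-8), center[2] + scale, 9))
            grids.append(np.linspace(max(center[3] - scale, 1e-3), center[3] + scale, 9))
            for t1 in grids[0]:
                for t2 in grids[1]:
                    for w in grids[2]:
                        for s in grids[3]:
                            val = brute_force_ofv(grouped, bins, [t1, t2], w, s)
                            if val < best:
                                best, center = val, (t1, t2, w, s)
        assert ext.ofv == pytest.approx(best, abs=1e-3)


class TestBiasTest:
    def test_chi_square_rule(self):
        base = BiasFit(np.array([0.0]), 0.0, 1.0, ofv=110.0, converged=True)
        ext = BiasFit(np.zeros(5), 0.0, 1.0, ofv=95.0, converged=True)
        t = bias_test(base, ext, df=5)
        assert t.delta_ofv == pytest.approx(15.0)
        assert t.critical_value == pytest.approx(chi2.ppf(0.95, 5), abs=1e-6)
        assert t.critical_value == pytest.approx(11.07, abs=0.01)
        assert t.significant

    def test_identical_fits_not_significant(self):
        base = BiasFit(np.array([0.1]), 0.0, 1.0, ofv=100.0, converged=True)
        ext = BiasFit(np.full(3, 0.1), 0.0, 1.0, ofv=100.0, converged=True)
        t = bias_test(base, ext)
        assert t.delta_ofv == 0.0
        assert not t.significant
        assert t.df == 3  # defaults to the number of bins

    def test_negative_delta_flags_refit(self):
        base = BiasFit(np.array([0.0]), 0.0, 1.0, ofv=100.0, converged=True)
        ext = BiasFit(np.zeros(2), 0.0, 1.0, ofv=100.5, converged=True)
        with pytest.warns(UserWarning, match="refit"):
            t = bias_test(base, ext)
        assert t.refit_needed

    def test_null_rejection_rate_is_calibrated(self):
        # under the null, Delta-OFV tested at chi2(N) is slightly conservative
        rng = np.random.default_rng(28)
        n_rej, reps = 0, 100
        for _ in range(reps):
            grouped = simulate_grouped(rng, 20, 10)
            bins = density_bins(grouped.all_idv, 5, min_per_bin=2, idv_name="TIME")
            t = bias_test(fit_base(grouped), fit_extended(grouped, bins))
            n_rej += t.significant
        assert n_rej / reps <= 0.12
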