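"""Robust correlation, connectomes, Fisher z, biweight efficiency utilities."""

import numpy as np
import pytest

import optoconn as oc
from optoconn.errors import DataError
from optoconn.connectivity import RobustCorrParams


def _bivariate(rng, n, rho):
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


class TestRobustCorrelation:
    def test_identical_series_give_one(self, rng):
        x = rng.standard_normal(500)
        assert oc.robust_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_pearson_on_clean_gaussian(self, rng):
        x, y = _bivariate(rng, 5000, 0.5)
        plain = np.corrcoef(x, y)[0, 1]
        robust = oc.robust_correlation(x, y)
        assert abs(robust - plain) < 0.02

    def test_beats_pearson_under_contamination(self, rng):
        """1% outlier pairs at 20 SD: robust stays closer to rho in >=95% of reps."""
        wins = 0
        reps = 200
        for _ in range(reps):
            x, y = _bivariate(rng, 1000, 0.5)
            idx = rng.choice(1000, size=10, replace=False)
            x[idx] += 20 * rng.choice([-1, 1], size=10)
            y[idx] += 20 * rng.choice([-1, 1], size=10)
            plain = np.corrcoef(x, y)[0, 1]
            robust = oc.robust_correlation(x, y)
            wins += abs(robust - 0.5) < abs(plain - 0.5)
        assert wins / reps >= 0.95

    def test_large_k_converges_to_pearson(self, rng):
        x, y = _bivariate(rng, 2000, 0.3)
        plain = np.corrcoef(x, y)[0, 1]
        robust = oc.robust_correlation(x, y, RobustCorrParams(k=1e6))
        assert abs(robust - plain) < 1e-6

    def test_symmetric_and_affine_invariant(self, rng):
        x, y = _bivariate(rng, 800, 0.4)
        r = oc.robust_correlation(x, y)
        assert oc.robust_correlation(y, x) == pytest.approx(r, abs=1e-12)
        assert oc.robust_correlation(3.0 * x + 7.0, 0.5 * y - 2.0) == pytest.approx(
            r, abs=1e-10
        )

    def test_constant_input_rejected(self, rng):
        with pytest.raises(DataError):
            oc.robust_correlation(np.ones(100), rng.standard_normal(100))

    def test_matrix_matches_pairwise_loop(self, rng):
        X = rng.standard_normal((5, 400))
        R = oc.robust_correlation_matrix(X)
        for i in range(5):
            for j in range(i + 1, 5):
                assert R[i, j] == pytest.approx(
                    oc.robust_correlation(X[i], X[j]), abs=1e-12
                )
        assert np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0)

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((6, 300))
        perm = rng.permutation(6)
        R = oc.robust_correlation_matrix(X)
        Rp = oc.robust_correlation_matrix(X[perm])
        np.testing.assert_allclose(Rp, R[np.ix_(perm, perm)], atol=1e-12)


class TestConnectome:
    def test_46_channels_give_1035_pairs(self, rng):
        montage = oc.make_montage(46)
        hbo = rng.standard_normal((46, 300))
        hb = oc.HbSeries(hbo=hbo, hbr=-0.3 * hbo + 0.1 * rng.standard_normal((46, 300)),
                         fs_hz=8.93, montage=montage)
        co, cr = oc.build_connectome(hb)
        i, j = np.triu_indices(46, k=1)
        assert i.size == 1035
        assert co.r.shape == (46, 46) and cr.r.shape == (46, 46)
        assert len(co.to_edge_frame()) == 1035

    def test_noiseless_single_network_rank_one_pattern(self):
        from optoconn.simulate import NetworkSpec, PhysiologySpec, _bilateral_bump

        loading = _bilateral_bump(8, 0.5, 1.5)
        spec = oc.CohortSpec(
            n_groups=1, n_per_group=(1,), n_channels=8, n_samples=1024,
            networks=(NetworkSpec(loading=loading, subject_sd=0.0),),
            physiology=PhysiologySpec(cardiac=(2.3, 0.0), respiration=(0.6, 0.0),
                                      mayer=(0.1, 0.0), systemic=(0.0, 0.01, 0.08)),
            drift_sd=0.0, noise_sd=1e-6, hbr_noise_sd=1e-6, spike_rate=0.0, seed=4,
        )
        hb, _ = oc.generate_hb(spec, 0)
        loaded = np.flatnonzero(loading > 1e-3)
        R = oc.robust_correlation_matrix(hb.hbo[loaded])
        np.testing.assert_allclose(R, 1.0, atol=1e-3)

    def test_connectome_tracks_ground_truth(self):
        """Estimated connectome reproduces the realized neural correlation.

        Oracle conditions isolate the estimation chain: Gaussian network time
        courses (the biweight window legitimately clips super-Gaussian bursts,
        which is robustness behaviour, tested separately under contamination),
        no slow systemic component and no GSR (both alter the correlation
        structure itself), analysis window = full record, and network band
        above the reach of the polynomial drift block at this record length.
        """
        from dataclasses import replace as dc_replace

        from optoconn.simulate import PhysiologySpec, default_networks

        nets = tuple(
            dc_replace(n, band=(0.03, 0.08), bursty=False)
            for n in default_networks(16)
        )
        spec = oc.CohortSpec(
            n_groups=1, n_per_group=(6,), n_channels=16, n_samples=1500, seed=7,
            networks=nets, physiology=PhysiologySpec(systemic=(0.0, 0.01, 0.08)),
        )
        recs, truth = oc.generate_cohort(spec)
        i, j = np.triu_indices(16, k=1)
        errs = []
        for rec, gt in zip(recs, truth.subjects):
            hb = oc.preprocess_recording(
                rec, n_samples=1500, global_signal_regression=False,
                truncate_strategy=0,
            )
            co, _ = oc.build_connectome(hb)
            errs.append(np.abs(co.r[i, j] - gt.true_connectome[i, j]).mean())
        assert np.mean(errs) < 0.1


class TestFisherZ:
    def test_closed_forms(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        Z = oc.fisher_z(R)
        assert Z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert Z[0, 1] == pytest.approx(0.5493, abs=1e-4)
        assert Z[0, 0] == 0.0  # diagonal masked
        assert oc.fisher_z(np.array([[1.0, 0.0], [0.0, 1.0]]))[0, 1] == 0.0

    def test_round_trip(self, rng):
        R = np.clip(rng.uniform(-0.9, 0.9, size=(4, 4)), -1, 1)
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        Z = oc.fisher_z(R)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(np.tanh(Z[off]), R[off], atol=1e-12)

    def test_unit_correlation_clipped_with_warning(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="clipping"):
            Z = oc.fisher_z(R)
        assert np.isfinite(Z[0, 1])


class TestGroupMean:
    def test_identical_subjects_mean_equals_each(self, rng):
        X = rng.standard_normal((4, 200))
        hb = oc.HbSeries(hbo=X, hbr=-X, fs_hz=8.93, montage=oc.make_montage(4))
        co, _ = oc.build_connectome(hb)
        out = oc.group_mean_connectome([co, co, co], np.zeros(3))
        np.testing.assert_allclose(out[0.0][1], co.r, atol=1e-9)

    def test_empty_group_rejected(self, rng):
        X = rng.standard_normal((3, 100))
        hb = oc.HbSeries(hbo=X, hbr=-X, fs_hz=8.93, montage=oc.make_montage(3))
        co, _ = oc.build_connectome(hb)
        with pytest.raises(DataError):
            oc.group_mean_connectome([], np.array([]))

    def test_homotopic_pairs_stronger_than_background(self, small_subjects, small_cohort):
        _, truth = small_cohort
        conns = [oc.build_connectome(hb)[0] for hb in small_subjects]
        mean_r = oc.group_mean_connectome(conns, np.zeros(len(conns)))[0.0][1]
        pairs = truth.homotopic_edges()
        hom = np.mean([mean_r[i, j] for i, j in pairs])
        i, j = np.triu_indices(mean_r.shape[0], k=1)
        mask = np.ones(i.size, bool)
        for a, b in pairs:
            mask &= ~((i == a) & (j == b))
        assert hom > mean_r[i[mask], j[mask]].mean()


class TestBiweightEfficiency:
    def test_tuning_constant_for_95_percent(self):
        assert oc.tuning_constant_for_efficiency(0.95) == pytest.approx(4.685, abs=5e-4)

    def test_mc_efficiency_near_95(self):
        eff = oc.relative_efficiency_mc(n_reps=3000, n=1000, seed=1)
        assert eff == pytest.approx(95.0, abs=2.5)

    def test_biweight_location_resists_outliers(self, rng):
        x = rng.standard_normal(500)
        x[:5] += 50.0
        assert abs(oc.biweight_location(x)) < 0.2
        assert abs(x.mean()) > 0.4
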