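"""Subsegment ensembles, KSG MI, Eq-style surrogate correction, node strength."""

import numpy as np
import pytest

from periqeeg import (
    EnsembleConfig,
    Recording,
    corrected_matrix,
    interrelation_series,
    joe_normalize,
    ksg_mutual_information,
    node_strength,
    pearson_ensemble,
    subsegment_layout,
)
from periqeeg.interrelation import _mi_matrices
from tests.conftest import ar2_series


class TestLayout:
    def test_paper_protocol_layout(self):
        starts = subsegment_layout(4096, 1024, 10)
        assert list(starts) == [0, 341, 683, 1024, 1365, 1707, 2048, 2389, 2731, 3072]

    def test_full_length_subsegment(self):
        assert list(subsegment_layout(1024, 1024, 5)) == [0] * 5

    def test_two_subsegments_hit_endpoints(self):
        assert list(subsegment_layout(4096, 1024, 2)) == [0, 3072]

    def test_single_subsegment_centered(self):
        assert list(subsegment_layout(4096, 1024, 1)) == [1536]

    def test_too_long_subsegment_rejected(self):
        with pytest.raises(ValueError):
            subsegment_layout(512, 1024, 4)


class TestPearsonEnsemble:
    def test_identical_channels(self, rng):
        x = rng.normal(size=4096)
        offs = subsegment_layout(4096, 1024, 10)
        assert np.allclose(pearson_ensemble(x, x, offs, 1024), 1.0)

    def test_negated_channel(self, rng):
        x = rng.normal(size=4096)
        offs = subsegment_layout(4096, 1024, 10)
        assert np.allclose(pearson_ensemble(x, -x, offs, 1024), -1.0)

    def test_independent_noise_near_zero(self):
        meds = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=4096), r.normal(size=4096)
            offs = subsegment_layout(4096, 1024, 10)
            meds.append(np.median(pearson_ensemble(x, y, offs, 1024)))
        assert np.abs(meds).max() <= 0.1

    def test_zero_variance_subsegment_missing(self, rng):
        x = rng.normal(size=2048)
        y = x.copy()
        y[:1024] = 5.0
        vals = pearson_ensemble(x, y, np.array([0, 1024]), 1024)
        assert np.isnan(vals[0]) and np.isfinite(vals[1])


class TestKSG:
    def test_independent_gaussians_unbiased(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            vals.append(ksg_mutual_information(r.normal(size=1024), r.normal(size=1024), 3, r))
        assert abs(np.mean(vals)) <= 0.02

    def test_gaussian_closed_form(self):
        target = -0.5 * np.log(1 - 0.81)
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=2048)
            y = 0.9 * x + np.sqrt(1 - 0.81) * r.normal(size=2048)
            vals.append(ksg_mutual_information(x, y, 3, r))
        assert abs(np.mean(vals) - target) <= 0.05

    def test_near_deterministic_dependence_is_large(self, rng):
        x = rng.normal(size=1024)
        assert ksg_mutual_information(x, x.copy(), 3, rng) >= 3.0

    def test_duplicate_values_handled(self, rng):
        x = rng.integers(0, 4, size=512).astype(float)
        y = rng.integers(0, 4, size=512).astype(float)
        mi = ksg_mutual_information(x, y, 3, rng)
        assert np.isfinite(mi) and mi >= 0.0

    def test_agrees_with_sklearn_estimator(self):
        """Independent implementation of the same k-NN estimator (scikit-learn)."""
        pytest.importorskip("sklearn")
        from sklearn.feature_selection import mutual_info_regression

        r = np.random.default_rng(0)
        x = r.normal(size=2048)
        y = 0.8 * x + 0.6 * r.normal(size=2048)
        ours = ksg_mutual_information(x, y, 3, r)
        theirs = mutual_info_regression(
            x[:, None], y, n_neighbors=3, random_state=0
        )[0]
        assert abs(ours - theirs) <= 0.1

    def test_batched_path_matches_reference(self, rng):
        W = rng.normal(size=(4, 1024))
        W[1] += 0.8 * W[0]
        W[3] += np.abs(W[2])
        offs = subsegment_layout(1024, 512, 3)
        mats = _mi_matrices(W, offs, 512, 3, np.random.default_rng(1), decimation=2)
        for o_idx, off in enumerate(offs):
            for i in range(4):
                for j in range(i + 1, 4):
                    ref = joe_normalize(
                        ksg_mutual_information(
                            W[i, off : off + 512 : 2],
                            W[j, off : off + 512 : 2],
                            3,
                            np.random.default_rng(2),
                        )
                    )
                    assert mats[o_idx, i, j] == pytest.approx(ref, abs=5e-3)
                    assert mats[o_idx, i, j] == mats[o_idx, j, i]


class TestJoeNormalization:
    def test_zero_maps_to_zero(self):
        assert joe_normalize(0.0) == 0.0

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8, 0.99])
    def test_gaussian_identity(self, rho):
        mi = -0.5 * np.log(1 - rho**2)
        assert joe_normalize(mi) == pytest.approx(rho, abs=1e-12)

    def test_monotone_approach_to_one(self):
        vals = joe_normalize(np.array([0.5, 1.0, 2.0, 4.0]))
        assert np.all(np.diff(vals) > 0)
        assert 0.999 < vals[-1] < 1.0


def _ensembles(rho_orig, rho_surr, n=3, n_ens=10, n_surr=10, spread=0.01):
    """Symmetric ensembles whose pair (0,1) has the requested medians."""
    r = np.random.default_rng(0)
    orig = r.normal(0.0, spread, size=(n_ens, n, n))
    surr = r.normal(0.0, spread, size=(n_ens * n_surr, n, n))
    orig = (orig + orig.transpose(0, 2, 1)) / 2
    surr = (surr + surr.transpose(0, 2, 1)) / 2
    orig[:, 0, 1] = orig[:, 1, 0] = rho_orig + np.linspace(-spread, spread, n_ens)
    surr[:, 0, 1] = surr[:, 1, 0] = rho_surr + np.linspace(-spread, spread, n_ens * n_surr)
    return orig, surr


class TestCorrectedMatrix:
    def test_direct_arithmetic(self):
        orig, surr = _ensembles(0.8, 0.3)
        C, s, rho, rho_s = corrected_matrix(orig, surr, alpha=0.05)
        assert s[0, 1] == 1.0
        assert C[0, 1] == pytest.approx((0.8 - 0.3) / (1 - 0.3), abs=1e-6)
        assert rho[0, 1] == pytest.approx(0.8, abs=1e-9)
        assert rho_s[0, 1] == pytest.approx(0.3, abs=1e-9)

    def test_not_significant_means_zero(self):
        orig, surr = _ensembles(0.31, 0.3, spread=0.2)
        C, s, _, _ = corrected_matrix(orig, surr, alpha=0.05)
        assert s[0, 1] == 0.0
        assert C[0, 1] == 0.0

    def test_full_correlation_fixed_point(self):
        orig, surr = _ensembles(1.0, 0.3)
        C, _, _, _ = corrected_matrix(orig, surr, alpha=0.05)
        assert C[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_negative_branch_mirrors_magnitude(self):
        orig, surr = _ensembles(-0.8, 0.3)
        C, s, _, _ = corrected_matrix(orig, surr, alpha=0.05)
        assert s[0, 1] == 1.0
        assert C[0, 1] == pytest.approx(-(0.8 - 0.3) / (1 - 0.3), abs=0.03)

    def test_degenerate_tied_ensembles_not_significant(self):
        orig = np.full((5, 3, 3), 0.5)
        surr = np.full((25, 3, 3), 0.5)
        C, s, _, _ = corrected_matrix(orig, surr, alpha=0.05)
        assert np.all(s[np.triu_indices(3, 1)] == 0.0)
        assert np.all(C[np.triu_indices(3, 1)] == 0.0)


class TestNodeStrength:
    def test_uniform_offdiagonal(self):
        for n in (3, 5, 10):
            m = np.full((n, n), 0.5)
            np.fill_diagonal(m, np.nan)
            assert np.allclose(node_strength(m), 0.5)

    def test_zero_matrix(self):
        m = np.zeros((4, 4))
        assert np.allclose(node_strength(m), 0.0)

    def test_maximal_matrix(self):
        m = -np.ones((6, 6))
        np.fill_diagonal(m, np.nan)
        assert np.allclose(node_strength(m), 1.0)

    def test_single_nonzero_pair(self):
        n = 5
        m = np.zeros((n, n))
        m[1, 3] = m[3, 1] = -0.6
        s = node_strength(m)
        assert s[1] == pytest.approx(0.6 / (n - 1))
        assert s[3] == pytest.approx(0.6 / (n - 1))
        assert np.all(s[[0, 2, 4]] == 0.0)

    def test_rejects_tiny_or_nonsquare(self):
        with pytest.raises(ValueError):
            node_strength(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            node_strength(np.zeros((3, 4)))


def _drive_recording(seed, n_noise=4, dur_s=40.0, fs=512.0):
    """Two channels sharing a strong narrowband ~10 Hz drive plus noise channels."""
    r = np.random.default_rng(seed)
    n = int(dur_s * fs)
    drive = ar2_series(r, n)  # alpha-like oscillation with phase diffusion
    drive /= drive.std()
    chans = [2.0 * drive + r.normal(size=n), 2.0 * drive + r.normal(size=n)]
    chans += [r.normal(size=n) for _ in range(n_noise)]
    return Recording(
        np.stack(chans), fs, onset_sample=n // 4, termination_sample=n // 2
    )


class TestInterrelationSeries:
    CFG = EnsembleConfig(
        window_len=4096, step=2048, subsegment_len=1024, n_ens=10, n_surr=5,
        surrogate_max_iterations=30,
    )

    def test_shared_drive_pair_is_significant(self):
        rec = _drive_recording(0)
        cfg = EnsembleConfig(
            window_len=4096, step=2048, subsegment_len=1024, n_ens=10, n_surr=5,
            surrogate_max_iterations=30, store_matrices=True,
        )
        series, result = interrelation_series(rec, cfg, kind="C", seed=1)
        sig_rate = result.significance[:, 0, 1].mean()
        strong_rate = (result.corrected[:, 0, 1] > 0.5).mean()
        assert sig_rate >= 0.9
        assert strong_rate >= 0.9
        # and the coupled channels dominate the node-strength series
        assert series.values[:2].mean() > 3.0 * series.values[2:].mean()

    def test_deterministic_for_fixed_seed(self):
        rec = _drive_recording(1)
        cfg = EnsembleConfig(
            window_len=4096, step=4096, subsegment_len=1024, n_ens=5, n_surr=3,
            surrogate_max_iterations=20,
        )
        a, _ = interrelation_series(rec, cfg, kind="C", seed=9)
        b, _ = interrelation_series(rec, cfg, kind="C", seed=9)
        assert np.array_equal(a.values, b.values)

    def test_store_matrices_payload(self):
        rec = _drive_recording(2, dur_s=16.0)
        cfg = EnsembleConfig(
            window_len=4096, step=4096, subsegment_len=1024, n_ens=5, n_surr=3,
            surrogate_max_iterations=20, store_matrices=True,
        )
        series, result = interrelation_series(rec, cfg, kind="C", seed=0)
        assert result.corrected.shape[0] == series.grid.n_windows
        iu = np.triu_indices(rec.n_channels, 1)
        corr = result.corrected[0][iu]
        sig = result.significance[0][iu]
        assert np.all((corr != 0) <= (sig == 1))
        assert np.all(np.abs(corr) <= 1.0)
        # node strength recomputable from the stored matrix
        assert np.allclose(node_strength(result.corrected[0]), series.values[:, 0])

    def test_m_not_larger_than_c_for_linear_coupling(self):
        """Multivariate surrogates absorb linear dependence: M stays below C."""
        wins = 0
        trials = 0
        cfg = EnsembleConfig(
            window_len=2048, step=2048, subsegment_len=1024, n_ens=5, n_surr=5,
            mi_decimation=4, surrogate_max_iterations=20,
        )
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = ar2_series(r, 2048)
            y = 0.7 * x + np.sqrt(1 - 0.49) * ar2_series(r, 2048)
            z = ar2_series(r, 2048)
            rec = Recording(np.stack([x, y, z]), 512.0, onset_sample=1, termination_sample=2)
            c_series, _ = interrelation_series(rec, cfg, kind="C", seed=seed)
            m_series, _ = interrelation_series(rec, cfg, kind="M", seed=seed)
            wins += float(np.median(m_series.values) <= np.median(c_series.values) + 1e-9)
            trials += 1
        assert wins / trials >= 0.8

    def test_rejects_unknown_kind(self, noise_recording):
        with pytest.raises(ValueError):
            interrelation_series(noise_recording, kind="X")
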