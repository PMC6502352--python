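import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from icod.ensembles import CovarianceResult, covariance, sample_ensemble
from icod.spectral import (
    count_outliers,
    ica_disentangle,
    icod,
    pca,
    recovery,
    recovery_random_closed_form,
    recovery_random_expectation,
    recovery_report,
    sca_first_mode,
    sca_matrix,
)
from icod.synthetic import SectorSpec, make_delta, make_delta_pair
from icod.trait_models import MultiTraitSelection, MutationalEffectVector, SelectionSpec


class TestPCA:
    def test_worked_example_eigenstructure(self, zero_projection_covariance, delta_l3):
        res = pca(zero_projection_covariance)
        np.testing.assert_allclose(res.eigenvalues, [0.5, 0.25, 0.0], atol=1e-12)
        first, last = res.first, res.last
        np.testing.assert_allclose(np.abs(first), [1, 1, 0] / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(np.abs(last), [1, 1, 0] / np.sqrt(2), atol=1e-12)
        assert recovery(last, delta_l3) == pytest.approx(1.0, abs=1e-12)
        assert recovery(first, delta_l3) == pytest.approx(1.0, abs=1e-12)

    def test_identity_covariance_flat_spectrum(self):
        res = pca(CovarianceResult(np.eye(4), np.full(4, 0.5)))
        np.testing.assert_allclose(res.eigenvalues, 1.0)
        d = MutationalEffectVector(np.array([1.0, 2.0, 0.5, -1.0]))
        rep = recovery_report(res, d)
        # in a degenerate spectrum every mode recovers equally poorly/well
        assert rep.recovery_per_mode.std() < 0.35

    def test_matches_characteristic_polynomial_oracle(self):
        """Eigenvalues agree with the roots of det(C - x I) computed
        independently from the characteristic polynomial."""
        rng = np.random.default_rng(12)
        A = rng.normal(size=(5, 5))
        C = A @ A.T / 5
        res = pca(CovarianceResult(C, np.full(5, 0.5)))
        poly = np.poly(C)  # coefficients of det(xI - C)
        roots = np.sort(np.real(np.roots(poly)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, roots, atol=1e-8)
        for j in range(5):
            resid = C @ res.eigenvectors[:, j] - res.eigenvalues[j] * res.eigenvectors[:, j]
            assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(C)

    def test_orthonormality(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(8, 8))
        res = pca(CovarianceResult(A @ A.T, np.full(8, 0.5)))
        np.testing.assert_allclose(
            res.eigenvectors.T @ res.eigenvectors, np.eye(8), atol=1e-8
        )

    def test_asymmetric_input_rejected(self):
        C = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CovarianceResult(C, np.full(2, 0.5))


class TestICOD:
    def test_outer_product_construction_oracle(self):
        """If C^-1 = I + kappa Delta Delta^T then the ICOD matrix is exactly
        kappa Delta_l Delta_l' off-diagonal and its top eigenvector
        recovers Delta."""
        rng = np.random.default_rng(14)
        L, kappa = 50, 4.0
        d = rng.normal(size=L)
        d /= np.linalg.norm(d)
        Cinv = np.eye(L) + kappa * np.outer(d, d)
        C = np.linalg.inv(Cinv)
        res = icod(CovarianceResult(C, np.full(L, 0.5)))
        off = kappa * np.outer(d, d)
        np.fill_diagonal(off, 0.0)
        np.testing.assert_allclose(res.matrix, off, atol=1e-8)
        assert recovery(res.first, MutationalEffectVector(d)) > 0.99

    def test_diagonal_covariance_gives_zero_matrix(self):
        res = icod(CovarianceResult(np.diag([0.2, 0.1, 0.15]), np.full(3, 0.5)))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_singular_covariance_names_pseudocount(self, zero_projection_covariance):
        with pytest.raises(np.linalg.LinAlgError, match="pseudocount"):
            icod(zero_projection_covariance)

    def test_small_coupling_law(self):
        """Off-diagonal of C^-1 correlates with kappa Delta_l Delta_l' when
        kappa sum(Delta^2) >> 1."""
        d = make_delta(SectorSpec(L=50, n_sector_sites=10, seed=15))
        sel = SelectionSpec.from_gamma(d, 0.0)
        ens = sample_ensemble(d, sel, 100000, seed=15)
        cov = covariance(ens, pseudocount=0.01)
        Cinv = np.linalg.inv(cov.C)
        mask = ~np.eye(50, dtype=bool)
        pred = sel.kappa * np.outer(d.effects, d.effects)
        r = np.corrcoef(Cinv[mask], pred[mask])[0, 1]
        assert r > 0.9

    def test_icod_beats_pca_under_biased_selection(self):
        """Strong selection bias creates conservation that disrupts the last
        principal component but not the ICOD first eigenvector."""
        d = make_delta(SectorSpec(L=60, n_sector_sites=12, seed=16))
        sel = SelectionSpec.from_gamma(d, 4.0)
        ens = sample_ensemble(d, sel, 8000, seed=16, method="mcmc")
        cov = covariance(ens, pseudocount=0.01)
        rec_icod = recovery(icod(cov).first, d)
        rec_pca = recovery(pca(cov).last, d)
        assert rec_icod > rec_pca + 0.05

    def test_pca_and_icod_agree_for_unbiased_selection(self, sector_delta):
        sel = SelectionSpec.from_gamma(sector_delta, 0.0)
        ens = sample_ensemble(sector_delta, sel, 100000, seed=17)
        cov = covariance(ens, pseudocount=0.01)
        rec_icod = recovery(icod(cov).first, sector_delta)
        rec_pca = recovery(pca(cov).last, sector_delta)
        assert rec_icod > 0.9 and rec_pca > 0.9
        assert abs(rec_icod - rec_pca) < 0.1

    def test_recovery_exceeds_random_baseline(self):
        """A concentrated sector (few sites, strongly heterogeneous effects,
        like the elastic-network case) has a low random baseline that the
        ICOD first eigenvector beats by at least five-fold."""
        d = make_delta(SectorSpec(L=100, n_sector_sites=3,
                                  effect_scale_sector=100.0, seed=18))
        sel = SelectionSpec.from_gamma(d, 0.0)
        ens = sample_ensemble(d, sel, 100000, seed=18)
        res = icod(covariance(ens, pseudocount=0.01))
        rec = recovery(res.first, d)
        rand = recovery_random_expectation(d, seed=18)
        assert rec > 5 * rand


class TestRecovery:
    @pytest.mark.parametrize(
        "nu, d, expected",
        [
            ((1, 1, 0), (-1, 1, 0), 1.0),                  # both worked-example PCs
            ((1, 0, 0), (-1, 1, 0), 1 / math.sqrt(2)),     # partial overlap
            ((2, -4, 1), (2, -4, 1), 1.0),                 # parallel vectors
        ],
    )
    def test_known_values(self, nu, d, expected):
        val = recovery(np.array(nu, float), MutationalEffectVector(np.array(d, float)))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            recovery(np.zeros(3), MutationalEffectVector(np.array([1.0, 0, 0])))

    @given(
        hnp.arrays(np.float64, 6, elements=st.floats(-10, 10)),
        hnp.arrays(np.float64, 6, elements=st.floats(-10, 10)),
        st.floats(0.1, 7.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariances_and_bounds(self, nu, d, scale):
        """Recovery lies in [0,1], is scale-invariant, and is blind to
        per-site sign flips of either vector."""
        if np.linalg.norm(nu) < 1e-6 or np.linalg.norm(d) < 1e-6:
            return
        dv = MutationalEffectVector(d)
        base = recovery(nu, dv)
        assert 0.0 <= base <= 1.0 + 1e-12
        assert recovery(scale * nu, dv) == pytest.approx(base, rel=1e-9)
        signs = np.where(np.arange(6) % 2, -1.0, 1.0)
        assert recovery(signs * nu, MutationalEffectVector(signs * d)) == pytest.approx(
            base, rel=1e-9
        )

    def test_recovery_one_iff_parallel_up_to_signs(self):
        rng = np.random.default_rng(19)
        d = rng.normal(size=20)
        assert recovery(np.abs(d), MutationalEffectVector(d)) == pytest.approx(1.0)


class TestRandomExpectation:
    def test_single_site_matches_sphere_marginal(self):
        """With one nonzero effect the statistic reduces to E|nu_l| for a
        uniform unit vector, known in closed form from the sphere marginal."""
        from scipy.special import gammaln

        L = 40
        d = np.zeros(L)
        d[3] = 2.0
        mc = recovery_random_expectation(MutationalEffectVector(d), n_draws=200000, seed=20)
        exact = 2 * math.exp(gammaln(L / 2) - gammaln((L - 1) / 2)) / ((L - 1) * math.sqrt(math.pi))
        assert mc == pytest.approx(exact, rel=0.02)

    def test_uniform_delta_matches_closed_form(self):
        d = MutationalEffectVector(np.ones(100))
        mc = recovery_random_expectation(d, n_draws=100000, seed=21)
        assert mc == pytest.approx(recovery_random_closed_form(d), rel=0.02)

    def test_output_strictly_between_zero_and_one(self):
        rng = np.random.default_rng(22)
        d = MutationalEffectVector(rng.normal(size=30))
        val = recovery_random_expectation(d, n_draws=500, seed=22)
        assert 0.0 < val < 1.0


class TestSCA:
    def test_unit_conservation_reduces_to_abs_covariance(self, monkeypatch):
        """With phi = 1 the SCA matrix is |C| and shares its spectrum."""
        rng = np.random.default_rng(23)
        ens_seqs = rng.integers(0, 2, size=(400, 6))
        from icod.ensembles import WeightedEnsemble

        ens = WeightedEnsemble(ens_seqs, np.full(400, 1 / 400))
        import icod.spectral as spectral_mod

        monkeypatch.setattr(
            spectral_mod, "conservation_factor", lambda p, background=0.5: np.ones(len(p))
        )
        res = spectral_mod.sca_matrix(ens, pseudocount=0.01)
        C = covariance(ens, pseudocount=0.01).C
        np.testing.assert_allclose(
            res.eigenvalues, np.sort(np.linalg.eigvalsh(np.abs(C)))[::-1], atol=1e-10
        )

    def test_sca_recovers_under_strong_bias_but_not_unbiased(self, sector_delta):
        """Conservation-driven SCA works for biased selection yet breaks down
        for unbiased selection, where ICOD still succeeds."""
        rand = recovery_random_expectation(sector_delta, seed=24)

        sel_biased = SelectionSpec.from_gamma(sector_delta, 2.0)
        ens_b = sample_ensemble(sector_delta, sel_biased, 100000, seed=24)
        rec_biased = recovery(sca_first_mode(sca_matrix(ens_b)), sector_delta)
        assert rec_biased > rand

        sel_flat = SelectionSpec.from_gamma(sector_delta, 0.0)
        ens_0 = sample_ensemble(sector_delta, sel_flat, 100000, seed=25)
        rec_flat = recovery(sca_first_mode(sca_matrix(ens_0)), sector_delta)
        rec_icod = recovery(icod(covariance(ens_0, pseudocount=0.01)).first, sector_delta)
        assert rec_flat < 2 * rand
        assert rec_icod > 0.9

    def test_conserved_site_without_pseudocount_rejected(self):
        from icod.ensembles import WeightedEnsemble

        ens = WeightedEnsemble(np.array([[1, 0], [1, 1]]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="pseudocount"):
            sca_matrix(ens, pseudocount=0.0)


class TestICA:
    def test_constructed_rotation_oracle(self):
        """Two sector-localized vectors mixed by a 45-degree rotation are
        un-mixed by the ICA step."""
        rng = np.random.default_rng(26)
        L = 100
        s1, s2 = np.zeros(L), np.zeros(L)
        s1[:20] = -rng.uniform(5, 15, 20)
        s2[20:40] = -rng.uniform(5, 15, 20)
        th = math.pi / 4
        v1 = math.cos(th) * s1 + math.sin(th) * s2
        v2 = -math.sin(th) * s1 + math.cos(th) * s2
        from icod.spectral import SpectralResult

        vecs = np.column_stack([v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)])
        res = SpectralResult(np.array([2.0, 1.5]), vecs, "icod")
        comps = ica_disentangle(res, n_components=2, seed=0)
        recs = np.array([
            [recovery(c, MutationalEffectVector(s)) for s in (s1, s2)] for c in comps
        ])
        best = max(
            min(recs[i, p[i]] for i in range(2))
            for p in itertools.permutations(range(2))
        )
        assert best >= 0.95

    def test_single_component_returns_top_eigenvector(self):
        from icod.spectral import SpectralResult

        rng = np.random.default_rng(27)
        vecs, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        res = SpectralResult(np.arange(6.0)[::-1], vecs, "icod")
        comps = ica_disentangle(res, n_components=1)
        np.testing.assert_array_equal(comps[0], res.first)

    def test_two_trait_ensemble_disentangled(self):
        """Double selection on two non-overlapping sectors: the ICOD spectrum
        shows two outliers and ICA recovers both effect vectors."""
        spec = SectorSpec(L=100, n_sector_sites=20, seed=28)
        d1, d2 = make_delta_pair(spec, 0.0)
        msel = MultiTraitSelection([
            (d1, SelectionSpec.from_gamma(d1, 0.0)),
            (d2, SelectionSpec.from_gamma(d2, 0.0)),
        ])
        ens = sample_ensemble(d1, msel.traits[0][1], 100000, seed=28, msel=msel)
        res = icod(covariance(ens, pseudocount=0.01))
        assert count_outliers(res.eigenvalues) == 2
        comps = ica_disentangle(res, n_components=2, seed=0)
        recs = np.array([[recovery(c, d) for d in (d1, d2)] for c in comps])
        best = max(
            min(recs[i, p[i]] for i in range(2))
            for p in itertools.permutations(range(2))
        )
        assert best >= 0.8

    def test_single_trait_spectrum_has_one_outlier(self, sector_delta):
        sel = SelectionSpec.from_gamma(sector_delta, 0.0)
        ens = sample_ensemble(sector_delta, sel, 100000, seed=29)
        res = icod(covariance(ens, pseudocount=0.01))
        assert count_outliers(res.eigenvalues) == 1

    def test_too_many_components_rejected(self):
        from icod.spectral import SpectralResult

        res = SpectralResult(np.array([1.0, 0.5]), np.eye(2), "icod")
        with pytest.raises(ValueError, match="exceeds"):
            ica_disentangle(res, n_components=3)
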