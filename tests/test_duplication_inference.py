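import itertools

import numpy as np
import pandas as pd
import pytest

from dupscan import (
    duplication_score,
    factor_pair_scramble_test,
    fit_mixture,
    infer_tstar,
    random_motif,
)
from dupscan.duplication_inference import (
    ScoreTable,
    distance_entropy_profile,
    lambda_null_quantile,
    score_pairs,
)
from dupscan.evolution_model import SitePair, p_duplication, p_independent
from dupscan.seq_io import ALPHABET, Background
from dupscan.synthetic_data import make_site_instance


@pytest.fixture(scope="module")
def bg():
    return Background.uniform()


@pytest.fixture(scope="module")
def two_motifs(bg):
    return random_motif("A", 2, seed=31), random_motif("B", 2, seed=32)


def _all_pairs(A, B, bg):
    out = []
    for a in itertools.product(ALPHABET, repeat=A.length):
        for b in itertools.product(ALPHABET, repeat=B.length):
            out.append(
                SitePair(
                    make_site_instance(A, "".join(a), bg),
                    make_site_instance(B, "".join(b), bg),
                    distance=10,
                )
            )
    return out


class TestScore:
    def test_score_vanishes_at_large_t(self, two_motifs, bg):
        A, B = two_motifs
        pair = _all_pairs(A, B, bg)[5]
        assert duplication_score(pair, 1e3) == pytest.approx(0.0, abs=1e-5)

    def test_exponential_moment_identity(self, two_motifs, bg):
        """E_ind[e^S] = 1 exhaustively: the score is a proper
        log-likelihood ratio."""
        A, B = two_motifs
        pairs = _all_pairs(A, B, bg)
        for t in (0.2, 1.0, 5.0):
            S = score_pairs(pairs, t)
            P_ind = np.array([p_independent(p) for p in pairs])
            assert float(np.sum(P_ind * np.exp(S))) == pytest.approx(1.0, abs=1e-10)

    def test_gibbs_inequalities(self, two_motifs, bg):
        A, B = two_motifs
        pairs = _all_pairs(A, B, bg)
        for t in (0.2, 1.0, 5.0):
            S = score_pairs(pairs, t)
            P_ind = np.array([p_independent(p) for p in pairs])
            P_dup = np.array([p_duplication(p, t) for p in pairs])
            assert float(np.sum(P_ind * S)) <= 1e-12
            assert float(np.sum(P_dup * S)) >= -1e-12

    def test_shared_consensus_scores_positive(self, bg):
        A = random_motif("A", 7, seed=41, peak_lo=0.8, peak_hi=0.9)
        cons = A.consensus()
        B = random_motif("B", 7, seed=42, peak_lo=0.8, peak_hi=0.9)
        pair = SitePair(
            make_site_instance(A, cons, bg),
            make_site_instance(A, cons, bg),
            distance=10,
        )
        assert duplication_score(pair, 0.5) > 0

    def test_vectorized_scores_match_single_pair_path(self, two_motifs, bg):
        A, B = two_motifs
        pairs = _all_pairs(A, B, bg)[:10]
        batch = score_pairs(pairs, 0.7)
        singles = [duplication_score(p, 0.7) for p in pairs]
        np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestTstar:
    def test_single_pair_warns_and_returns_argmax(self, two_motifs, bg):
        A, B = two_motifs
        pair = _all_pairs(A, B, bg)[0]
        grid = np.geomspace(0.01, 10, 12)
        st = infer_tstar([pair], grid)
        curve = np.array([duplication_score(pair, t) for t in grid])
        assert st.t_star == pytest.approx(grid[int(np.argmax(curve))])

    def test_independent_ensemble_pushes_tstar_to_boundary(self, bg, rng):
        from dupscan.synthetic_data import sample_from_motif
        from dupscan.seq_io import decode

        A = random_motif("A", 7, seed=51)
        B = random_motif("B", 7, seed=52)
        pairs = [
            SitePair(
                make_site_instance(A, decode(a), bg),
                make_site_instance(B, decode(b), bg),
                distance=150,
            )
            for a, b in zip(
                sample_from_motif(A, 300, rng), sample_from_motif(B, 300, rng)
            )
        ]
        st = infer_tstar(pairs, np.geomspace(1e-2, 1e2, 15))
        assert st.boundary
        assert st.t_star == pytest.approx(1e2)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            infer_tstar([], np.geomspace(0.01, 1, 10))


class TestMixture:
    def test_null_scores_give_rho_and_lambda_near_zero(self):
        rng = np.random.default_rng(8)
        far = rng.normal(0, 1, 1200)
        near = rng.choice(far, 300, replace=False)
        fit = fit_mixture(near, far, n_bootstrap=0)
        assert fit.rho < 0.15
        band = lambda_null_quantile(far, n=300, n_draws=100, seed=1)
        assert fit.Lambda < 1.5 * band

    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(9)
        far = rng.normal(0, 1, 1200)
        near = np.concatenate([rng.choice(far, 150), rng.normal(2.2, 1.4, 150)])
        fit = fit_mixture(near, far, n_bootstrap=20, seed=2)
        assert fit.rho == pytest.approx(0.5, abs=0.15)
        assert fit.rho_ci[0] <= fit.rho <= fit.rho_ci[1]
        assert fit.Lambda == pytest.approx(fit.n * fit.D, rel=1e-12)
        assert fit.Lambda > lambda_null_quantile(far, n=300, n_draws=100, seed=3)

    def test_fully_shifted_scores_hit_upper_bound(self):
        rng = np.random.default_rng(10)
        far = rng.normal(0, 1, 500)
        near = rng.normal(6.0, 1.0, 60)
        fit = fit_mixture(near, far, n_bootstrap=0)
        assert fit.rho > 0.9

    def test_degenerate_far_sample_rejected(self):
        with pytest.raises(ValueError, match="variance|degenerate"):
            fit_mixture(np.zeros(20), np.ones(50), n_bootstrap=0)

    def test_mixture_density_integrates_to_one(self):
        rng = np.random.default_rng(11)
        far = rng.normal(0, 1, 600)
        near = np.concatenate([rng.choice(far, 100), rng.normal(2.5, 1.0, 100)])
        fit = fit_mixture(near, far, n_bootstrap=0)
        x = np.linspace(-12, 15, 4001)
        integral = np.trapezoid(fit.mixture_pdf(x), x)
        assert integral == pytest.approx(1.0, abs=1e-4)


class TestEndToEnd:
    """Label-free mixture fitting on fully simulated evolution ensembles.

    With exponential divergence times, duplications much older than 1/mu
    leave no sequence trace, so the fitted rho is a lower bound on the
    planted duplicated fraction; the test asserts detection and calibration,
    not exact recovery.
    """

    def test_label_free_fit_detects_duplications_and_stays_calibrated(self, bg):
        from dupscan import SimulationConfig, infer_tstar, simulate_pair_ensemble

        A = random_motif("A", 7, seed=81)
        B = random_motif("B", 7, seed=82)
        cfg = SimulationConfig(
            motif_pairs=[(A, B)], tau_bar=1.0, n_events=60, pairs_per_event=5,
            n_independent=900, seed=14,
        )
        ens = simulate_pair_ensemble(cfg)
        common = ens.subset("common")
        indep = ens.subset("independent")
        st = infer_tstar(common, np.geomspace(1e-2, 1e2, 31))
        near = np.concatenate(
            [st.table["S"].to_numpy(), score_pairs(indep[:300], st.t_star)]
        )  # planted fraction 0.5
        far = score_pairs(indep[300:], st.t_star)
        fit = fit_mixture(near, far, n_bootstrap=0)
        assert fit.rho > 0.15
        assert fit.Lambda > lambda_null_quantile(far, n=near.size, n_draws=100, seed=5)
        # pure independent 'near' class: no spurious duplication fraction
        null_fit = fit_mixture(score_pairs(indep[:300], st.t_star), far, n_bootstrap=0)
        assert null_fit.rho < 0.1


class TestDistanceProfile:
    def _table(self, rng, shifts):
        rows = []
        for i, (lo, hi, shift, n) in enumerate(shifts):
            d = rng.integers(lo, hi, n)
            s = rng.normal(shift, 1.0, n)
            for dist, sc in zip(d, s):
                rows.append({"pair_id": i, "factor_a": "A", "factor_b": "B",
                             "distance": int(dist), "offset": 0, "S": float(sc)})
        return pd.DataFrame(rows)

    def test_planted_decay_recovered(self):
        rng = np.random.default_rng(12)
        table = self._table(
            rng,
            [(1, 20, 2.0, 150), (20, 40, 1.0, 150), (40, 60, 0.4, 150),
             (100, 300, 0.0, 600)],
        )
        prof = distance_entropy_profile(
            table, [(1, 20), (20, 40), (40, 60)], far_threshold=100
        )
        assert list(prof["D"]) == sorted(prof["D"], reverse=True)
        assert np.all(prof["D"] >= 0)

    def test_underpopulated_bin_skipped(self):
        rng = np.random.default_rng(13)
        table = self._table(rng, [(1, 20, 0.5, 5), (100, 300, 0.0, 200)])
        prof = distance_entropy_profile(table, [(1, 20)], far_threshold=100)
        assert len(prof) == 0


class TestScramble:
    def _table(self, rng, n_groups=8, n_per=25, shift_group=None):
        rows = []
        for g in range(n_groups):
            mean = 3.0 if g == shift_group else 0.0
            for s in rng.normal(mean, 1.0, n_per):
                rows.append({"factor_a": f"F{g}", "factor_b": f"G{g}",
                             "distance": 10, "offset": 0, "S": float(s)})
        return pd.DataFrame(rows)

    def test_exchangeable_scores_give_large_p(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(20):
            res = factor_pair_scramble_test(self._table(rng), n_scrambles=60, seed=0)
            ps.append(res.p_value)
        assert np.median(ps) > 0.1

    def test_shifted_factor_pair_detected(self):
        rng = np.random.default_rng(15)
        res = factor_pair_scramble_test(
            self._table(rng, shift_group=3), n_scrambles=200, seed=0
        )
        assert res.p_value < 0.01

    def test_single_factor_pair_rejected(self):
        table = pd.DataFrame(
            {"factor_a": ["A"] * 5, "factor_b": ["B"] * 5,
             "distance": [10] * 5, "offset": [0] * 5, "S": [0.1] * 5}
        )
        with pytest.raises(ValueError):
            factor_pair_scramble_test(table)
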