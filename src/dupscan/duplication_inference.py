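"""Inference of common vs independent descent from duplication scores.

The duplication score of a site pair is the log-likelihood ratio

    S(a, b; t) = ln P_dup(a, b; t) - ln[ Q_A(a) Q_B(b) ],

positive when the pair is more likely to have arisen by duplication of a
common ancestor followed by divergence than from independent origins.  The
evolutionary-distance parameter t is a model fit parameter, inferred by
maximizing the total score over an ensemble of pairs (t* close to the mean
divergence time in simulations).

The observed score distribution of a class of pairs is decomposed with the
mixed-descent model

    Q(S) = (1 - rho) Q_ind(S) + rho Q_dup(S),

where Q_ind is estimated nonparametrically from pairs at large mutual
distance (independent descent), Q_dup is a location-scale (Gaussian)
component constrained to lie above the Q_ind mean, and rho is the duplicated
fraction.  The statistical evidence for the mixture is Lambda = n * D, the
number of pairs times the relative entropy between the observed distribution
and Q_ind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .evolution_model import (
    Propagator,
    SitePair,
    build_fitness,
    build_rates,
    p_duplication_from_propagators,
    p_independent,
    propagate,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scores


def duplication_score(pair: SitePair, t: float) -> float:
    """S = ln P_dup(a, b; t) - ln P_ind(a, b) for one pair."""
    prop_a = propagate(
        build_rates(build_fitness(pair.site_a.motif, pair.site_a.background)), t
    )
    prop_b = propagate(
        build_rates(build_fitness(pair.site_b.motif, pair.site_b.background)), t
    )
    return _score_with_propagators(pair, prop_a, prop_b)


def _score_with_propagators(pair: SitePair, prop_a: Propagator, prop_b: Propagator) -> float:
    pd_ = p_duplication_from_propagators(pair, prop_a, prop_b)
    pi_ = p_independent(pair)
    return float(np.log(pd_) - np.log(pi_))


def score_pairs(pairs: Sequence[SitePair], t: float) -> np.ndarray:
    """Duplication scores of many pairs at one t.

    Propagators are cached per (motif, background), and pairs sharing the
    same motifs, backgrounds, and alignment are scored in a single
    vectorized pass over the per-column joint matrices.
    """
    from .seq_io import encode

    cache: dict[tuple[int, int], Propagator] = {}

    def prop(site) -> Propagator:
        key = (id(site.motif), id(site.background))
        if key not in cache:
            cache[key] = propagate(
                build_rates(build_fitness(site.motif, site.background)), t
            )
        return cache[key]

    out = np.empty(len(pairs))
    groups: dict[tuple, list[int]] = {}
    for idx, p in enumerate(pairs):
        groups.setdefault(
            (
                id(p.site_a.motif),
                id(p.site_b.motif),
                id(p.site_a.background),
                id(p.site_b.background),
                p.offset,
            ),
            [],
        ).append(idx)
    for members in groups.values():
        first = pairs[members[0]]
        if first.site_a.motif.length != first.site_b.motif.length:
            for idx in members:
                out[idx] = _score_with_propagators(
                    pairs[idx], prop(pairs[idx].site_a), prop(pairs[idx].site_b)
                )
            continue
        prop_a = prop(first.site_a)
        prop_b = prop(first.site_b)
        L = first.site_a.motif.length
        cols = np.arange(L)
        JA, JB = _pair_column_joints(prop_a, prop_b, cols, cols)
        qa = first.site_a.motif.freq
        qb = first.site_b.motif.freq
        A = np.stack([encode(pairs[i].site_a.sequence) for i in members])
        B = np.stack([encode(pairs[i].site_b.sequence) for i in members])
        with np.errstate(divide="ignore"):
            la = np.log(JA[cols[None, :], A, B]).sum(axis=1)
            lb = np.log(JB[cols[None, :], A, B]).sum(axis=1)
            log_pind = (
                np.log(qa[cols[None, :], A]).sum(axis=1)
                + np.log(qb[cols[None, :], B]).sum(axis=1)
            )
        log_pdup = np.logaddexp(la, lb) + np.log(0.5)
        out[np.asarray(members)] = log_pdup - log_pind
    return out


def _pair_column_joints(prop_a, prop_b, cols_a: np.ndarray, cols_b: np.ndarray):
    """Joint 4x4 matrices per column for both ancestral assignments."""
    from .evolution_model import _column_joint

    return _column_joint(prop_a, prop_b, cols_a, cols_b)


@dataclass
class ScoreTable:
    """Per-pair duplication scores at the fitted evolutionary distance t*."""

    table: pd.DataFrame  # pair_id, factor_a, factor_b, distance, offset, S
    t_star: float
    t_grid: np.ndarray
    total_curve: np.ndarray  # sum of S over pairs at each grid t
    boundary: bool  # t* on the grid boundary => no duplication signal

    @property
    def scores(self) -> np.ndarray:
        return self.table["S"].to_numpy()


def default_t_grid(n: int = 30, lo: float = 1e-3, hi: float = 1e3) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def infer_tstar(pairs: Sequence[SitePair], t_grid: np.ndarray | None = None) -> ScoreTable:
    """Fit t* by maximizing the total duplication score over a log-spaced grid.

    Emits the full curve sum_pairs S(t); a t* on the grid boundary is
    flagged (expected when there is no duplication signal, since the mean
    score under independent descent is non-positive and tends to zero as
    t grows)."""
    if len(pairs) == 0:
        raise ValueError("need at least one site pair")
    if len(pairs) == 1:
        logger.warning("inferring t* from a single pair")
    grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    all_scores = np.stack([score_pairs(pairs, t) for t in grid])  # |grid| x n
    curve = all_scores.sum(axis=1)
    i_star = int(np.argmax(curve))
    boundary = i_star in (0, len(grid) - 1)
    if boundary:
        logger.warning("t* sits on the grid boundary: no duplication signal")
    table = pd.DataFrame(
        {
            "pair_id": np.arange(len(pairs)),
            "factor_a": [p.factors[0] for p in pairs],
            "factor_b": [p.factors[1] for p in pairs],
            "distance": [p.distance for p in pairs],
            "offset": [p.offset for p in pairs],
            "S": all_scores[i_star],
        }
    )
    return ScoreTable(
        table=table,
        t_star=float(grid[i_star]),
        t_grid=grid,
        total_curve=curve,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Mixture model


@dataclass
class MixtureFit:
    """Mixed-descent decomposition of a score distribution."""

    rho: float
    mu_dup: float
    sigma_dup: float
    q_ind: Callable[[np.ndarray], np.ndarray]
    n: int
    D: float  # relative entropy of observed vs Q_ind (nats)
    Lambda: float  # n * D
    loglik: float
    rho_ci: tuple[float, float] | None = None

    def mixture_pdf(self, s: np.ndarray) -> np.ndarray:
        return (1 - self.rho) * self.q_ind(s) + self.rho * stats.norm.pdf(
            s, self.mu_dup, self.sigma_dup
        )


def _binned_relative_entropy(
    scores: np.ndarray, kde: stats.gaussian_kde, n_bins: int = 20
) -> float:
    """Relative entropy D(empirical || reference) on a common binning (nats)."""
    lo = float(scores.min())
    hi = float(scores.max())
    pad = 1e-9 + 0.05 * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    p, _ = np.histogram(scores, bins=edges)
    p = p / p.sum()
    q = np.array(
        [kde.integrate_box_1d(edges[i], edges[i + 1]) for i in range(n_bins)]
    )
    q = np.clip(q, 1e-12, None)
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _fit_mixture_ml(
    scores: np.ndarray, kde: stats.gaussian_kde, mean_far: float, sd_far: float
) -> tuple[float, float, float, float]:
    """Grid search plus local refinement of (rho, mu_d, sigma_d).

    Identifiability constraints: the common-descent component must sit at
    least one Q_ind standard deviation above the Q_ind mean (otherwise a
    component overlapping the bulk absorbs sampling noise and inflates rho),
    and its scale is bounded below to avoid the vanishing-width mixture
    degeneracy.
    """
    q_ind_vals = np.clip(kde(scores), 1e-300, None)
    mu_lo = mean_far + 1.0 * sd_far

    def negloglik(params: np.ndarray) -> float:
        rho, mu, sig = params
        if not (0.0 <= rho <= 1.0) or mu < mu_lo or sig < 0.3 * sd_far:
            return np.inf
        dens = (1 - rho) * q_ind_vals + rho * stats.norm.pdf(scores, mu, sig)
        if np.any(dens <= 0):
            return np.inf
        return -float(np.log(dens).sum())

    hi_mu = max(mean_far + 5 * sd_far, float(scores.max()))
    mus = np.linspace(mu_lo, hi_mu, 12)
    sigmas = sd_far * np.geomspace(0.3, 3.0, 6)
    rhos = np.linspace(0.0, 1.0, 21)
    best = (0.0, mus[0], sigmas[0])
    best_nll = negloglik(np.array(best))
    for rho in rhos:  # ascending: ties resolve to the smaller rho
        for mu in mus:
            for sig in sigmas:
                nll = negloglik(np.array([rho, mu, sig]))
                if nll < best_nll - 1e-9:
                    best_nll, best = nll, (rho, mu, sig)
    res = optimize.minimize(
        negloglik, np.array(best), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    if res.fun < best_nll:
        rho, mu, sig = res.x
        rho = float(np.clip(rho, 0.0, 1.0))
        return rho, float(mu), float(sig), -float(res.fun)
    return best[0], best[1], best[2], -best_nll


def fit_mixture(
    scores_near: np.ndarray,
    scores_far: np.ndarray,
    n_bootstrap: int = 100,
    seed: int | None = 0,
) -> MixtureFit:
    """Fit the mixed-descent model to near-distance scores.

    ``scores_far`` (pairs at large mutual distance in a common module)
    define the independent-descent distribution Q_ind via a Gaussian kernel
    density estimate.  The duplicated fraction rho and the Gaussian Q_dup
    parameters are fitted by maximum likelihood on ``scores_near``; the
    evidence is Lambda = n * D with D the binned relative entropy between
    the near-score distribution and Q_ind.  A bootstrap percentile interval
    on rho is attached when ``n_bootstrap > 0``.
    """
    scores_near = np.asarray(scores_near, dtype=float)
    scores_far = np.asarray(scores_far, dtype=float)
    if scores_far.size < 30:
        raise ValueError("need at least 30 far-distance scores to estimate Q_ind")
    if scores_near.size < 10:
        raise ValueError("need at least 10 near-distance scores")
    sd_far = float(scores_far.std(ddof=1))
    if sd_far == 0.0:
        raise ValueError("degenerate far-score sample (zero variance)")
    kde = stats.gaussian_kde(scores_far)
    mean_far = float(scores_far.mean())

    rho, mu, sig, loglik = _fit_mixture_ml(scores_near, kde, mean_far, sd_far)
    D = _binned_relative_entropy(scores_near, kde)
    fit = MixtureFit(
        rho=rho,
        mu_dup=mu,
        sigma_dup=sig,
        q_ind=kde,
        n=scores_near.size,
        D=D,
        Lambda=scores_near.size * D,
        loglik=loglik,
    )
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            resampled = rng.choice(scores_near, size=scores_near.size, replace=True)
            r, *_ = _fit_mixture_ml(resampled, kde, mean_far, sd_far)
            boots.append(r)
        fit.rho_ci = (
            float(np.percentile(boots, 2.5)),
            float(np.percentile(boots, 97.5)),
        )
    return fit


def lambda_null_quantile(
    scores_far: np.ndarray,
    n: int,
    n_draws: int = 200,
    quantile: float = 0.95,
    seed: int | None = 0,
) -> float:
    """Null band for Lambda: resample n scores from the far sample, compute
    Lambda against Q_ind, return the requested quantile."""
    scores_far = np.asarray(scores_far, dtype=float)
    kde = stats.gaussian_kde(scores_far)
    rng = np.random.default_rng(seed)
    lams = []
    for _ in range(n_draws):
        draw = rng.choice(scores_far, size=n, replace=True)
        lams.append(n * _binned_relative_entropy(draw, kde))
    return float(np.quantile(lams, quantile))


# ---------------------------------------------------------------------------
# Distance profile and scramble control


def distance_entropy_profile(
    score_table: ScoreTable | pd.DataFrame,
    distance_bins: Sequence[tuple[int, int]],
    far_threshold: int = 100,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Relative entropy D(r) between each distance bin's score distribution
    and the far-distance (independent-descent) distribution.

    Bins are half-open [lo, hi); underpopulated bins are skipped with a
    warning.  A rapid decay of D(r) indicates a local mechanism generating
    excess similarity between adjacent sites.
    """
    table = score_table.table if isinstance(score_table, ScoreTable) else score_table
    far = table.loc[table["distance"] >= far_threshold, "S"].to_numpy()
    if far.size < 30:
        raise ValueError("not enough far-distance pairs to estimate Q_ind")
    kde = stats.gaussian_kde(far)
    rows = []
    for lo, hi in distance_bins:
        sel = table.loc[
            (table["distance"] >= lo)
            & (table["distance"] < hi)
            & (table["distance"] < far_threshold),
            "S",
        ].to_numpy()
        if sel.size < min_pairs:
            logger.warning("distance bin [%d, %d) has %d < %d pairs; skipped",
                           lo, hi, sel.size, min_pairs)
            continue
        rows.append(
            {
                "r_lo": lo,
                "r_hi": hi,
                "n": sel.size,
                "D": _binned_relative_entropy(sel, kde),
            }
        )
    return pd.DataFrame(rows, columns=["r_lo", "r_hi", "n", "D"])


@dataclass
class ScrambleTestResult:
    observed_means: pd.Series  # per factor pair
    scrambled_means: np.ndarray
    ks_statistic: float
    p_value: float


def factor_pair_scramble_test(
    score_table: ScoreTable | pd.DataFrame,
    n_scrambles: int = 100,
    seed: int | None = 0,
) -> ScrambleTestResult:
    """Test whether positive scores concentrate in particular factor pairs.

    Partial score averages per (unordered) factor pair are compared, by a
    two-sample KS test, with the averages obtained after scrambling the
    score values across pairs.  Indistinguishable distributions mean excess
    similarity is a broad feature of adjacent sites, not a property of a
    subset of factor pairs.
    """
    table = score_table.table if isinstance(score_table, ScoreTable) else score_table
    key = [tuple(sorted(fp)) for fp in zip(table["factor_a"], table["factor_b"])]
    df = pd.DataFrame({"fp": key, "S": table["S"].to_numpy()})
    groups = df.groupby("fp")["S"]
    if groups.ngroups < 2:
        raise ValueError("need at least two distinct factor pairs")
    observed = groups.mean()
    sizes = groups.size().to_numpy()
    values = df["S"].to_numpy()
    rng = np.random.default_rng(seed)
    scrambled = []
    for _ in range(n_scrambles):
        perm = rng.permutation(values)
        start = 0
        for sz in sizes:
            scrambled.append(perm[start : start + sz].mean())
            start += sz
    scrambled = np.asarray(scrambled)
    ks, p = stats.ks_2samp(observed.to_numpy(), scrambled)
    return ScrambleTestResult(
        observed_means=observed,
        scrambled_means=scrambled,
        ks_statistic=float(ks),
        p_value=float(p),
    )
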