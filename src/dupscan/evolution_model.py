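"""Evolutionary model for binding sites: fitness landscapes, substitution
dynamics, propagators, and pair likelihoods for common vs independent descent.

The fitness of a site sequence a under a factor's motif is the additive
information-based (Halpern--Bruno) landscape

    F(a) = sum_i f_i(a_i),    f_i(alpha) = ln( q_i(alpha) / p0(alpha) ),

scaled in units of the effective population size, under which the motif
distribution Q(a) is the mutation--selection--drift equilibrium and the
average fitness of functional sites equals the motif's sequence information.
Point substitutions follow Kimura--Ohta rates

    u(alpha -> beta) = mu * m(alpha -> beta) * g(s),
    g(s) = s / (1 - exp(-s)),   s = f_i(beta) - f_i(alpha),

combining mutation with the fixation probability of a mutant of scaled
selection coefficient s.  With background-weighted mutation,
m(alpha -> beta) = p0(beta), the process is reversible with stationary
distribution q_i — the detailed-balance property the common-descent
likelihood relies on.  Time is measured in units of 1/mu (mu = 1 by
default); t and mu are not separately identifiable.

The joint probability of a site pair (a, b) under common descent is the
equal-prior mixture of the two ancestral assignments

    P_dup(a, b; t) = 1/2 [ P_A-anc(a, b; t) + P_B-anc(a, b; t) ],
    P_A-anc(a, b; t) = sum_c Q_A(c) G_A(a|c; t) G_B(b|c; t),

while under independent descent P_ind(a, b) = Q_A(a) Q_B(b).  As t grows,
P_dup converges to P_ind and the histories become indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .seq_io import Background, Motif, SiteInstance, encode

MUTATION_MODELS = ("background-weighted", "uniform")


@dataclass(frozen=True)
class FitnessLandscape:
    """Additive per-position fitness contributions of a motif."""

    motif: Motif
    background: Background
    f: np.ndarray  # L x 4, f_i(alpha) = ln(q_i(alpha)/p0(alpha))

    @property
    def length(self) -> int:
        return self.f.shape[0]

    def fitness(self, sequence: str | np.ndarray) -> float:
        """F(a) = sum_i f_i(a_i); sequence must be motif-length, N-free."""
        idx = encode(sequence) if isinstance(sequence, str) else sequence
        if idx.size != self.length or np.any(idx < 0):
            raise ValueError("sequence must be motif-length and unambiguous")
        return float(self.f[np.arange(self.length), idx].sum())


def build_fitness(motif: Motif, background: Background) -> FitnessLandscape:
    """Information-based fitness landscape of a motif.

    The expectation of F under the motif distribution equals the motif's
    sequence information.
    """
    return FitnessLandscape(
        motif=motif, background=background, f=motif.log_odds(background)
    )


def _g(s: np.ndarray) -> np.ndarray:
    """Fixation factor g(s) = s / (1 - exp(-s)), numerically stable.

    g(0) = 1; g(s) -> s for large s; g(s) -> |s| e^{-|s|} for large -s.
    """
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    small = np.abs(s) < 1e-8
    out[small] = 1.0 + s[small] / 2.0  # expansion around 0
    pos = (~small) & (s > 0)
    neg = (~small) & (s < 0)
    out[pos] = s[pos] / (-np.expm1(-s[pos]))
    out[neg] = -s[neg] * np.exp(s[neg]) / (-np.expm1(s[neg]))
    return out


@dataclass(frozen=True)
class SubstitutionProcess:
    """Per-position 4x4 substitution rate matrices under selection."""

    landscape: FitnessLandscape
    mu: float
    mutation_model: str
    R: np.ndarray  # L x 4 x 4, rows sum to 0

    @property
    def length(self) -> int:
        return self.R.shape[0]


def build_rates(
    landscape: FitnessLandscape,
    mu: float = 1.0,
    mutation_model: str = "background-weighted",
) -> SubstitutionProcess:
    """Kimura--Ohta rate matrices from a fitness landscape.

    ``background-weighted`` mutation (m(alpha->beta) = p0(beta)) gives a
    reversible process with stationary motif distribution; ``uniform``
    (m = 1/4 to every target) retains stationarity only for uniform
    background.
    """
    if mutation_model not in MUTATION_MODELS:
        raise ValueError(f"unknown mutation model {mutation_model!r}")
    if not np.all(np.isfinite(landscape.f)):
        raise ValueError("non-finite fitness values")
    L = landscape.length
    if mutation_model == "background-weighted":
        m = np.tile(landscape.background.p0, (4, 1))
    else:
        m = np.full((4, 4), 0.25)
    R = np.zeros((L, 4, 4))
    for i in range(L):
        s = landscape.f[i][None, :] - landscape.f[i][:, None]  # s[a, b] = f_b - f_a
        Ri = mu * m * _g(s)
        np.fill_diagonal(Ri, 0.0)
        np.fill_diagonal(Ri, -Ri.sum(axis=1))
        R[i] = Ri
    return SubstitutionProcess(
        landscape=landscape, mu=mu, mutation_model=mutation_model, R=R
    )


@dataclass(frozen=True)
class Propagator:
    """Per-position transition matrices G_i(t) = exp(t R_i)."""

    process: SubstitutionProcess
    t: float
    G: np.ndarray  # L x 4 x 4, stochastic

    @property
    def length(self) -> int:
        return self.G.shape[0]


def propagate(process: SubstitutionProcess, t: float) -> Propagator:
    """Transition probabilities after evolutionary distance t >= 0.

    For the reversible background-weighted process the matrix exponential is
    computed by symmetrization and eigendecomposition; otherwise via the
    general Pade-based exponential.  Tiny negative entries are clipped and
    rows renormalized.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    L = process.length
    G = np.empty((L, 4, 4))
    reversible = process.mutation_model == "background-weighted"
    q = process.landscape.motif.freq
    for i in range(L):
        if reversible:
            d = np.sqrt(q[i])
            A = (d[:, None] / d[None, :]) * process.R[i]
            A = 0.5 * (A + A.T)  # exactly symmetric up to round-off
            w, V = np.linalg.eigh(A)
            Gi = (V * np.exp(t * w)) @ V.T
            Gi = (1.0 / d)[:, None] * Gi * d[None, :]
        else:
            Gi = scipy.linalg.expm(t * process.R[i])
        Gi = np.clip(Gi, 0.0, None)
        Gi /= Gi.sum(axis=1, keepdims=True)
        G[i] = Gi
    return Propagator(process=process, t=t, G=G)


# ---------------------------------------------------------------------------
# Site pairs and descent likelihoods


@dataclass
class SitePair:
    """A pair of binding sites compared in a gapless alignment.

    When motif lengths differ, the shorter motif is slid within the longer
    one; ``offset`` is the start of the aligned block inside the longer
    motif and ``aligned_length = min(L_A, L_B)``.  Overhang columns of the
    longer motif contribute their own motif marginal to both descent
    likelihoods, so the score compares the same columns under both models.
    """

    site_a: SiteInstance
    site_b: SiteInstance
    distance: int
    offset: int = 0

    def __post_init__(self):
        la, lb = self.site_a.motif.length, self.site_b.motif.length
        if not (0 <= self.offset <= abs(la - lb)):
            raise ValueError("offset out of range")

    @property
    def aligned_length(self) -> int:
        return min(self.site_a.motif.length, self.site_b.motif.length)

    @property
    def factors(self) -> tuple[str, str]:
        return (self.site_a.motif.name, self.site_b.motif.name)


def _aligned_columns(pair: SitePair) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Aligned (motif-column indices, letters) for A and B."""
    la, lb = pair.site_a.motif.length, pair.site_b.motif.length
    n = pair.aligned_length
    a = encode(pair.site_a.sequence)
    b = encode(pair.site_b.sequence)
    if la <= lb:
        cols_a = np.arange(n)
        cols_b = pair.offset + np.arange(n)
    else:
        cols_a = pair.offset + np.arange(n)
        cols_b = np.arange(n)
    return cols_a, a[cols_a], cols_b, b[cols_b]


def _overhang_logmarginal(pair: SitePair) -> float:
    """Log-probability of the longer motif's unaligned letters under its own
    motif marginal (identical under both descent models)."""
    la, lb = pair.site_a.motif.length, pair.site_b.motif.length
    if la == lb:
        return 0.0
    if la > lb:
        motif, seq, n, off = pair.site_a.motif, encode(pair.site_a.sequence), lb, pair.offset
    else:
        motif, seq, n, off = pair.site_b.motif, encode(pair.site_b.sequence), la, pair.offset
    cols = np.concatenate([np.arange(off), np.arange(off + n, motif.length)])
    return float(np.log(motif.freq[cols, seq[cols]]).sum())


def p_independent(pair: SitePair) -> float:
    """Probability of the pair under independent descent:
    product over aligned columns of q_A(a_i) q_B(b_j), times the overhang
    marginals of the longer motif."""
    ca, a, cb, b = _aligned_columns(pair)
    qa = pair.site_a.motif.freq[ca, a]
    qb = pair.site_b.motif.freq[cb, b]
    return float(np.exp(np.log(qa).sum() + np.log(qb).sum() + _overhang_logmarginal(pair)))


def _column_joint(
    prop_a: Propagator, prop_b: Propagator, cols_a: np.ndarray, cols_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per aligned column, the 4x4 joint matrices J[a, b] for the
    A-ancestral and B-ancestral histories."""
    qa = prop_a.process.landscape.motif.freq
    qb = prop_b.process.landscape.motif.freq
    n = cols_a.size
    JA = np.empty((n, 4, 4))
    JB = np.empty((n, 4, 4))
    for k in range(n):
        GA = prop_a.G[cols_a[k]]
        GB = prop_b.G[cols_b[k]]
        JA[k] = GA.T @ (qa[cols_a[k], :, None] * GB)  # sum_c q_A(c) G_A(a|c) G_B(b|c)
        JB[k] = GA.T @ (qb[cols_b[k], :, None] * GB)
    return JA, JB


def p_duplication(pair: SitePair, t: float) -> float:
    """Probability of the pair under duplication of a common ancestor at
    evolutionary distance t, with equal prior on which site kept the
    ancestral function."""
    if t < 0:
        raise ValueError("t must be non-negative")
    prop_a = propagate(build_rates(build_fitness(pair.site_a.motif, pair.site_a.background)), t)
    prop_b = propagate(build_rates(build_fitness(pair.site_b.motif, pair.site_b.background)), t)
    return p_duplication_from_propagators(pair, prop_a, prop_b)


def p_duplication_from_propagators(
    pair: SitePair, prop_a: Propagator, prop_b: Propagator
) -> float:
    """As :func:`p_duplication`, reusing precomputed propagators."""
    ca, a, cb, b = _aligned_columns(pair)
    JA, JB = _column_joint(prop_a, prop_b, ca, cb)
    k = np.arange(ca.size)
    with np.errstate(divide="ignore"):  # zero entries occur at t = 0
        log_pa = np.log(JA[k, a, b]).sum()
        log_pb = np.log(JB[k, a, b]).sum()
    m = max(log_pa, log_pb)
    if np.isneginf(m):
        return 0.0
    log_pdup = m + np.log(0.5 * (np.exp(log_pa - m) + np.exp(log_pb - m)))
    return float(np.exp(log_pdup + _overhang_logmarginal(pair)))


def choose_offset(pair: SitePair, t: float) -> int:
    """Pick the gapless alignment offset maximizing P_dup at distance t
    (ties to the smallest offset); identical columns are then used for
    P_ind so the likelihood ratio is well defined."""
    la, lb = pair.site_a.motif.length, pair.site_b.motif.length
    span = abs(la - lb)
    if span == 0:
        return 0
    best, best_p = 0, -np.inf
    for off in range(span + 1):
        cand = SitePair(pair.site_a, pair.site_b, pair.distance, offset=off)
        p = p_duplication(cand, t)
        if p > best_p * (1 + 1e-12):
            best, best_p = off, p
    return best
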