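"""Binding correlation between transcription factors.

The binding correlation C(A->B) is the average information-based fitness of
A-motif sites under the B-factor's landscape,

    C(A->B) = sum_i sum_alpha q^A_i(alpha) ln( q^B_i(alpha) / p0(alpha) ),

the cross-entropy (up to a constant) between the motif distributions.  It
satisfies C(A->A) = I_A and C(A->B) = I_A - D(Q_A || Q_B) <= I_A for motifs
compared over the same columns, and is bounded below in expectation by the
background average -D(P0 || Q_B) <= 0.  A large C(A->B), comparable to the
fitness of weak B-sites, means a duplicated A-site can act as a seed from
which point mutations can build a functional B-site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evolution_model import build_fitness
from .seq_io import Background, Motif, SiteInstance

LN2 = float(np.log(2.0))


@dataclass
class CorrelationRecord:
    """Cross-motif fitness statistics for an ordered factor pair (A, B)."""

    factor_a: str
    factor_b: str
    offset: int
    C_ab: float  # nats
    I_a: float  # sequence information of A over the aligned columns (nats)
    I_b: float  # sequence information of B over the aligned columns (nats)
    bg_b: float  # background average fitness for B over aligned columns (<= 0)
    site_fitness_values: np.ndarray | None = None  # F_B over known B sites

    @property
    def C_ab_bits(self) -> float:
        return self.C_ab / LN2


def _aligned_cols(la: int, lb: int, offset: int) -> tuple[np.ndarray, np.ndarray]:
    n = min(la, lb)
    if la <= lb:
        return np.arange(n), offset + np.arange(n)
    return offset + np.arange(n), np.arange(n)


def _cross_entropy_terms(
    qa: np.ndarray, qb: np.ndarray, p0: np.ndarray, offset: int
) -> tuple[float, float, float, float]:
    ca, cb = _aligned_cols(qa.shape[0], qb.shape[0], offset)
    A = qa[ca]
    B = qb[cb]
    lb = np.log(B) - np.log(p0)[None, :]
    la = np.log(A) - np.log(p0)[None, :]
    C_ab = float(np.sum(A * lb))
    I_a = float(np.sum(A * la))
    I_b = float(np.sum(B * lb))
    bg_b = float(np.sum(p0[None, :] * lb))
    return C_ab, I_a, I_b, bg_b


def binding_correlation(
    motif_a: Motif,
    motif_b: Motif,
    background: Background,
    sites_b: Sequence[SiteInstance] | None = None,
) -> CorrelationRecord:
    """Binding correlation C(A->B) with its reference quantities.

    When motif lengths differ, the shorter motif is slid within the longer
    one and the full-overlap offset maximizing C(A->B) is used (ties to the
    smallest offset); all reported quantities refer to those aligned
    columns.  If ``sites_b`` is given, the fitness F_B of each known B site
    is attached for context.
    """
    span = abs(motif_a.length - motif_b.length)
    best_off, best = 0, -np.inf
    for off in range(span + 1):
        c_ab, *_ = _cross_entropy_terms(
            motif_a.freq, motif_b.freq, background.p0, off
        )
        if c_ab > best + 1e-15:
            best, best_off = c_ab, off
    C_ab, I_a, I_b, bg_b = _cross_entropy_terms(
        motif_a.freq, motif_b.freq, background.p0, best_off
    )
    fitness_values = None
    if sites_b is not None:
        land_b = build_fitness(motif_b, background)
        fitness_values = np.array([land_b.fitness(s.sequence) for s in sites_b])
    return CorrelationRecord(
        factor_a=motif_a.name,
        factor_b=motif_b.name,
        offset=best_off,
        C_ab=C_ab,
        I_a=I_a,
        I_b=I_b,
        bg_b=bg_b,
        site_fitness_values=fitness_values,
    )
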