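"""Synthetic inputs for the duplication-detection pipeline.

Three generators, all bit-reproducible from an explicit seed:

* first-order Markov background sequences matching given mono- and
  dinucleotide statistics (the null model for pair-count calibration);
* regulatory modules with planted pairs of duplicated segments at
  controlled lags, with a ground-truth table for recovery scoring;
* ensembles of binding-site pairs evolving by common descent (ancestor
  drawn from one of the two motif equilibria, exponential divergence times,
  duplication then divergence under the two fitness landscapes) or by
  independent descent (each site drawn from its own motif distribution).

The ensemble generator follows the simulation-validation protocol used to
test the duplication-score inference: several factor pairs (some equal,
some different), a set of duplication events with divergence time
tau ~ Exponential(tau_bar), and a batch of site pairs drawn per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evolution_model import SitePair, build_fitness, build_rates, propagate
from .seq_io import (
    ALPHABET,
    Background,
    Motif,
    RegulatoryModule,
    SiteAnnotation,
    SiteInstance,
    decode,
    encode,
)


# ---------------------------------------------------------------------------
# Background sequence


def sample_markov(
    background: Background,
    length: int,
    n_sequences: int,
    seed: int | np.random.Generator | None = 0,
) -> list[str]:
    """Seeded first-order Markov sequences with the given statistics.

    Initial letters follow p0; subsequent letters follow the dinucleotide
    conditional rows.  Sampling is inverse-CDF from a single stream, one
    position at a time across all sequences.
    """
    if background.dinucleotide is None:
        raise ValueError("background must carry dinucleotide conditionals")
    if length < 1 or n_sequences < 1:
        raise ValueError("length and n_sequences must be positive")
    rows = background.dinucleotide
    if np.any(rows.sum(axis=1) <= 0):
        raise ValueError("degenerate transition matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum0 = np.cumsum(background.p0)
    cum = np.cumsum(rows, axis=1)
    out = np.empty((n_sequences, length), dtype=np.int8)
    out[:, 0] = np.searchsorted(cum0, rng.random(n_sequences) * cum0[-1])
    for j in range(1, length):
        u = rng.random(n_sequences)
        rowcum = cum[out[:, j - 1]]
        out[:, j] = (rowcum > (u * rowcum[:, -1])[:, None]).argmax(axis=1)
    return [decode(row) for row in out]


# ---------------------------------------------------------------------------
# Planted-duplication modules


def plant_correlated_modules(
    n_modules: int,
    module_length: int,
    motif_length: int,
    pair_distances: Sequence[int],
    n_pairs: int,
    background: Background | None = None,
    seed: int | np.random.Generator | None = 0,
    mismatches: int = 0,
) -> tuple[list[RegulatoryModule], pd.DataFrame]:
    """Markov-background modules with planted duplicated segments.

    Each module receives ``n_pairs`` left/right copies, cycling through
    ``pair_distances``: the left segment is the background sequence itself
    and the right segment is its copy (with ``mismatches`` random
    substitutions) placed ``lag`` bp downstream.  Pairs occupy disjoint
    blocks, so planted pairs do not overlap each other.  Returns the modules
    and a truth table (module_id, lag, left_pos).
    """
    if n_pairs > 0:
        if max(pair_distances) > module_length - 2 * motif_length:
            raise ValueError("requested lag does not fit in the module")
        block = max(pair_distances) + 2 * motif_length
        if n_pairs * block > module_length:
            raise ValueError("too many pairs for the module length")
    bg = background if background is not None else Background.uniform()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs = sample_markov(bg, module_length, n_modules, rng)
    modules: list[RegulatoryModule] = []
    truth_rows = []
    for m_idx, s in enumerate(seqs):
        arr = encode(s)
        mod_id = f"sim_module_{m_idx}"
        if n_pairs > 0:
            block = max(pair_distances) + 2 * motif_length
            slack = module_length - n_pairs * block
            offsets = np.sort(rng.choice(slack + 1, size=n_pairs, replace=True)) if slack > 0 else np.zeros(n_pairs, dtype=int)
            for k in range(n_pairs):
                lag = int(pair_distances[(m_idx * n_pairs + k) % len(pair_distances)])
                x = int(k * block + offsets[k])
                copy = arr[x : x + motif_length].copy()
                if mismatches > 0:
                    pos = rng.choice(motif_length, size=min(mismatches, motif_length), replace=False)
                    for p in pos:
                        copy[p] = (copy[p] + 1 + rng.integers(3)) % 4
                arr[x + lag : x + lag + motif_length] = copy
                truth_rows.append({"module_id": mod_id, "lag": lag, "left_pos": x})
        modules.append(
            RegulatoryModule(
                id=mod_id, chrom=mod_id, start=0, end=module_length,
                sequence=decode(arr),
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["module_id", "lag", "left_pos"])
    return modules, truth


# ---------------------------------------------------------------------------
# Motifs and site-pair ensembles


def random_motif(
    name: str,
    length: int = 7,
    seed: int | np.random.Generator | None = 0,
    peak_lo: float = 0.6,
    peak_hi: float = 0.95,
) -> Motif:
    """A random peaked motif: one preferred base per position with weight
    drawn in [peak_lo, peak_hi], the remainder spread over the other bases.
    Defaults give information contents typical of eukaryotic factors
    (roughly 6-12 bits at length 7)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = np.empty((length, 4))
    for i in range(length):
        peak = rng.uniform(peak_lo, peak_hi)
        rest = rng.dirichlet(np.ones(3)) * (1 - peak)
        row = np.empty(4)
        pref = rng.integers(4)
        row[pref] = peak
        row[[j for j in range(4) if j != pref]] = rest
        freq[i] = row / row.sum()
    return Motif(name=name, freq=freq)


def sample_from_motif(motif: Motif, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n site sequences (n x L int array) from the motif distribution."""
    cum = np.cumsum(motif.freq, axis=1)
    u = rng.random((n, motif.length))
    return np.stack(
        [(cum[j] > u[:, j][:, None]).argmax(axis=1) for j in range(motif.length)],
        axis=1,
    ).astype(np.int8)


def make_site_instance(
    motif: Motif,
    sequence: str,
    background: Background,
    module_id: str = "sim",
    start: int = 0,
) -> SiteInstance:
    """Wrap a raw sequence as a plus-strand SiteInstance (synthetic plumbing)."""
    ann = SiteAnnotation(
        module_id=module_id,
        chrom=module_id,
        start=start,
        end=start + motif.length,
        strand="+",
        factor=motif.name,
    )
    return SiteInstance(annotation=ann, sequence=sequence, motif=motif, background=background)


@dataclass
class SimulationConfig:
    """Study conditions for the site-pair evolution simulation."""

    motif_pairs: list[tuple[Motif, Motif]]
    tau_bar: float = 1.0
    n_events: int = 100
    pairs_per_event: int = 10
    n_independent: int = 1000
    seed: int = 0
    mutation_model: str = "background-weighted"
    mu: float = 1.0
    background: Background = field(default_factory=Background.uniform)
    near_distance_range: tuple[int, int] = (5, 50)
    far_distance_range: tuple[int, int] = (100, 300)

    def __post_init__(self):
        if self.tau_bar <= 0:
            raise ValueError("tau_bar must be positive")
        if min(self.n_events, self.pairs_per_event) < 1 or self.n_independent < 0:
            raise ValueError("counts must be positive")
        for a, b in self.motif_pairs:
            if a.length != b.length:
                raise ValueError(
                    "simulated motif pairs must have equal length "
                    f"({a.name}: {a.length}, {b.name}: {b.length})"
                )


@dataclass
class SimulatedEnsemble:
    """Labelled site pairs with their generating conditions."""

    pairs: list[SitePair]
    labels: np.ndarray  # 'common' or 'independent' per pair
    tau: np.ndarray  # true divergence time per pair (nan for independent)
    config: SimulationConfig

    def subset(self, label: str) -> list[SitePair]:
        return [p for p, l in zip(self.pairs, self.labels) if l == label]


def _sample_descendant(
    G: np.ndarray, ancestor: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n descendants of one ancestor: position j evolves by row G[j, c_j]."""
    L = ancestor.size
    out = np.empty((n, L), dtype=np.int8)
    for j in range(L):
        row = G[j, ancestor[j]]
        cum = np.cumsum(row)
        out[:, j] = (cum > (rng.random(n) * cum[-1])[:, None]).argmax(axis=1)
    return out


def simulate_pair_ensemble(config: SimulationConfig) -> SimulatedEnsemble:
    """Simulate site-pair ensembles of common and independent descent.

    For each motif pair (A, B) and each of ``n_events`` duplication events:
    the common ancestor is drawn with equal probability from Q_A or Q_B, the
    divergence time tau from Exponential(tau_bar), and ``pairs_per_event``
    pairs are drawn with a ~ G_A(.|c; tau) and b ~ G_B(.|c; tau) per
    position.  ``n_independent`` pairs per motif pair are drawn as a ~ Q_A,
    b ~ Q_B.  Pair distances are drawn uniformly from the near range for
    common descent and the far range for independent descent.
    """
    rng = np.random.default_rng(config.seed)
    bg = config.background
    pairs: list[SitePair] = []
    labels: list[str] = []
    taus: list[float] = []
    pair_counter = 0
    for motif_a, motif_b in config.motif_pairs:
        proc_a = build_rates(
            build_fitness(motif_a, bg), mu=config.mu, mutation_model=config.mutation_model
        )
        proc_b = build_rates(
            build_fitness(motif_b, bg), mu=config.mu, mutation_model=config.mutation_model
        )
        # common descent: duplication events, then divergence
        event_tau = rng.exponential(config.tau_bar, size=config.n_events)
        for tau in event_tau:
            source = motif_a if rng.random() < 0.5 else motif_b
            ancestor = sample_from_motif(source, 1, rng)[0]
            GA = propagate(proc_a, float(tau)).G
            GB = propagate(proc_b, float(tau)).G
            a_seqs = _sample_descendant(GA, ancestor, config.pairs_per_event, rng)
            b_seqs = _sample_descendant(GB, ancestor, config.pairs_per_event, rng)
            dists = rng.integers(
                config.near_distance_range[0],
                config.near_distance_range[1] + 1,
                size=config.pairs_per_event,
            )
            for a, b, r in zip(a_seqs, b_seqs, dists):
                pairs.append(
                    SitePair(
                        make_site_instance(motif_a, decode(a), bg, start=pair_counter * 100),
                        make_site_instance(motif_b, decode(b), bg, start=pair_counter * 100 + int(r)),
                        distance=int(r),
                    )
                )
                labels.append("common")
                taus.append(float(tau))
                pair_counter += 1
        # independent descent
        a_seqs = sample_from_motif(motif_a, config.n_independent, rng)
        b_seqs = sample_from_motif(motif_b, config.n_independent, rng)
        dists = rng.integers(
            config.far_distance_range[0],
            config.far_distance_range[1] + 1,
            size=config.n_independent,
        )
        for a, b, r in zip(a_seqs, b_seqs, dists):
            pairs.append(
                SitePair(
                    make_site_instance(motif_a, decode(a), bg, start=pair_counter * 100),
                    make_site_instance(motif_b, decode(b), bg, start=pair_counter * 100 + int(r)),
                    distance=int(r),
                )
            )
            labels.append("independent")
            taus.append(float("nan"))
            pair_counter += 1
    return SimulatedEnsemble(
        pairs=pairs, labels=np.array(labels), tau=np.array(taus), config=config
    )
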