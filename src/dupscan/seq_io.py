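"""Reading regulatory sequence data and preparing binding-site instances.

This module handles the standard formats at the boundary of the analysis:
FASTA for regulatory-module sequences, BED6+1 for binding-site annotations
(column 7 carries the module id), and JASPAR-style matrix files for binding
motifs.  It also implements the site-curation filters used to obtain an
unbiased site set, strand-aware extraction of motif-length site sequences,
and estimation of local background nucleotide frequencies.

Coordinates are 0-based half-open throughout (BED semantics).  Minus-strand
sites are reverse-complemented into motif orientation before any scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0, C=1, G=2, T=3, other=-1)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] if i >= 0 else "N" for i in indices)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegulatoryModule:
    """A cis-regulatory module: a contiguous genomic segment with its sequence."""

    id: str
    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"module {self.id}: end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"module {self.id}: sequence length {len(self.sequence)} "
                f"!= end - start = {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteAnnotation:
    """An annotated transcription-factor binding site inside a module."""

    module_id: str
    chrom: str
    start: int
    end: int
    strand: str
    factor: str

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("site interval must have length >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "SiteAnnotation") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Background:
    """Background nucleotide statistics of a sequence region.

    ``p0`` is the single-nucleotide frequency vector (A, C, G, T) and
    ``dinucleotide`` the 4x4 conditional frequency matrix
    P(next = beta | current = alpha) used by the first-order Markov null.
    ``q0 = sum(p0**2)`` is the probability that two random letters match.
    """

    p0: np.ndarray
    dinucleotide: np.ndarray | None = None

    def __post_init__(self):
        p0 = np.asarray(self.p0, dtype=float)
        object.__setattr__(self, "p0", p0)
        if p0.shape != (4,) or np.any(p0 <= 0):
            raise ValueError("p0 must be a strictly positive 4-vector")
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("p0 must sum to 1")
        if self.dinucleotide is not None:
            d = np.asarray(self.dinucleotide, dtype=float)
            object.__setattr__(self, "dinucleotide", d)
            if d.shape != (4, 4) or np.any(np.abs(d.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("dinucleotide rows must sum to 1")

    @property
    def q0(self) -> float:
        return float(np.sum(self.p0**2))

    @staticmethod
    def uniform() -> "Background":
        return Background(p0=np.full(4, 0.25), dinucleotide=np.full((4, 4), 0.25))

    @staticmethod
    def from_counts(counts: np.ndarray, pseudocount: float = 0.5) -> "Background":
        counts = np.asarray(counts, dtype=float)
        counts = counts + pseudocount / 4.0
        return Background(p0=counts / counts.sum())

    @staticmethod
    def from_sequences(
        sequences: Iterable[str], pseudocount: float = 0.5
    ) -> "Background":
        """Estimate mono- and dinucleotide frequencies from sequences (N skipped)."""
        mono = np.zeros(4)
        di = np.zeros((4, 4))
        for seq in sequences:
            s = encode(seq)
            valid = s >= 0
            mono += np.bincount(s[valid], minlength=4)
            a, b = s[:-1], s[1:]
            ok = (a >= 0) & (b >= 0)
            np.add.at(di, (a[ok], b[ok]), 1.0)
        mono = mono + pseudocount / 4.0
        di = di + pseudocount / 4.0
        return Background(
            p0=mono / mono.sum(), dinucleotide=di / di.sum(axis=1, keepdims=True)
        )

    @staticmethod
    def from_sequence(sequence: str, pseudocount: float = 0.5) -> "Background":
        return Background.from_sequences([sequence], pseudocount=pseudocount)


@dataclass(frozen=True)
class Motif:
    """A binding motif: position weight matrix q_i(alpha) over columns A,C,G,T.

    Rows are strictly positive and sum to one; a pseudocount is applied at
    construction so logarithms and substitution rates are always finite.
    """

    name: str
    freq: np.ndarray

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise ValueError("freq must be an Lx4 matrix")
        if np.any(freq <= 0):
            raise ValueError("motif frequencies must be strictly positive")
        if np.any(np.abs(freq.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("motif rows must sum to 1")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @staticmethod
    def from_counts(
        name: str,
        counts: np.ndarray,
        background: Background | None = None,
        pseudocount: float = 0.5,
    ) -> "Motif":
        """Build a motif from a count (or frequency) matrix.

        A total pseudocount of ``pseudocount`` per position, distributed
        proportionally to the background frequencies, is added before
        normalization.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be an Lx4 matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        p0 = background.p0 if background is not None else np.full(4, 0.25)
        counts = counts + pseudocount * p0[None, :]
        return Motif(name=name, freq=counts / counts.sum(axis=1, keepdims=True))

    def log_odds(self, background: Background) -> np.ndarray:
        """Per-position log-odds ln(q_i(alpha)/p0(alpha)) — the additive
        fitness contributions of the information-based landscape."""
        return np.log(self.freq) - np.log(background.p0)[None, :]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.freq, axis=1))


@dataclass(frozen=True)
class SiteInstance:
    """A binding site bound to its motif: motif-oriented sequence of length L."""

    annotation: SiteAnnotation
    sequence: str
    motif: Motif
    background: Background

    def __post_init__(self):
        if len(self.sequence) != self.motif.length:
            raise ValueError("site sequence length must equal motif length")


# ---------------------------------------------------------------------------
# Parsing


def read_fasta_modules(path: str | Path) -> dict[str, RegulatoryModule]:
    """Read regulatory modules from FASTA.

    The record id is the module id.  If the description contains a
    ``chrom:start-end`` location token, genomic coordinates are taken from
    it; otherwise the module defines its own coordinate system
    (chrom = module id, start = 0).
    """
    modules: dict[str, RegulatoryModule] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        chrom, start, end = rec.id, 0, len(seq)
        for token in rec.description.split()[1:]:
            if ":" in token and "-" in token.split(":", 1)[1]:
                c, span = token.split(":", 1)
                lo, hi = span.split("-", 1)
                try:
                    chrom, start, end = c, int(lo), int(hi)
                except ValueError:
                    continue
                break
        modules[rec.id] = RegulatoryModule(
            id=rec.id, chrom=chrom, start=start, end=end, sequence=seq
        )
    return modules


def write_fasta_modules(modules: Iterable[RegulatoryModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in modules:
            fh.write(f">{m.id} {m.chrom}:{m.start}-{m.end}\n")
            for i in range(0, len(m.sequence), 80):
                fh.write(m.sequence[i : i + 80] + "\n")


def read_bed_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read site annotations from BED6+1 (name = factor, column 7 = module id)."""
    sites: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 BED columns, got {len(fields)}"
                )
            chrom, start, end, factor, _score, strand, module_id = fields[:7]
            sites.append(
                SiteAnnotation(
                    module_id=module_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    factor=factor,
                )
            )
    return sites


def write_bed_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.factor}\t0\t{s.strand}"
                f"\t{s.module_id}\n"
            )


def read_jaspar_motifs(
    path: str | Path,
    background: Background | None = None,
    pseudocount: float = 0.5,
) -> dict[str, Motif]:
    """Read JASPAR-format matrices (counts or frequencies) into motifs."""
    from Bio import motifs as bio_motifs

    out: dict[str, Motif] = {}
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # Biopython raises assorted parse errors
            raise ValueError(f"malformed JASPAR matrix file {path}: {exc}") from exc
        for rec in records:
            counts = np.array(
                [[rec.counts[b][i] for b in ALPHABET] for i in range(rec.length)],
                dtype=float,
            )
            name = rec.name or rec.matrix_id
            out[name] = Motif.from_counts(
                name, counts, background=background, pseudocount=pseudocount
            )
    return out


def write_jaspar_motifs(motifs: Iterable[Motif], path: str | Path) -> None:
    """Write motifs as JASPAR matrices.

    Frequencies are written as counts at a large nominal depth so that the
    pseudocount applied on re-reading perturbs them negligibly.
    """
    depth = 1e6
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for j, base in enumerate(ALPHABET):
                row = " ".join(f"{v * depth:.2f}" for v in m.freq[:, j])
                fh.write(f"{base} [ {row} ]\n")


def read_regulatory_set(
    fasta_path: str | Path, bed_path: str | Path, motif_path: str | Path
) -> tuple[dict[str, RegulatoryModule], list[SiteAnnotation], dict[str, Motif]]:
    """Load a full analysis input: modules, site annotations, and motifs.

    Validates that every annotation lies inside its module and that every
    factor name resolves to a motif.
    """
    modules = read_fasta_modules(fasta_path)
    annotations = read_bed_sites(bed_path)
    motifs = read_jaspar_motifs(motif_path)
    for ann in annotations:
        if ann.module_id not in modules:
            raise KeyError(f"site refers to unknown module {ann.module_id!r}")
        mod = modules[ann.module_id]
        if ann.chrom != mod.chrom or ann.start < mod.start or ann.end > mod.end:
            raise ValueError(
                f"site {ann.factor}@{ann.chrom}:{ann.start}-{ann.end} lies "
                f"outside module {mod.id} ({mod.chrom}:{mod.start}-{mod.end})"
            )
        if ann.factor not in motifs:
            raise KeyError(f"no motif for factor {ann.factor!r}")
    return modules, annotations, motifs


# ---------------------------------------------------------------------------
# Curation and extraction


def curate_sites(annotations: Sequence[SiteAnnotation]) -> list[SiteAnnotation]:
    """Apply the three bias-avoiding site filters.

    (iii) sites on the X chromosome are excluded (high recent-duplication
    and repeat activity); (ii) sites with any sequence overlap with another
    site are excluded (the fitness landscapes describe selection for a
    single function); (i) only factors whose sites occur in at least two
    distinct modules are kept (so a motif is not shaped by one module's
    sequence context).  Deterministic, order-preserving, idempotent.
    """
    def _is_x(chrom: str) -> bool:
        c = chrom[3:] if chrom.lower().startswith("chr") else chrom
        return c.upper() == "X"

    kept = [a for a in annotations if not _is_x(a.chrom)]

    # remove every member of any overlapping pair
    overlapping: set[int] = set()
    by_chrom: dict[str, list[tuple[int, SiteAnnotation]]] = {}
    for i, a in enumerate(kept):
        by_chrom.setdefault(a.chrom, []).append((i, a))
    for items in by_chrom.values():
        items.sort(key=lambda ia: (ia[1].start, ia[1].end))
        for k in range(len(items)):
            i, a = items[k]
            for j, b in items[k + 1 :]:
                if b.start >= a.end:
                    break
                overlapping.update((i, j))
    kept = [a for i, a in enumerate(kept) if i not in overlapping]

    modules_per_factor: dict[str, set[str]] = {}
    for a in kept:
        modules_per_factor.setdefault(a.factor, set()).add(a.module_id)
    return [a for a in kept if len(modules_per_factor[a.factor]) >= 2]


def extract_site_sequences(
    modules: Mapping[str, RegulatoryModule],
    annotations: Sequence[SiteAnnotation],
    motifs: Mapping[str, Motif],
    background: Background | None = None,
    flank_bp: int | None = None,
) -> list[SiteInstance]:
    """Extract motif-oriented site sequences of length exactly L per site.

    When an annotated footprint does not match its motif length, longer
    footprints are cut and shorter ones extended with flanking nucleotides:
    among all gapless windows of length L overlapping the annotation, the
    one maximizing the additive fitness F(a) (binding affinity under the
    motif's landscape) is returned; ties go to the leftmost window.
    Windows containing N are disqualified.  A site whose module cannot
    supply a valid window is skipped with a warning.

    ``background`` defaults to module-wide frequencies; if ``flank_bp`` is
    given, a local background is estimated around each site instead.
    """
    instances: list[SiteInstance] = []
    module_bg = {
        mid: Background.from_sequence(m.sequence) for mid, m in modules.items()
    }
    for ann in annotations:
        motif = motifs[ann.factor]
        L = motif.length
        mod = modules[ann.module_id]
        if flank_bp is not None:
            bg = local_background(mod, ann, flank_bp)
        else:
            bg = background if background is not None else module_bg[ann.module_id]
        s = ann.start - mod.start
        e = ann.end - mod.start
        if e - s == L:
            raw = mod.sequence[s:e]
            if "N" in raw:
                logger.warning("site %s@%d contains N; skipped", ann.factor, ann.start)
                continue
            seq = raw if ann.strand == "+" else reverse_complement(raw)
            instances.append(SiteInstance(ann, seq, motif, bg))
            continue
        # candidate windows of length L overlapping [s, e)
        lo = max(0, s - L + 1)
        hi = min(len(mod) - L, e - 1)
        if hi < lo:
            logger.warning(
                "module %s too short for a length-%d window at site %s@%d; skipped",
                mod.id, L, ann.factor, ann.start,
            )
            continue
        f = motif.log_odds(bg)
        best_w, best_F = None, -np.inf
        for w in range(lo, hi + 1):
            raw = mod.sequence[w : w + L]
            if "N" in raw:
                continue
            oriented = raw if ann.strand == "+" else reverse_complement(raw)
            idx = encode(oriented)
            F = float(f[np.arange(L), idx].sum())
            if F > best_F + 1e-12:
                best_F, best_w = F, w
        if best_w is None:
            logger.warning(
                "no N-free window for site %s@%d in module %s; skipped",
                ann.factor, ann.start, mod.id,
            )
            continue
        raw = mod.sequence[best_w : best_w + L]
        seq = raw if ann.strand == "+" else reverse_complement(raw)
        instances.append(SiteInstance(ann, seq, motif, bg))
    return instances


def local_background(
    module: RegulatoryModule,
    site: SiteAnnotation,
    flank_bp: int = 1000,
    pseudocount: float = 0.5,
) -> Background:
    """Estimate background frequencies from flanks around a site.

    Counts come from ``flank_bp`` on each side of the site (site excluded),
    truncated at module edges.  If both flanks are empty the module-wide
    frequencies are used instead, with a warning.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    s = site.start - module.start
    e = site.end - module.start
    left = module.sequence[max(0, s - flank_bp) : s]
    right = module.sequence[e : e + flank_bp]
    flank = left + right
    if not flank:
        logger.warning(
            "empty flank for site %s@%d; falling back to module-wide background",
            site.factor, site.start,
        )
        return Background.from_sequence(module.sequence, pseudocount=pseudocount)
    return Background.from_sequences([left, right], pseudocount=pseudocount)
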