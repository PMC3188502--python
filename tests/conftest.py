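import numpy as np
import pytest

from dupscan import Background, Motif, random_motif
from dupscan.seq_io import (
    RegulatoryModule,
    SiteAnnotation,
    write_bed_sites,
    write_fasta_modules,
    write_jaspar_motifs,
)


@pytest.fixture
def uniform_bg() -> Background:
    return Background.uniform()


@pytest.fixture
def motif7() -> Motif:
    return random_motif("M7", length=7, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_regulatory_set(tmp_path):
    """Two modules, three sites, two motifs, written to disk."""
    rng = np.random.default_rng(7)
    seqs = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(2)]
    modules = [
        RegulatoryModule(id="mod1", chrom="chr2L", start=1000, end=1400, sequence=seqs[0]),
        RegulatoryModule(id="mod2", chrom="chr3R", start=5000, end=5400, sequence=seqs[1]),
    ]
    annotations = [
        SiteAnnotation("mod1", "chr2L", 1010, 1017, "+", "factorA"),
        SiteAnnotation("mod1", "chr2L", 1100, 1107, "-", "factorB"),
        SiteAnnotation("mod2", "chr3R", 5050, 5057, "+", "factorA"),
    ]
    motifs = [random_motif("factorA", 7, seed=1), random_motif("factorB", 7, seed=2)]
    fasta = tmp_path / "modules.fasta"
    bed = tmp_path / "sites.bed"
    jaspar = tmp_path / "motifs.jaspar"
    write_fasta_modules(modules, fasta)
    write_bed_sites(annotations, bed)
    write_jaspar_motifs(motifs, jaspar)
    return {
        "fasta": fasta,
        "bed": bed,
        "jaspar": jaspar,
        "modules": modules,
        "annotations": annotations,
        "motifs": motifs,
    }
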