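import hypothesis
import numpy as np
import pytest

from dhsenrich.io_formats import DhsTrack, GenomeAnnotation, TagSnp

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def annotation():
    """Two small chromosomes with hand-placed, stranded TSS."""
    return GenomeAnnotation(
        chromosomes={"chr1": 2_000_000, "chr2": 1_000_000},
        tss_sites=[
            ("chr1", 100_000, "+", "geneA"),
            ("chr1", 500_000, "-", "geneB"),
            ("chr1", 1_500_000, "+", "geneC"),
            ("chr2", 50_000, "-", "geneD"),
            ("chr2", 800_000, "+", "geneE"),
        ],
    )


@pytest.fixture
def random_annotation():
    """A denser random annotation for brute-force oracle checks."""
    rng = np.random.default_rng(42)
    sites = []
    for chrom, length in (("chr1", 2_000_000), ("chr2", 1_000_000)):
        for i, pos in enumerate(sorted(rng.integers(0, length, 40))):
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append((chrom, int(pos), strand, f"{chrom}_g{i}"))
    return GenomeAnnotation(
        chromosomes={"chr1": 2_000_000, "chr2": 1_000_000}, tss_sites=sites
    )


def snp(rsid="rs1", chrom="chr1", pos=1_000_000, p=1e-9, maf=0.2, cons=()):
    return TagSnp(
        rsid=rsid, chromosome=chrom, position=pos, pvalue=p, maf=maf,
        consequences=tuple(cons),
    )


@pytest.fixture
def make_snp():
    return snp


@pytest.fixture
def small_track():
    return DhsTrack(
        sample_id="S1",
        peaks=[("chr1", 100, 200), ("chr1", 300, 450), ("chr2", 0, 50)],
        tissue="kidney",
        replicate=1,
    )
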