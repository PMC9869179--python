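import numpy as np
import pytest

from hifmeta import (
    BindingSite,
    GeneAnnotation,
    GenomicInterval,
    SignatureSet,
    load_signature,
)


@pytest.fixture(scope="session")
def sig48():
    return load_signature("conserved48")


@pytest.fixture(scope="session")
def tiny_signature():
    return SignatureSet(genes=("SIG1", "SIG2", "SIG3", "SIG4", "SIG5"))


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


def random_sites(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500,
                 max_count=100.0):
    sites = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        sites.append(
            BindingSite(
                GenomicInterval(chrom, start, start + length),
                count=float(rng.uniform(0, max_count)),
            )
        )
    return sites


def random_annotation(rng, n, chroms=("chr1", "chr2"), span=100_000):
    return [
        GeneAnnotation(
            f"GENE{i:04d}",
            chroms[rng.integers(len(chroms))],
            int(rng.integers(0, span)),
            "+" if rng.random() < 0.5 else "-",
        )
        for i in range(n)
    ]
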