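import numpy as np
import pytest

from mutevo.neoantigens import Transcript
from mutevo.variants import FilterConfig, Variant, VariantCatalog

# 50-codon CDS with no internal stop; protein length 50
_CODONS_50 = (
    "ATG GAA GCT GTT AAA CTG GAT CGT TTC ATC "
    "AAC CCG AGC ACC TGG TAC GGT CAC ATG GCA "
    "GTG CTC GAC AGA TTT ATT AAT CCT TCC ACG "
    "TGG TAT GGC CAT GCC GTA CTT GAC CGC TTC "
    "ATA AAT CCA AGT ACA TGG TAC GGA CAC GCG "
).split()


@pytest.fixture(scope="session")
def cds_50() -> str:
    cds = "".join(_CODONS_50) + "TAA"
    assert len(cds) == 153
    return cds


@pytest.fixture
def transcript_50(cds_50) -> Transcript:
    return Transcript(id="TX1", gene="G1", cdna=cds_50, cds_start=1, cds_end=len(cds_50))


@pytest.fixture
def default_filter_config() -> FilterConfig:
    return FilterConfig()


def make_variant(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    depth=100,
    alt_count=30,
    alt_fwd=14,
    alt_rev=14,
    **kwargs,
) -> Variant:
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=depth,
        alt_count=alt_count,
        alt_fwd=alt_fwd,
        alt_rev=alt_rev,
        **kwargs,
    )


def random_catalog(rng: np.random.Generator, n: int, sample_id="S", timepoint="T0"):
    """Random valid catalog with a spread of strand patterns and AFs."""
    variants = []
    used = set()
    while len(variants) < n:
        pos = int(rng.integers(1, 100_000))
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        key = ("chr1", pos, str(ref), str(alt))
        if key in used:
            continue
        used.add(key)
        depth = int(rng.integers(1, 300))
        alt_count = int(rng.integers(0, depth + 1))
        non_terminal = int(rng.integers(0, alt_count + 1))
        fwd = int(rng.integers(0, non_terminal + 1))
        variants.append(
            Variant(
                chrom="chr1",
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                depth=depth,
                alt_count=alt_count,
                alt_fwd=fwd,
                alt_rev=non_terminal - fwd,
            )
        )
    return VariantCatalog(sample_id, timepoint, variants)
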