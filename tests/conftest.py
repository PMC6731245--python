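import numpy as np
import pandas as pd
import pytest

from germstrata.pedigree import Individual, MutationCall, Pedigree, TissueObservation


@pytest.fixture
def small_pedigree() -> Pedigree:
    """Two pedigrees of 2 parents + 3 WGS offspring each."""
    inds = []
    for p in ("A", "B"):
        inds += [
            Individual(f"{p}_F", "male", "parent", p),
            Individual(f"{p}_M", "female", "parent", p),
        ]
        for k in range(3):
            inds.append(
                Individual(
                    id=f"{p}_O{k}",
                    sex="male" if k % 2 == 0 else "female",
                    role="offspring",
                    pedigree_id=p,
                    mother_id=f"{p}_M",
                    father_id=f"{p}_F",
                    litter_index=k,
                    parental_age_weeks=16.0 + 8 * k,
                )
            )
    return Pedigree(inds)


def make_call(pos=100, alt_reads=50, ref_reads=50, individual="A_O0", chrom="chr1", **kw):
    return MutationCall(
        chrom=chrom,
        pos=pos,
        ref_allele="C",
        alt_allele="T",
        individual_id=individual,
        observations=[TissueObservation("spleen", ref_reads, alt_reads)],
        **kw,
    )


def call_table(rows) -> pd.DataFrame:
    """rows: (chrom, pos, ref, alt, individual, tissue, ref_reads, alt_reads)"""
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "individual",
            "tissue",
            "ref_reads",
            "alt_reads",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
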