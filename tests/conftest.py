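import numpy as np
import pandas as pd
import pytest

from protmr.sumstats import HarmonizedPair, VariantRecord


def pair(vid="v1", be=0.1, se_e=0.02, bo=0.05, se_o=0.01,
         eaf=0.3, flag="aligned") -> HarmonizedPair:
    return HarmonizedPair(vid, "A", be, se_e, eaf, bo, se_o, eaf, flag)


def variant(vid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
            beta=0.1, se=0.02, pval=1e-10, n=35000.0,
            trait_type="quantitative") -> VariantRecord:
    return VariantRecord(vid, chrom, pos, ea, oa, eaf, beta, se, pval, n,
                         trait_type=trait_type)


@pytest.fixture
def make_pair():
    return pair


@pytest.fixture
def make_variant():
    return variant


@pytest.fixture
def ratio_pairs():
    """Two instruments with ratio estimates 0.5 (w=100) and 1.0 (w=25)."""
    return [pair("a", be=1.0, se_e=0.01, bo=0.5, se_o=0.1),
            pair("b", be=1.0, se_e=0.01, bo=1.0, se_o=0.2)]
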