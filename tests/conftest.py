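import numpy as np
import pytest

import besthet as bh


@pytest.fixture
def sib_pedigree():
    """Two outbred full siblings (one brother, one sister) and their parents."""
    return bh.build_pedigree(
        [("f", "0", "0", "M"), ("m", "0", "0", "F"),
         ("s1", "f", "m", "M"), ("s2", "f", "m", "F")]
    )


@pytest.fixture
def inbred_sib_pedigree():
    """Full siblings whose parents are themselves brother and sister."""
    return bh.build_pedigree(
        [("gf", "0", "0", "M"), ("gm", "0", "0", "F"),
         ("p1", "gf", "gm", "M"), ("p2", "gf", "gm", "F"),
         ("c1", "p1", "p2", "M"), ("c2", "p1", "p2", "F")]
    )


@pytest.fixture
def avuncular_pedigree():
    """Aunt and nephew: the aunt's brother fathers the nephew."""
    return bh.build_pedigree(
        [("gf", "0", "0", "M"), ("gm", "0", "0", "F"),
         ("aunt", "gf", "gm", "F"), ("pa", "gf", "gm", "M"),
         ("sp", "0", "0", "F"), ("neph", "pa", "sp", "M")]
    )


@pytest.fixture
def xlinked_sib_pedigree():
    """Two brothers and two sisters with their parents (all sexes set)."""
    return bh.build_pedigree(
        [("f", "0", "0", "M"), ("m", "0", "0", "F"),
         ("b1", "f", "m", "M"), ("b2", "f", "m", "M"),
         ("g1", "f", "m", "F"), ("g2", "f", "m", "F")]
    )


@pytest.fixture
def sib_kinship():
    """Kinship matrix of an outbred diploid full-sib pair."""
    return bh.KinshipSpec(["a", "b"], np.array([[0.5, 0.25], [0.25, 0.5]]))


@pytest.fixture
def msat_spectrum():
    """Fixed synthetic 10-allele microsatellite-like spectrum (H ~= 0.82)."""
    return bh.LocusSpectrum(
        np.array([0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.05, 0.03, 0.02, 0.01])
    )


@pytest.fixture
def mixed_design():
    """The 60-individual design: 10 inbred full-sib, 10 outbred full-sib,
    10 avuncular pairs, each individual related to exactly one other."""
    return [
        bh.PairSpec("full_sib_inbred_sibmating", 10),
        bh.PairSpec("full_sib_outbred", 10),
        bh.PairSpec("avuncular", 10),
    ]
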