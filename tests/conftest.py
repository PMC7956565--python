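"""Shared fixtures and hypothesis configuration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from idpchar import refdata
from idpchar.sequences import ProteinSequence

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Strategy for random canonical protein sequences.
protein_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=120)


def build_domain_pair() -> tuple[ProteinSequence, ProteinSequence]:
    """Synthetic stand-ins for the two 66-residue ABA-WDS domains.

    The real sequences are not bundled; these constructions honor the
    published composition constraints instead: 66 residues, 9 K/R, 13 D/E
    and 9 His in the wheat-like domain, and the four reported substitutions
    (10 H->R, 17 A->V, 45 V->L, 63 Q->T) separating the barley-like domain
    from it.
    """
    res = ["A"] * 66
    for i in range(9):          # 9 positive residues (K)
        res[i] = "K"
    res[9] = "H"                # position 10 (His in the wheat-like domain)
    for i in range(10, 16):     # 6 acidic
        res[i] = "E"
    res[16] = "A"               # position 17
    for i in range(17, 24):     # 7 more acidic -> 13 D/E total
        res[i] = "D" if i % 2 else "E"
    for i in range(24, 32):     # 8 more His -> 9 total
        res[i] = "H"
    res[44] = "V"               # position 45
    res[62] = "Q"               # position 63
    tt = ProteinSequence(id="Tt-like", residues="".join(res), source="synthetic")
    hv_res = list(res)
    for pos, old, new in refdata.TT_HV_SUBSTITUTIONS:
        assert hv_res[pos - 1] == old
        hv_res[pos - 1] = new
    hv = ProteinSequence(id="Hv-like", residues="".join(hv_res), source="synthetic")
    return tt, hv


@pytest.fixture(scope="session")
def domain_pair():
    return build_domain_pair()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
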