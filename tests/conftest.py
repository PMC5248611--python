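"""Shared fixtures: a toy reference, a double-tiled panel and read builders."""

import numpy as np
import pytest

from smmipkit import design_tiled_panel, make_reference
from smmipkit.dna import revcomp
from smmipkit.reads import ReadPair


@pytest.fixture(scope="session")
def reference():
    return make_reference(5000, seed=42)


@pytest.fixture(scope="session")
def panel(reference):
    """20 probes in plus/minus pairs tiling 10 adjacent 112-nt targets."""
    return design_tiled_panel(reference, n_smmips=20)


def make_pair(smmip, captured_seq, tag="ACGTA", name="r", read_length=151):
    """Build a read pair for a probe from its captured-strand insert.

    Mirrors the documented layout: read 2 = tag + extension arm + insert...,
    read 1 = reverse complement from the ligation-arm side.
    """
    amplicon = tag + smmip.extension_arm + captured_seq + revcomp(smmip.ligation_arm)
    r2 = amplicon[:read_length]
    r1 = revcomp(amplicon)[:read_length]
    return ReadPair(name=name, r1=r1, q1="I" * len(r1), r2=r2, q2="I" * len(r2))


def captured(reference, smmip):
    """The probe's reference insert on its targeted strand."""
    window = reference[smmip.target_start : smmip.target_end]
    return window if smmip.targeted_strand == "+" else revcomp(window)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
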