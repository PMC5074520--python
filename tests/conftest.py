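"""Shared fixtures: a hand-analysable toy transcript and a small trained model."""

import pytest

from tiscall.features import EfficiencyTable
from tiscall.model import TrainingConfig
from tiscall.synthetic import SimulationParams, end_to_end_fixture
from tiscall.transcripts import Transcript


def build_toy_transcript() -> Transcript:
    """A 323-nt transcript whose 5' UTR contains exactly one eligible candidate.

    The 203-nt UTR is a CCG repeat (which contains no AUG / near-cognate
    triplet in any frame) with a single C->U substitution at index 151 planting
    a CUG at index 150 (Kozak position -53).  The 120-nt CDS starts with AUG,
    carries a UAA in the candidate's frame at index 207, and ends with the main
    stop.  Hand-derived expectations: one candidate, CUG at -53, out of frame,
    ORF length 60 nt.
    """
    utr = ("CCG" * 68)[:203]
    utr = utr[:150] + "CUG" + utr[153:]
    cds = "AUG" + "GUAAGC" + "GCC" * 36 + "UAA"
    assert len(cds) == 120
    return Transcript("toy1", utr + cds, cds_start=204)


@pytest.fixture(scope="session")
def toy_transcript() -> Transcript:
    return build_toy_transcript()


@pytest.fixture(scope="session")
def small_pipeline():
    """A small but fully trained synthetic pipeline (no orthologs, 2 repeats)."""
    return end_to_end_fixture(
        SimulationParams(n_transcripts=25, seed=7),
        TrainingConfig(seed=7, n_repeats=2),
        use_orthologs=False,
    )


@pytest.fixture(scope="session")
def tiny_efficiency_table() -> EfficiencyTable:
    """Minimal efficiency table: every lookup falls back to the mean (50.0)."""
    return EfficiencyTable({"AAAAAAAUGAA": 40.0, "CCCCCCAUGCC": 60.0})
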