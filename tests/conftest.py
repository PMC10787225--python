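import pytest

from hairpinscan import FilterConfig, PropensityProfile, ProteinRecord


@pytest.fixture
def config():
    return FilterConfig()


def as_candidate_coords(candidates):
    """Project candidates to (n_start, n_end, c_start, c_end) tuples."""
    return [
        (c.n_strand.start, c.n_strand.end, c.c_strand.start, c.c_strand.end)
        for c in candidates
    ]


@pytest.fixture
def make_pair():
    """Build an aligned (record, profile) pair from a sequence and scores."""

    def _make(sequence, scores, protein_id="TEST1"):
        return (
            ProteinRecord(id=protein_id, sequence=sequence),
            PropensityProfile(protein_id=protein_id, scores=tuple(scores)),
        )

    return _make
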