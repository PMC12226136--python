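import numpy as np
import pytest

from cleavemap.model import PeptideObservation, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_protein():
    # K/R and D/E placed so both working proteases have internal sites.
    return ProteinRecord("TOY1", "MKTAYRAAKAAPELWSDEGHMNKLVR")


def make_obs(
    protein: ProteinRecord,
    start: int,
    end: int,
    protease: str = "trypsin",
    abundance_E: float | None = 1000.0,
    abundance_EQ: float | None = 1000.0,
    modifications=None,
) -> PeptideObservation:
    """Observation consistent with a protein by construction."""
    return PeptideObservation(
        protein_id=protein.id,
        sequence=protein.subsequence(start, end),
        start=start,
        end=end,
        prev_aa="-" if start == 1 else protein.residue(start - 1),
        next_aa="-" if end == len(protein) else protein.residue(end + 1),
        working_protease=protease,
        modifications=modifications or [],
        abundance_E=abundance_E,
        abundance_EQ=abundance_EQ,
    )


@pytest.fixture
def obs_factory():
    return make_obs
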