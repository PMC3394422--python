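import random

import pytest

from phytomir.datamodel import MatureMiRNA, TargetSite
from phytomir.energy import energy_ratio
from phytomir.synth import design_site

#: 21 nt guide used across tests; typical plant mature-miRNA length.
MIRNA21 = "UGACCUAGGCAUCGAUGGCAA"


@pytest.fixture
def mirna21() -> MatureMiRNA:
    return MatureMiRNA(id="miR-test", seq=MIRNA21)


def make_site(
    mirna: MatureMiRNA,
    edits=(),
    start: int = 100,
    transcript_id: str = "TX1",
    engine=None,
    **overrides,
):
    """Ground-truth site for a designed duplex, energy ratio annotated."""
    _, duplex = design_site(mirna, edits)
    from phytomir.align import weighted_score

    fields = dict(
        mirna_id=mirna.id,
        transcript_id=transcript_id,
        start=start,
        end=start + duplex.target_span,
        duplex=duplex,
        engine=engine,
        score=weighted_score(duplex),
        energy_ratio=energy_ratio(duplex, mirna),
    )
    fields.update(overrides)
    return TargetSite(**fields)


def make_interval_site(
    start,
    end,
    mirna_id="miR-test",
    transcript_id="TX1",
    engine=None,
    score=0.0,
    **overrides,
):
    """Coordinate-only site (no duplex) for interval/filter tests."""
    return TargetSite(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=start,
        end=end,
        engine=engine,
        score=score,
        **overrides,
    )


def random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260926)
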