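import pytest

from metaqtl import (
    ConsensusMap,
    MarkerLocus,
    QtlRecord,
    load_fixture_tables,
    parse_map_file,
)

MAP_TEXT = """\
chromosome\tmarker\tdistance_from_previous_cM
# three-chromosome toy consensus map
c1\tM1\t0
c1\tM2\t10
c1\tM3\t10
c1\tM4\t20
c1\tM5\t40
c2\tN1\t0
c2\tN2\t5.2
c2\tN3\t3.1
c5\tP1\t0
c5\tP2\t60
c5\tP3\t60
"""


@pytest.fixture
def toy_map() -> ConsensusMap:
    """c1 spans 80 cM (markers at 0,10,20,40,80), c2 8.3 cM, c5 120 cM."""
    return parse_map_file(MAP_TEXT)


def make_record(
    qtl_name="q1",
    chromosome="c1",
    trait="Micro",
    position=None,
    ci_lo=None,
    ci_hi=None,
    study_id="s1",
    **kw,
) -> QtlRecord:
    return QtlRecord(
        map_name="toy",
        qtl_name=qtl_name,
        study_id=study_id,
        chromosome=chromosome,
        trait=trait,
        position=position,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        **kw,
    )


def placed_records(chromosome, positions, traits, ci_half=2.0, study="s1"):
    """Fully resolved records at given positions, cycling over traits."""
    out = []
    for i, pos in enumerate(positions):
        trait = traits[i % len(traits)]
        out.append(
            make_record(
                qtl_name=f"q{i:03d}",
                chromosome=chromosome,
                trait=trait,
                position=float(pos),
                ci_lo=max(0.0, pos - ci_half),
                ci_hi=pos + ci_half,
                study_id=study,
            )
        )
    return out


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()
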