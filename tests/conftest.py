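import pytest

import phenolink as pl

# 5-term diamond: root R; A,B is_a R; C is_a A and B; D is_a C
DIAMOND_OBO = """\
[Term]
id: X:0000001
name: rootish

[Term]
id: X:0000002
name: alpha
is_a: X:0000001

[Term]
id: X:0000003
name: beta
is_a: X:0000001

[Term]
id: X:0000004
name: gamma
is_a: X:0000002
is_a: X:0000003

[Term]
id: X:0000005
name: delta
is_a: X:0000004
"""

R, A, B, C, D = (f"X:000000{i}" for i in range(1, 6))


@pytest.fixture
def diamond():
    return pl.parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def worked_fixture():
    """Default synthetic corpus: four leaf phenotypes sharing four genes."""
    return pl.generate_fixture(pl.FixtureParams(seed=11))


def assemble_kb(fixture):
    """Run the full in-memory pipeline on a generated fixture."""
    onto = pl.parse_obo(fixture.obo_text)
    gad = pl.read_association_table(fixture.gad_tsv, pl.Source.GAD)
    gwas = pl.read_association_table(fixture.gwasdb_tsv, pl.Source.GWASDB)
    matched = pl.map_labels(onto, gad)
    imported, report = pl.import_mapping(fixture.mapping_tsv, onto, gwas)
    kb = pl.build_knowledgebase(onto, [gad, gwas], [matched, imported])
    return kb, report


@pytest.fixture(scope="session")
def worked_kb(worked_fixture):
    kb, _ = assemble_kb(worked_fixture)
    return kb


FOUR_PHENOTYPES = ["HP:0100739", "HP:0100753", "HP:0000716", "HP:0000709"]
FOUR_GENES = {"COMT", "HTR2A", "SLC6A3", "SLC6A4"}
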