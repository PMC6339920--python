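import pytest

from funtax.function_db import (
    FunctionDB,
    FunctionalUnit,
    GenomeRecord,
    PathwayDefinition,
)
from funtax.inference import correct_abundance
from funtax.taxa_io import parse_taxa_table

FIXTURE_TAXA_TSV = (
    "lineage\tS1\tS2\n"
    "k__Bacteria; g__Taxona\t50\t50\n"
    "k__Bacteria; g__Taxonb\t50\t50\n"
)


@pytest.fixture
def fixture_db():
    """Two genomes, four EC units, two overlapping pathways.

    G1 (genus Taxona): 1 16S copy, e1 x2, e2 x1.
    G2 (genus Taxonb): 2 16S copies, e2 x2, e3 x2.
    P1 = {e1, e2}; P2 = {e2, e3, e4} (e4 encoded by nobody).
    """
    units = {u: FunctionalUnit(u, "EC", f"enzyme {u}") for u in ("e1", "e2", "e3", "e4")}
    genomes = [
        GenomeRecord("G1", {"domain": "Bacteria", "genus": "Taxona"}, 1, {"e1": 2, "e2": 1}),
        GenomeRecord("G2", {"domain": "Bacteria", "genus": "Taxonb"}, 2, {"e2": 2, "e3": 2}),
    ]
    pathways = [
        PathwayDefinition("P1", "pathway one", "Metabolism", "Amino Acid Metabolism",
                          "pathway one", ("e1", "e2")),
        PathwayDefinition("P2", "pathway two", "Metabolism", "Carbohydrate Metabolism",
                          "pathway two", ("e2", "e3", "e4")),
    ]
    return FunctionDB(genomes, units, pathways)


@pytest.fixture
def fixture_profile(tmp_path):
    """50/50 community of the two fixture genera (counts, Greengenes dialect)."""
    path = tmp_path / "taxa.tsv"
    path.write_text(FIXTURE_TAXA_TSV)
    return parse_taxa_table(path)


@pytest.fixture
def fixture_corrected(fixture_profile, fixture_db):
    corrected, _ = correct_abundance(fixture_profile, fixture_db)
    return corrected


TAXON_A = "k__Bacteria; g__Taxona"
TAXON_B = "k__Bacteria; g__Taxonb"
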