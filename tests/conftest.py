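import datetime as dt

import pytest

from meromix.io_formats import ContigRecord, GeneRecord, TaxLineage
from meromix.synthetic_lake import (
    correlation_scenario,
    default_scenario,
    noise_free_scenario,
    simulate,
)

# Three lineages sharing structure at several ranks: two congeneric-family
# green sulfur bacteria and one cyanobacterium.  Used by voting tests and
# the exhaustive voter oracle.
LINEAGE_A = TaxLineage((
    "Bacteria", "Chlorobi", "Chlorobia", "Chlorobiales",
    "Chlorobiaceae", "Chlorobium",
))
LINEAGE_B = TaxLineage((
    "Bacteria", "Chlorobi", "Chlorobia", "Chlorobiales",
    "Chlorobiaceae", "Prosthecochloris",
))
LINEAGE_C = TaxLineage((
    "Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales",
    "Synechococcaceae", "Synechococcus",
))


def make_contig(lineages, contig_id="c1", sample_id="s1", length=1000, depth=10.0):
    """Contig with one gene per entry; None entries are unannotated genes."""
    genes = [
        GeneRecord(
            gene_id=f"{contig_id}_g{i}",
            contig_id=contig_id,
            lineage=lineage,
        )
        for i, lineage in enumerate(lineages)
    ]
    return ContigRecord(contig_id, sample_id, length, depth, genes)


@pytest.fixture(scope="session")
def noise_free_result():
    return simulate(noise_free_scenario(seed=11))


@pytest.fixture(scope="session")
def noisy_result():
    return simulate(default_scenario(seed=7))


@pytest.fixture(scope="session")
def default_scenario_fixture():
    return default_scenario(seed=7)


@pytest.fixture(scope="session")
def correlation_result():
    return simulate(correlation_scenario(seed=3, n_dates=40, coupling=0.9))


@pytest.fixture()
def a_date():
    return dt.date(2014, 12, 15)
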