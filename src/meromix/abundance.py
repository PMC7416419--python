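"""Coverage-weighted OTU abundance accounting.

The relative abundance of an OTU in a metagenome is its contigs' summed
coverage (contig length x read depth) divided by the summed coverage of
*all* contigs in that metagenome, times 100.  Because the denominator spans
every contig -- abundant OTUs, the low-abundance remainder, and the
unassigned pool -- values are comparable across metagenomes and each row of
an abundance table sums to 100.

Filter fractions are separate metagenomes and are never merged.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .contig_taxonomy import OTUBin
from .io_formats import MetagenomeSample

UNASSIGNED = "unassigned"

#: Domain-level remainder columns for non-abundant OTUs.
OTHER_COLUMNS = ("Other Bacteria", "Other Archaea", "Other Eukarya", "Other Viruses")

_DOMAIN_TO_OTHER = {
    "Bacteria": "Other Bacteria",
    "Archaea": "Other Archaea",
    "Eukarya": "Other Eukarya",
    "Eukaryota": "Other Eukarya",
    "Viruses": "Other Viruses",
}


def other_column_for(domain: str) -> str:
    """Map an OTU's domain to its 'Other' remainder column."""
    try:
        return _DOMAIN_TO_OTHER[domain]
    except KeyError:
        raise ValueError(f"no 'Other' grouping for domain {domain!r}") from None


def relative_abundance(
    sample: MetagenomeSample, bins: Sequence[OTUBin]
) -> pd.Series:
    """One abundance-table row: percent relative abundance per OTU plus the
    unassigned remainder.

    Any contig of the sample not claimed by a bin falls into ``unassigned``,
    so the row always sums to 100.  A sample with zero total coverage has no
    defined composition and raises ``ValueError``.
    """
    total = sample.total_coverage()
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id} has zero total coverage")
    coverage = {c.contig_id: c.coverage() for c in sample.contigs}
    row: dict[str, float] = {}
    claimed = 0.0
    for otu in bins:
        cov = sum(coverage[cid] for cid in otu.contig_ids.get(sample.sample_id, ()))
        row[otu.otu_name] = cov / total * 100.0
        claimed += cov
    row[UNASSIGNED] = (total - claimed) / total * 100.0
    return pd.Series(row, name=sample.sample_id)


def abundance_table(
    samples: Iterable[MetagenomeSample], bins: Sequence[OTUBin]
) -> pd.DataFrame:
    """Samples x OTUs matrix of relative abundances (percent)."""
    rows = [relative_abundance(sample, bins) for sample in samples]
    table = pd.DataFrame(rows).fillna(0.0)
    table.index.name = "sample_id"
    return table


def peak_relative_abundance(
    table: pd.DataFrame,
    scope: Callable[[str], bool] | Sequence[str] | None = None,
) -> pd.Series:
    """Per-OTU maximum relative abundance over a scoped set of samples.

    ``scope`` may be ``None`` (all samples), a list of sample ids, or a
    predicate over sample ids (e.g. membership in a season, depth, or
    filter fraction).
    """
    if scope is None:
        sub = table
    elif callable(scope):
        sub = table.loc[[sid for sid in table.index if scope(sid)]]
    else:
        sub = table.loc[list(scope)]
    if sub.empty:
        raise ValueError("peak relative abundance over an empty sample scope")
    return sub.max(axis=0)


def total_abundance(
    bins: Sequence[OTUBin], samples: Iterable[MetagenomeSample]
) -> pd.Series:
    """Per-OTU summed coverage over all scoped samples (the Fig.-ordering
    weight)."""
    coverage: dict[str, float] = {}
    for sample in samples:
        for contig in sample.contigs:
            coverage[contig.contig_id] = contig.coverage()
    totals = {
        otu.otu_name: sum(coverage.get(cid, 0.0) for cid in otu.all_contig_ids())
        for otu in bins
    }
    return pd.Series(totals, dtype=float)


def select_abundant(
    table: pd.DataFrame,
    totals: pd.Series | None = None,
    threshold: float = 1.0,
) -> list[str]:
    """OTUs whose relative abundance reaches ``threshold`` percent
    (inclusive) in at least one metagenome.

    Ordered by descending total abundance when ``totals`` is given,
    otherwise by descending peak relative abundance.
    """
    otu_columns = [c for c in table.columns if c != UNASSIGNED and c not in OTHER_COLUMNS]
    peaks = table[otu_columns].max(axis=0)
    abundant = [otu for otu in otu_columns if peaks[otu] >= threshold]
    if totals is not None:
        abundant.sort(key=lambda otu: -float(totals.get(otu, 0.0)))
    else:
        abundant.sort(key=lambda otu: -float(peaks[otu]))
    return abundant


def group_other(
    table: pd.DataFrame,
    abundant: Sequence[str],
    domains: Mapping[str, str],
) -> pd.DataFrame:
    """Fold non-abundant OTU columns into domain-level 'Other' columns.

    ``domains`` maps OTU name -> domain label.  Row sums are preserved
    exactly; the unassigned column passes through untouched.
    """
    out = pd.DataFrame(index=table.index)
    for otu in abundant:
        out[otu] = table[otu]
    for column in OTHER_COLUMNS:
        out[column] = 0.0
    for column in table.columns:
        if column in abundant or column == UNASSIGNED:
            continue
        if column in OTHER_COLUMNS:
            out[column] += table[column]
            continue
        if column not in domains:
            raise ValueError(f"no domain known for OTU column {column!r}")
        target = other_column_for(domains[column])
        out[target] = out[target] + table[column]
    out[UNASSIGNED] = table[UNASSIGNED] if UNASSIGNED in table else 0.0
    out.index.name = table.index.name
    return out
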