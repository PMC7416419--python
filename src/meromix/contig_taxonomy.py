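"""Contig taxonomy assignment by gene-lineage voting, and OTU binning.

A contig inherits a taxonomy from the lineages of its predicted genes:

(a) at least 30% (inclusive) of the genes on the contig must carry a
    taxonomic assignment, otherwise the contig is unassigned;
(b) the winning taxon is the one held by the most genes, voted at the
    deepest rank at which at least two assigned genes agree; a tie at a rank
    escalates the vote one rank higher (species -> genus -> ... -> domain);
(c) if no rank produces a unique winner -- in particular when every
    assigned gene carries a distinct lineage -- the contig is unassigned.

A single assigned gene on a qualifying contig is unopposed and wins at its
own lowest rank.  Contigs with zero genes are unassigned.  Contigs sharing a
winning (taxon, rank) are then binned as OTUs at that lowest available rank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import RANKS, ContigRecord, TaxLineage

#: Rule (a): minimum fraction of genes with any taxonomic assignment.
MIN_ASSIGNED_FRACTION = 0.30

#: Functional analyses drop contigs with two or fewer open reading frames.
MIN_GENES_FOR_FUNCTION = 3


@dataclass(frozen=True)
class ContigAssignment:
    """Outcome of the vote for one contig.

    ``lineage is None`` iff ``assigned_rank == 'unassigned'``.
    ``vote_fraction`` is the winning taxon's share of the contig's assigned
    genes (1.0 for an unopposed single gene; 0.0 when unassigned).
    """

    contig_id: str
    sample_id: str
    lineage: TaxLineage | None
    assigned_rank: str
    vote_fraction: float
    n_genes: int

    def __post_init__(self) -> None:
        if (self.lineage is None) != (self.assigned_rank == "unassigned"):
            raise ValueError("lineage must be absent exactly when rank is 'unassigned'")


def _unassigned(contig: ContigRecord) -> ContigAssignment:
    return ContigAssignment(
        contig_id=contig.contig_id,
        sample_id=contig.sample_id,
        lineage=None,
        assigned_rank="unassigned",
        vote_fraction=0.0,
        n_genes=len(contig.genes),
    )


def assign_contig_taxonomy(contig: ContigRecord) -> ContigAssignment:
    """Vote a taxonomy for one contig from its genes' lineages.

    Total function: every contig yields either a lineage truncated at the
    winning rank or the unassigned verdict.
    """
    genes = contig.genes
    n_total = len(genes)
    assigned = [g.lineage for g in genes if g.lineage is not None and g.lineage.depth > 0]
    if n_total == 0 or not assigned:
        return _unassigned(contig)
    if len(assigned) / n_total < MIN_ASSIGNED_FRACTION:
        return _unassigned(contig)

    if len(assigned) == 1:
        # Unopposed single gene: wins at its own lowest rank.
        lineage = assigned[0]
        return ContigAssignment(
            contig_id=contig.contig_id,
            sample_id=contig.sample_id,
            lineage=lineage,
            assigned_rank=lineage.lowest_rank(),
            vote_fraction=1.0,
            n_genes=n_total,
        )

    # Vote deepest-first.  A rank produces a winner when a unique taxon
    # (identified by its full path down to that rank) is carried by >= 2
    # genes and strictly more genes than any rival at that rank.
    for depth in range(len(RANKS), 0, -1):
        counts = Counter(
            lin.prefix(depth) for lin in assigned if lin.depth >= depth
        )
        if not counts:
            continue
        top = max(counts.values())
        if top < 2:
            continue
        winners = [path for path, count in counts.items() if count == top]
        if len(winners) == 1:
            winner = winners[0]
            return ContigAssignment(
                contig_id=contig.contig_id,
                sample_id=contig.sample_id,
                lineage=winner,
                assigned_rank=RANKS[depth - 1],
                vote_fraction=top / len(assigned),
                n_genes=n_total,
            )
        # tie at this rank: re-vote one rank higher
    return _unassigned(contig)


@dataclass
class OTUBin:
    """A bin of contigs sharing a voted taxonomy at its lowest rank."""

    otu_name: str
    rank: str
    lineage: TaxLineage
    contig_ids: dict[str, list[str]] = field(default_factory=dict)  # sample -> contigs
    functional_contig_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def domain(self) -> str:
        return self.lineage.domain or "unassigned"

    def all_contig_ids(self) -> list[str]:
        return [cid for ids in self.contig_ids.values() for cid in ids]


def _otu_name(lineage: TaxLineage, taken: set[str]) -> str:
    """Human-facing OTU name: the lowest-rank label, with higher-rank context
    prepended for alphanumeric placeholder names (e.g. ``'Verrucomicrobia
    SW10'``) and for label collisions across lineages."""
    label = lineage.lowest_label()
    needs_context = (
        lineage.depth >= 2
        and (any(ch.isdigit() for ch in label) or label in taken)
    )
    if needs_context:
        label = f"{lineage.labels[-2]} {label}"
    base = label
    suffix = 2
    while label in taken:
        label = f"{base} ({suffix})"
        suffix += 1
    return label


def bin_otus(
    assignments: list[ContigAssignment],
    min_genes_for_function: int = MIN_GENES_FOR_FUNCTION,
) -> tuple[list[OTUBin], dict[str, list[str]]]:
    """Group assigned contigs into OTU bins at their lowest voted rank.

    Returns the bins plus the unassigned pool (sample -> contig ids).  Each
    bin also tracks its functional-contig subset, dropping contigs with
    fewer than ``min_genes_for_function`` genes (by default, contigs with
    <= 2 open reading frames are excluded from functional analyses).
    """
    by_key: dict[tuple[TaxLineage, str], list[ContigAssignment]] = {}
    unassigned: dict[str, list[str]] = {}
    for assignment in assignments:
        if assignment.lineage is None:
            unassigned.setdefault(assignment.sample_id, []).append(assignment.contig_id)
            continue
        key = (assignment.lineage, assignment.assigned_rank)
        by_key.setdefault(key, []).append(assignment)

    bins: list[OTUBin] = []
    taken: set[str] = set()
    for (lineage, rank), members in sorted(
        by_key.items(), key=lambda item: item[0][0]
    ):
        name = _otu_name(lineage, taken)
        taken.add(name)
        otu = OTUBin(otu_name=name, rank=rank, lineage=lineage)
        for assignment in members:
            otu.contig_ids.setdefault(assignment.sample_id, []).append(
                assignment.contig_id)
            if assignment.n_genes >= min_genes_for_function:
                otu.functional_contig_ids.setdefault(assignment.sample_id, []).append(
                    assignment.contig_id)
        bins.append(otu)
    return bins, unassigned
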