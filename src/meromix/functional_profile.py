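"""KEGG-based functional potential: per-metagenome KO abundances, pathway
aggregation with cross-sample normalization, and role disambiguation of
redox/homologous enzymes by local protein alignment.

The abundance of a KO term in a metagenome is the summed read depth of the
*contigs* carrying at least one gene annotated with that term (a contig
counts once per KO regardless of how many of its genes share the
annotation).  Pathway abundances are normalized so that metagenomes of
different sequencing effort are comparable:

    [ sum_{KO in pathway} abundance_KO / ReadDepth_cont ]
        x [ sum over all metagenomes of ReadDepth_cont / N ]

where ``ReadDepth_cont`` is the per-metagenome summed read depth of
KO-bearing contigs and ``N`` the number of metagenomes in the dataset.  With
N = 1 the two factors cancel and the normalized value equals the raw one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .io_formats import MetagenomeSample


@dataclass(frozen=True)
class PathwayDef:
    """A pathway or enzyme: the KO terms that constitute it and how their
    abundances aggregate (``sum`` by default, ``mean`` where a pathway is
    better summarized by its average step)."""

    name: str
    ko_terms: tuple[str, ...]
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"aggregation must be 'sum' or 'mean', got {self.aggregation!r}")
        if not self.ko_terms:
            raise ValueError(f"pathway {self.name!r} has no KO terms")


@dataclass
class KeggProfile:
    """Per-dataset KO abundance state: samples x KO abundances and the
    per-sample summed read depth of KO-bearing contigs."""

    ko_table: pd.DataFrame  # rows: sample_id, columns: KO, values >= 0
    read_depth_cont: pd.Series  # per-sample sum of read depths of KO contigs

    @property
    def n_samples(self) -> int:
        return len(self.ko_table.index)


def ko_abundance(
    sample: MetagenomeSample,
    ko_annotations: Mapping[str, tuple[str, frozenset[str]]] | None = None,
) -> dict[str, float]:
    """Per-KO abundance for one metagenome.

    ``ko_annotations`` maps gene_id -> (contig_id, KO set); when omitted the
    KO terms already attached to the sample's gene records are used.  A KO
    annotation naming a contig absent from the sample is an error.
    """
    depth_of = {c.contig_id: c.read_depth for c in sample.contigs}
    contigs_per_ko: dict[str, set[str]] = {}
    if ko_annotations is None:
        for contig in sample.contigs:
            for gene in contig.genes:
                for ko in gene.ko_terms:
                    contigs_per_ko.setdefault(ko, set()).add(contig.contig_id)
    else:
        for gene_id, (contig_id, kos) in ko_annotations.items():
            if contig_id not in depth_of:
                raise ValueError(
                    f"KO annotation for gene {gene_id!r} references contig "
                    f"{contig_id!r} absent from sample {sample.sample_id}"
                )
            for ko in kos:
                contigs_per_ko.setdefault(ko, set()).add(contig_id)
    # summation in sorted contig order keeps results bit-reproducible
    return {
        ko: sum(depth_of[cid] for cid in sorted(contigs))
        for ko, contigs in contigs_per_ko.items()
    }


def kegg_profile(samples: Iterable[MetagenomeSample]) -> KeggProfile:
    """Build the dataset-wide KO profile from annotated samples."""
    rows: dict[str, dict[str, float]] = {}
    rdc: dict[str, float] = {}
    for sample in samples:
        abundances = ko_abundance(sample)
        rows[sample.sample_id] = abundances
        ko_contigs = {
            contig.contig_id
            for contig in sample.contigs
            if any(gene.ko_terms for gene in contig.genes)
        }
        depth_of = {c.contig_id: c.read_depth for c in sample.contigs}
        rdc[sample.sample_id] = sum(depth_of[cid] for cid in sorted(ko_contigs))
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table.sort_index(axis=1)
    table.index.name = "sample_id"
    return KeggProfile(ko_table=table, read_depth_cont=pd.Series(rdc))


def normalized_pathway_abundance(
    profile: KeggProfile, pathways: Sequence[PathwayDef]
) -> pd.DataFrame:
    """Samples x pathways matrix of normalized abundances.

    A sample whose KO-bearing contigs have zero summed read depth cannot be
    normalized and raises ``ValueError``.
    """
    rdc = profile.read_depth_cont
    zero = rdc.index[rdc <= 0].tolist()
    if zero:
        raise ValueError(f"samples with zero KO-contig read depth: {zero}")
    mean_rdc = float(rdc.mean())  # the dataset-wide normalization factor
    out = pd.DataFrame(index=profile.ko_table.index)
    for pathway in pathways:
        present = [ko for ko in pathway.ko_terms if ko in profile.ko_table.columns]
        if present:
            block = profile.ko_table[present]
            if pathway.aggregation == "sum":
                raw = block.sum(axis=1)
            else:
                # mean over the pathway's full KO list: missing terms are zero
                raw = block.sum(axis=1) / len(pathway.ko_terms)
        else:
            raw = pd.Series(0.0, index=profile.ko_table.index)
        out[pathway.name] = raw / rdc.loc[out.index] * mean_rdc
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Role disambiguation by parameterized local alignment
# ---------------------------------------------------------------------------

#: Local alignment parameters for role assignment: match +2, mismatch -1,
#: gap open -0.5 (charged on the first gapped position), gap extend -0.1.
ALIGN_MATCH = 2.0
ALIGN_MISMATCH = -1.0
ALIGN_GAP_OPEN = -0.5
ALIGN_GAP_EXTEND = -0.1


def _role_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_gap_score = ALIGN_GAP_OPEN
    aligner.extend_gap_score = ALIGN_GAP_EXTEND
    return aligner


def local_alignment_score(a: str, b: str) -> float:
    """Smith-Waterman-style local alignment score under the role-assignment
    scoring scheme (score only; an empty alignment scores 0)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return float(_role_aligner().score(a, b))


@dataclass
class RoleLibrary:
    """Labelled reference protein sequences for functionally ambiguous
    enzyme families (e.g. oxidative vs. reductive homologs)."""

    references: dict[str, list[str]] = field(default_factory=dict)  # role -> seqs

    @classmethod
    def from_fasta(cls, path: str) -> "RoleLibrary":
        """Load a role library from FASTA; the role is the first word of the
        description line after the sequence id."""
        refs: dict[str, list[str]] = {}
        for record in SeqIO.parse(path, "fasta"):
            words = record.description.split()
            if len(words) < 2:
                raise ValueError(
                    f"reference {record.id!r} carries no role in its description"
                )
            refs.setdefault(words[1], []).append(str(record.seq))
        return cls(refs)


@dataclass(frozen=True)
class RoleAssignment:
    role: str
    score: float
    tie: bool  # another role achieved the same best score


def assign_role(query_protein: str, library: RoleLibrary) -> RoleAssignment:
    """Assign the role of the best-scoring reference to a query protein.

    Ties across roles resolve to the lexicographically first role and are
    flagged so downstream analyses can treat them as ambiguous.
    """
    if not library.references:
        raise ValueError("empty role library")
    best_per_role: dict[str, float] = {}
    for role, sequences in library.references.items():
        if not sequences:
            continue
        best_per_role[role] = max(
            local_alignment_score(query_protein, ref) for ref in sequences
        )
    if not best_per_role:
        raise ValueError("role library contains no sequences")
    best = max(best_per_role.values())
    winners = sorted(role for role, score in best_per_role.items() if score == best)
    return RoleAssignment(role=winners[0], score=best, tie=len(winners) > 1)
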