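"""Viral cluster abundance, CRISPR spacer -> protospacer matching, cluster
expansion by sequence similarity, and putative host assignment.

Viral contigs arrive pre-grouped into clusters (>= 2 members) or singletons.
Cluster abundance over a time period is the summed read depth of member
contigs across all metagenomes of that period; a cluster is *abundant* when
its total strictly exceeds a threshold (default 4000) in at least one
period.

Spacer matching is a short-query nucleotide search: exact k-mer seeds
(default k = 12) on both strands are extended ungapped to the full spacer,
and a hit is kept when identity and alignment fraction clear their cut-offs
(defaults 97% each).  For 20-60 bp spacers these two gates dominate any
e-value criterion, which is database-size dependent and deliberately not
modelled.  Coordinates are 0-based half-open on the target contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from scipy import stats

from .io_formats import MetagenomeSample, period_of

#: Default abundance threshold on per-period total read depth (strict >).
ABUNDANCE_THRESHOLD = 4000.0

#: Spacer-match defaults: megablast-like identity gate and near-full-length
#: alignment requirement.
SPACER_MIN_IDENTITY = 97.0
SPACER_MIN_FRACTION = 0.97
SEED_K = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ViralCluster:
    """A group of similar viral contigs (>= 2 members) or a singleton."""

    cluster_id: str
    member_ids: list[str]
    kind: str = ""  # derived when blank

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"cluster {self.cluster_id} has no members")
        derived = "singleton" if len(self.member_ids) == 1 else "cluster"
        if not self.kind:
            self.kind = derived
        elif self.kind != derived:
            raise ValueError(
                f"cluster {self.cluster_id}: kind {self.kind!r} inconsistent "
                f"with {len(self.member_ids)} member(s)"
            )


@dataclass(frozen=True)
class SpacerHit:
    """A spacer -> protospacer match on a target contig.

    ``start``/``end`` are 0-based half-open on the target's forward strand;
    ``strand`` is '+' when the spacer matches the forward strand.
    """

    spacer_id: str
    target_contig: str
    identity_pct: float
    alignment_fraction: float
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct out of [0, 100]")
        if not 0.0 < self.alignment_fraction <= 1.0:
            raise ValueError("alignment_fraction out of (0, 1]")


def cluster_period_abundance(
    clusters: Sequence[ViralCluster],
    samples: Iterable[MetagenomeSample],
    period_fn: Callable | None = None,
    threshold: float = ABUNDANCE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum member-contig read depths per (cluster, time period).

    Returns the clusters x periods table of total read depth and a boolean
    per-cluster 'abundant' flag: total strictly above ``threshold`` in at
    least one period.  All metagenomes of a period (every depth and filter
    fraction) are pooled.
    """
    period_fn = period_fn or (lambda meta: period_of(meta.date))
    depth_by_contig: dict[str, dict[str, float]] = {}
    periods: list[str] = []
    for sample in samples:
        label = period_fn(sample.meta)
        if label not in periods:
            periods.append(label)
        for contig in sample.contigs:
            depth_by_contig.setdefault(contig.contig_id, {})
            depth_by_contig[contig.contig_id][label] = (
                depth_by_contig[contig.contig_id].get(label, 0.0) + contig.read_depth
            )
    table = pd.DataFrame(0.0, index=[c.cluster_id for c in clusters], columns=periods)
    for cluster in clusters:
        for member in cluster.member_ids:
            for label, depth in depth_by_contig.get(member, {}).items():
                table.loc[cluster.cluster_id, label] += depth
    abundant = (table > threshold).any(axis=1)
    abundant.name = "abundant"
    table.index.name = "cluster_id"
    return table, abundant


def _ungapped_hits(
    spacer_id: str, spacer: str, contig_id: str, contig: str,
    min_identity: float, min_fraction: float, k: int, strand: str,
) -> list[SpacerHit]:
    """Seed-and-extend scan of one spacer orientation against one contig."""
    hits = []
    offsets: set[int] = set()
    for i in range(len(spacer) - k + 1):
        seed = spacer[i: i + k]
        pos = contig.find(seed)
        while pos != -1:
            offsets.add(pos - i)
            pos = contig.find(seed, pos + 1)
    for offset in sorted(offsets):
        lo = max(0, offset)
        hi = min(len(contig), offset + len(spacer))
        aligned = hi - lo
        if aligned <= 0:
            continue
        matches = sum(
            1 for j in range(lo, hi) if contig[j] == spacer[j - offset]
        )
        identity = matches / aligned * 100.0
        fraction = aligned / len(spacer)
        if identity >= min_identity and fraction >= min_fraction:
            hits.append(SpacerHit(
                spacer_id=spacer_id, target_contig=contig_id,
                identity_pct=identity, alignment_fraction=fraction,
                start=lo, end=hi, strand=strand,
            ))
    return hits


def match_spacers(
    spacers: Mapping[str, str],
    contigs: Mapping[str, str],
    min_identity: float = SPACER_MIN_IDENTITY,
    min_fraction: float = SPACER_MIN_FRACTION,
    seed_k: int = SEED_K,
) -> list[SpacerHit]:
    """Align CRISPR spacers against contigs, both strands, ungapped.

    Hits are reported wherever an exact ``seed_k``-mer anchors an ungapped
    placement whose identity (matches / aligned length) and alignment
    fraction (aligned length / spacer length) clear the thresholds.
    Coordinates always refer to the contig's forward strand.
    """
    hits: list[SpacerHit] = []
    for spacer_id, spacer in spacers.items():
        if len(spacer) < seed_k:
            raise ValueError(
                f"spacer {spacer_id!r} shorter than the {seed_k}-mer seed"
            )
        rc = reverse_complement(spacer)
        for contig_id, contig in contigs.items():
            found = _ungapped_hits(
                spacer_id, spacer, contig_id, contig,
                min_identity, min_fraction, seed_k, "+",
            )
            found += _ungapped_hits(
                spacer_id, rc, contig_id, contig,
                min_identity, min_fraction, seed_k, "-",
            )
            hits.extend(found)
    return hits


# Cluster expansion uses a gapped local alignment (simple scheme: match +2,
# mismatch -1, gaps -1.5 per position) with identity computed over aligned
# columns, approximating a blastn-style search at desk scale.
_EXPAND_GAP = -1.5


def _expand_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = _EXPAND_GAP
    aligner.extend_gap_score = _EXPAND_GAP
    return aligner


def _alignment_identity_fraction(query: str, target: str) -> tuple[float, float]:
    """Best local alignment of query vs target: (identity % over aligned
    columns, aligned query length / query length)."""
    aligner = _expand_aligner()
    if aligner.score(query, target) <= 0:
        return 0.0, 0.0
    best = aligner.align(query, target)[0]
    matches = 0
    columns = 0
    q_aligned = 0
    for (qs, qe), (ts, te) in zip(*best.aligned):
        block = qe - qs
        columns += block
        q_aligned += block
        matches += sum(1 for i in range(block) if query[qs + i] == target[ts + i])
    if columns == 0:
        return 0.0, 0.0
    return matches / columns * 100.0, q_aligned / len(query)


def expand_cluster(
    cluster: ViralCluster,
    member_seqs: Mapping[str, str],
    candidates: Mapping[str, str],
    min_identity: float = 90.0,
    min_fraction: float = 0.98,
) -> ViralCluster:
    """Add candidate contigs whose best alignment to any member clears both
    the identity and alignment-fraction thresholds.

    Idempotent on a fixed candidate set: expanding an expanded cluster with
    the same inputs adds nothing new.
    """
    members = list(cluster.member_ids)
    member_set = set(members)
    for contig_id in sorted(candidates):
        if contig_id in member_set:
            continue
        seq = candidates[contig_id]
        for member in cluster.member_ids:
            ref = member_seqs.get(member)
            if ref is None:
                continue
            identity, fraction = _alignment_identity_fraction(seq, ref)
            if identity >= min_identity and fraction >= min_fraction:
                members.append(contig_id)
                member_set.add(contig_id)
                break
    return ViralCluster(cluster_id=cluster.cluster_id, member_ids=members)


def assign_hosts(
    hits: Iterable[SpacerHit],
    spacer_origin: Mapping[str, str],
    clusters: Sequence[ViralCluster],
) -> dict[str, set[str]]:
    """Candidate hosts per cluster: the taxa whose CRISPR arrays contributed
    spacers hitting any member contig.

    Multiple hosts are reported unranked; a cluster with no spacer hits maps
    to an empty set.
    """
    cluster_of: dict[str, str] = {}
    for cluster in clusters:
        for member in cluster.member_ids:
            cluster_of[member] = cluster.cluster_id
    hosts: dict[str, set[str]] = {c.cluster_id: set() for c in clusters}
    for hit in hits:
        cluster_id = cluster_of.get(hit.target_contig)
        if cluster_id is None:
            continue
        taxon = spacer_origin.get(hit.spacer_id)
        if taxon is not None:
            hosts[cluster_id].add(taxon)
    return hosts


def host_virus_correlation(
    host_series: Sequence[float], virus_series: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between a host marker read-depth series and a
    viral cluster depth series, with the two-sided p from the t
    distribution on n - 2 degrees of freedom."""
    if len(host_series) != len(virus_series):
        raise ValueError("host and virus series differ in length")
    if len(host_series) < 3:
        raise ValueError("need at least 3 paired observations")
    if _is_constant(host_series) or _is_constant(virus_series):
        raise ValueError("correlation undefined for a constant series")
    r, p = stats.pearsonr(host_series, virus_series)
    return float(r), float(p)


def _is_constant(series: Sequence[float]) -> bool:
    first = series[0]
    return all(math.isclose(x, first, rel_tol=0.0, abs_tol=0.0) for x in series)
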