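"""Domain records and readers/writers for the tabular and FASTA formats the
pipeline exchanges.

The pipeline operates downstream of assembly and annotation: its inputs are
per-metagenome annotation tables (gene -> taxonomic lineage, gene -> KEGG
orthology term, contig length/read-depth summaries), sequence FASTA for viral
contigs and CRISPR spacers, and a sample metadata CSV.  All tabular output is
TSV with a single header line; missing numeric metadata is serialized as an
empty string.  Spacer/protospacer coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Taxonomic ranks in hierarchical order, domain first.
RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

#: Sampled depth codes, upper oxic zone -> interface -> lower anoxic zone.
DEPTH_CODES: tuple[str, ...] = ("U1", "U2", "U3", "I", "L1", "L2", "L3")

#: Sequential size-fractionation filters (pore size, micrometres).  Each
#: fraction of a water sample is a separate metagenome.
FILTER_FRACTIONS: tuple[float, ...] = (3.0, 0.8, 0.1)

#: Environmental metadata keys carried per sample.
ENV_KEYS: tuple[str, ...] = (
    "depth_m", "salinity_pct", "daylength_h", "sunlight_h", "air_temp_C",
)

_SEASON_BY_MONTH = {
    12: "summer", 1: "summer", 2: "summer",
    7: "winter", 8: "winter",
    10: "spring", 11: "spring",
}

#: Minimum contig length retained by the upstream annotation pipeline.
MIN_CONTIG_BP = 200

NUCLEOTIDES = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def season_of(date: _dt.date) -> str:
    """Map a sampling date to its austral season.

    December-February is summer, July-August winter, October-November
    spring.  The remaining months were never sampled and raise ``ValueError``
    so that a mislabeled date fails loudly instead of being silently grouped.
    """
    try:
        return _SEASON_BY_MONTH[date.month]
    except KeyError:
        raise ValueError(
            f"month {date.month} is outside the sampled seasons "
            "(Dec-Feb, Jul-Aug, Oct-Nov)"
        ) from None


def period_of(date: _dt.date) -> str:
    """Time-period label for a sampling date, e.g. ``'Dec. 2006'``."""
    return f"{date.strftime('%b')}. {date.year}"


@dataclass(frozen=True, order=True)
class TaxLineage:
    """A ranked taxonomy path (domain -> species).

    Assigned ranks form a contiguous prefix from the domain downward: a
    lineage naming a genus necessarily also names family, order, class,
    phylum, and domain.  An empty lineage is permitted and means "no
    assignment".
    """

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) > len(RANKS):
            raise ValueError(f"lineage deeper than {len(RANKS)} ranks: {self.labels}")
        for label in self.labels:
            if not label or not label.strip():
                raise ValueError(f"rank gap or blank label in lineage {self.labels}")

    @classmethod
    def parse(cls, text: str) -> "TaxLineage":
        """Parse a semicolon-delimited lineage string.

        Trailing empty fields are trimmed (a lineage assigned only to genus
        level is commonly written with a trailing run of semicolons); an
        empty field *inside* the path is a rank gap and is rejected.
        """
        parts = [p.strip() for p in text.split(";")]
        while parts and parts[-1] == "":
            parts.pop()
        if any(p == "" for p in parts):
            raise ValueError(f"rank gap in lineage string {text!r}")
        return cls(tuple(parts))

    @property
    def depth(self) -> int:
        return len(self.labels)

    @property
    def domain(self) -> str | None:
        return self.labels[0] if self.labels else None

    def lowest_rank(self) -> str:
        """Name of the deepest assigned rank; ``'unassigned'`` if empty."""
        if not self.labels:
            return "unassigned"
        return RANKS[len(self.labels) - 1]

    def lowest_label(self) -> str:
        if not self.labels:
            return "unassigned"
        return self.labels[-1]

    def prefix(self, depth: int) -> "TaxLineage":
        """Truncate to the first ``depth`` ranks."""
        return TaxLineage(self.labels[:depth])

    def label_at(self, depth: int) -> str | None:
        return self.labels[depth - 1] if self.depth >= depth else None

    def __str__(self) -> str:
        return ";".join(self.labels)


@dataclass(frozen=True)
class GeneRecord:
    """A predicted protein-coding gene on a contig.

    ``lineage is None`` means the gene carries no taxonomic assignment; such
    genes count toward the denominator of the 30% assignment-fraction rule
    but never vote.
    """

    gene_id: str
    contig_id: str
    lineage: TaxLineage | None = None
    ko_terms: frozenset[str] = frozenset()


@dataclass
class ContigRecord:
    """An assembled contig: the unit of all abundance arithmetic.

    ``coverage`` (length x read depth) is the weight every abundance sum
    uses.
    """

    contig_id: str
    sample_id: str
    length_bp: int
    read_depth: float
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp < MIN_CONTIG_BP:
            raise ValueError(
                f"contig {self.contig_id}: length {self.length_bp} below the "
                f"{MIN_CONTIG_BP} bp minimum retained by assembly upload"
            )
        if self.read_depth < 0:
            raise ValueError(f"contig {self.contig_id}: negative read depth")

    def coverage(self) -> float:
        return self.length_bp * self.read_depth


@dataclass(frozen=True)
class SampleMeta:
    """Identity and environmental context of one metagenome."""

    sample_id: str
    date: _dt.date
    depth_code: str
    filter_fraction_um: float
    env: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_code not in DEPTH_CODES:
            raise ValueError(f"unknown depth code {self.depth_code!r}")
        if self.filter_fraction_um not in FILTER_FRACTIONS:
            raise ValueError(f"unknown filter fraction {self.filter_fraction_um!r}")
        season_of(self.date)  # validates the month eagerly
        unknown = set(self.env) - set(ENV_KEYS)
        if unknown:
            raise ValueError(f"unknown environmental keys {sorted(unknown)}")

    @property
    def season(self) -> str:
        return season_of(self.date)

    @property
    def period(self) -> str:
        return period_of(self.date)


@dataclass
class MetagenomeSample:
    """A metagenome: its metadata plus all of its contigs."""

    meta: SampleMeta
    contigs: list[ContigRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig in self.contigs:
            if contig.sample_id != self.meta.sample_id:
                raise ValueError(
                    f"contig {contig.contig_id} belongs to {contig.sample_id}, "
                    f"not {self.meta.sample_id}"
                )
            if contig.contig_id in seen:
                raise ValueError(f"duplicate contig id {contig.contig_id}")
            seen.add(contig.contig_id)

    @property
    def sample_id(self) -> str:
        return self.meta.sample_id

    def total_coverage(self) -> float:
        return sum(c.coverage() for c in self.contigs)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gene_taxonomy(path: str | Path) -> dict[str, tuple[str, TaxLineage | None]]:
    """Read a gene-taxonomy TSV: gene_id, contig_id, percent identity,
    semicolon-delimited lineage.

    An empty lineage field yields ``None`` (no assignment); a lineage with an
    internal rank gap is a parse error naming the offending line.
    """
    out: dict[str, tuple[str, TaxLineage | None]] = {}
    with open(path, newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            gene_id, contig_id, _pid, lineage_text = fields
            if gene_id in out:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            if lineage_text.strip(" ;") == "":
                lineage: TaxLineage | None = None
            else:
                try:
                    lineage = TaxLineage.parse(lineage_text)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out[gene_id] = (contig_id, lineage)
    return out


def read_gene_ko(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a gene-KO TSV: gene_id, contig_id, KO identifier.

    Multiple KO terms per gene are accepted either as repeated rows or as a
    comma-delimited list in the third column; both spellings accumulate into
    one set per gene.
    """
    contig_of: dict[str, str] = {}
    terms: dict[str, set[str]] = {}
    with open(path, newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            gene_id, contig_id, ko_field = fields
            if gene_id in contig_of and contig_of[gene_id] != contig_id:
                raise ParseError(
                    f"{path}:{lineno}: gene {gene_id!r} listed on two contigs"
                )
            contig_of[gene_id] = contig_id
            kos = {k.strip() for k in ko_field.split(",") if k.strip()}
            if not kos:
                raise ParseError(f"{path}:{lineno}: empty KO field")
            terms.setdefault(gene_id, set()).update(kos)
    return {g: (contig_of[g], frozenset(terms[g])) for g in contig_of}


def read_contig_depths(path: str | Path) -> dict[str, tuple[int, float]]:
    """Read a contig depth-summary TSV (header line; contig_id, length,
    mean read depth)."""
    out: dict[str, tuple[int, float]] = {}
    with open(path, newline="") as handle:
        header = handle.readline()
        if not header.strip():
            raise ParseError(f"{path}: missing header line")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            contig_id, length_text, depth_text = fields
            if contig_id in out:
                raise ParseError(f"{path}:{lineno}: duplicate contig {contig_id!r}")
            try:
                length = int(length_text)
                depth = float(depth_text)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if length < MIN_CONTIG_BP:
                raise ParseError(
                    f"{path}:{lineno}: contig length {length} below "
                    f"{MIN_CONTIG_BP} bp"
                )
            if depth < 0:
                raise ParseError(f"{path}:{lineno}: negative read depth")
            out[contig_id] = (length, depth)
    return out


def read_contig_samples(path: str | Path) -> dict[str, str]:
    """Read the contig -> sample membership TSV (header; contig_id,
    sample_id)."""
    out: dict[str, str] = {}
    with open(path, newline="") as handle:
        handle.readline()
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            contig_id, sample_id = fields
            if contig_id in out:
                raise ParseError(f"{path}:{lineno}: duplicate contig {contig_id!r}")
            out[contig_id] = sample_id
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read nucleotide FASTA into an id -> sequence mapping.

    Ids must be unique and sequences restricted to A/C/G/T/N (case folded to
    upper).
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise ParseError(
                f"{path}: sequence {record.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        out[record.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata CSV.

    Columns: sample_id, date (ISO), depth_code, filter_fraction_um, then the
    optional environmental columns (blank = missing).  The combination
    (date, depth_code, filter_fraction_um) must be unique.
    """
    metas: list[SampleMeta] = []
    seen: set[tuple[str, str, float]] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            env = {
                key: float(row[key])
                for key in ENV_KEYS
                if row.get(key) not in (None, "")
            }
            meta = SampleMeta(
                sample_id=row["sample_id"],
                date=_dt.date.fromisoformat(row["date"]),
                depth_code=row["depth_code"],
                filter_fraction_um=float(row["filter_fraction_um"]),
                env=env,
            )
            key = (row["date"], meta.depth_code, meta.filter_fraction_um)
            if key in seen:
                raise ParseError(f"{path}: duplicate sample stratum {key}")
            seen.add(key)
            metas.append(meta)
    return metas


# ---------------------------------------------------------------------------
# Writers (and their round-trip partners)
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a DataFrame as TSV with a single header line.

    Missing values are serialized as empty strings so the file stays
    plain-text diffable.
    """
    frame.to_csv(path, sep="\t", index=index_label is not None,
                 index_label=index_label, na_rep="")


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> None:
    write_table(table, path, index_label="sample_id")


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, index_col="sample_id")


def write_sample_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["sample_id", "date", "depth_code", "filter_fraction_um", *ENV_KEYS])
        for meta in metas:
            writer.writerow([
                meta.sample_id,
                meta.date.isoformat(),
                meta.depth_code,
                meta.filter_fraction_um,
                *[meta.env.get(key, "") for key in ENV_KEYS],
            ])


def write_gene_taxonomy(samples: Iterable[MetagenomeSample], path: str | Path) -> None:
    """Write every gene's taxonomy row (gene_id, contig_id, percent identity
    placeholder, lineage)."""
    with open(path, "w", newline="") as handle:
        for sample in samples:
            for contig in sample.contigs:
                for gene in contig.genes:
                    lineage = "" if gene.lineage is None else str(gene.lineage)
                    handle.write(f"{gene.gene_id}\t{contig.contig_id}\t100.0\t{lineage}\n")


def write_gene_ko(samples: Iterable[MetagenomeSample], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        for sample in samples:
            for contig in sample.contigs:
                for gene in contig.genes:
                    for ko in sorted(gene.ko_terms):
                        handle.write(f"{gene.gene_id}\t{contig.contig_id}\t{ko}\n")


def write_contig_depths(samples: Iterable[MetagenomeSample], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        handle.write("contig_id\tlength_bp\tread_depth\n")
        for sample in samples:
            for contig in sample.contigs:
                handle.write(
                    f"{contig.contig_id}\t{contig.length_bp}\t{contig.read_depth:.6g}\n"
                )


def write_contig_samples(samples: Iterable[MetagenomeSample], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        handle.write("contig_id\tsample_id\n")
        for sample in samples:
            for contig in sample.contigs:
                handle.write(f"{contig.contig_id}\t{sample.sample_id}\n")


def assemble_samples(
    metas: Iterable[SampleMeta],
    depths: Mapping[str, tuple[int, float]],
    contig_samples: Mapping[str, str],
    gene_taxonomy: Mapping[str, tuple[str, TaxLineage | None]] | None = None,
    gene_ko: Mapping[str, tuple[str, frozenset[str]]] | None = None,
) -> list[MetagenomeSample]:
    """Reconstruct in-memory samples from the on-disk annotation tables."""
    gene_taxonomy = gene_taxonomy or {}
    gene_ko = gene_ko or {}
    genes_by_contig: dict[str, dict[str, GeneRecord]] = {}
    for gene_id, (contig_id, lineage) in gene_taxonomy.items():
        genes_by_contig.setdefault(contig_id, {})[gene_id] = GeneRecord(
            gene_id=gene_id, contig_id=contig_id, lineage=lineage)
    for gene_id, (contig_id, kos) in gene_ko.items():
        bucket = genes_by_contig.setdefault(contig_id, {})
        existing = bucket.get(gene_id)
        bucket[gene_id] = GeneRecord(
            gene_id=gene_id,
            contig_id=contig_id,
            lineage=existing.lineage if existing else None,
            ko_terms=kos,
        )
    contigs_by_sample: dict[str, list[ContigRecord]] = {}
    for contig_id, (length, depth) in depths.items():
        try:
            sample_id = contig_samples[contig_id]
        except KeyError:
            raise ParseError(f"contig {contig_id!r} has no sample membership") from None
        genes = sorted(genes_by_contig.get(contig_id, {}).values(),
                       key=lambda g: g.gene_id)
        contigs_by_sample.setdefault(sample_id, []).append(
            ContigRecord(contig_id, sample_id, length, depth, list(genes)))
    samples = []
    for meta in metas:
        contigs = contigs_by_sample.pop(meta.sample_id, [])
        contigs.sort(key=lambda c: c.contig_id)
        samples.append(MetagenomeSample(meta=meta, contigs=contigs))
    if contigs_by_sample:
        missing = sorted(contigs_by_sample)
        raise ParseError(f"contigs reference unknown samples: {missing[:5]}")
    return samples
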