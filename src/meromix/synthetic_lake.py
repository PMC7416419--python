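"""Synthetic stratified-lake metagenome generator.

The generator emits post-assembly annotation objects -- contigs with
lengths, read depths, and per-gene lineage/KO annotations -- for a sampling
design of several depths x three filter fractions x multiple dates, along
with a ground-truth table of each OTU's realized coverage share per
metagenome.  It emulates the statistical structure the downstream analysis
assumes:

* a dominant interface phototroph whose relative abundance collapses from
  ~80% in summer to a few percent in winter and ~1% in spring;
* depth-restricted anaerobes confined to the lower anoxic zone;
* an unassigned background of contigs whose genes carry no lineage;
* virion partitioning: viral contigs appear only in the 0.1 um filter
  fraction while their cellular hosts appear only in the 0.8/3.0 um
  fractions;
* virus clusters whose read-depth series is positively coupled to their
  host's abundance with a configurable target Pearson correlation, and
  whose genomes donate CRISPR spacers to the host.

Everything is deterministic given the scenario seed.  No read-level
simulation is performed: the generator's output is the annotation layer the
real pipeline would receive from an assembly + annotation service.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    DEPTH_CODES,
    ContigRecord,
    GeneRecord,
    MetagenomeSample,
    SampleMeta,
    TaxLineage,
    season_of,
)
from .viral_linkage import ViralCluster

SEASONS = ("summer", "winter", "spring")

#: Nominal depth (m) per depth code, surface to bottom of the water column.
DEPTH_M = {"U1": 0.0, "U2": 5.0, "U3": 12.0, "I": 13.5,
           "L1": 15.0, "L2": 18.5, "L3": 23.5}

#: Virus share multiplier is clipped to this band around its mean so that a
#: stratum's total target abundance stays bounded.
_VIRUS_BAND = (0.25, 1.75)
_VIRUS_AMPLITUDE = 0.3


@dataclass(frozen=True)
class OTUProfile:
    """Target behaviour of one cellular OTU across the design.

    ``season_response`` is the mean target relative abundance (percent) in
    each season, applied at every depth of ``depth_niche``;
    ``contig_length_dist`` holds log-normal parameters (mu, sigma) in
    log-bp; ``gene_density`` is genes per kbp; ``taxon_assignment_rate`` is
    the probability that a gene carries the OTU's lineage (the remainder
    emulates genes the annotation service could not place).
    """

    name: str
    lineage: TaxLineage
    depth_niche: tuple[str, ...]
    season_response: Mapping[str, float]
    contig_count_range: tuple[int, int] = (5, 10)
    contig_length_dist: tuple[float, float] = (8.0, 0.6)
    gene_density: float = 1.0
    taxon_assignment_rate: float = 1.0
    ko_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for depth in self.depth_niche:
            if depth not in DEPTH_CODES:
                raise ValueError(f"{self.name}: unknown depth code {depth!r}")
        for season, value in self.season_response.items():
            if season not in SEASONS:
                raise ValueError(f"{self.name}: unknown season {season!r}")
            if value < 0:
                raise ValueError(f"{self.name}: negative target abundance")
        if not 0.0 <= self.taxon_assignment_rate <= 1.0:
            raise ValueError(f"{self.name}: assignment rate outside [0, 1]")

    def target(self, season: str, depth_code: str) -> float:
        if depth_code not in self.depth_niche:
            return 0.0
        return float(self.season_response.get(season, 0.0))


@dataclass(frozen=True)
class VirusProfile:
    """A virus (cluster seed) coupled to a host OTU.

    ``coupling`` is the target Pearson correlation between the virus
    read-depth series and the host's abundance series across paired
    sampling strata; ``spacer_donor`` marks the host's CRISPR array as
    carrying substrings of this genome; ``virion_partitioned`` restricts
    the virus's contigs to the 0.1 um fraction.
    """

    name: str
    host_otu: str
    coupling: float
    genome_length_bp: int = 30_000
    spacer_donor: bool = False
    virion_partitioned: bool = True
    mean_share: float = 4.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError(f"{self.name}: coupling outside [-1, 1]")
        if self.genome_length_bp < 200:
            raise ValueError(f"{self.name}: genome shorter than a contig")

    @property
    def lineage(self) -> TaxLineage:
        return TaxLineage(("Viruses", self.name))


@dataclass(frozen=True)
class LakeScenario:
    """Full parameterization of one synthetic sampling campaign."""

    otu_profiles: tuple[OTUProfile, ...]
    virus_profiles: tuple[VirusProfile, ...] = ()
    dates: tuple[_dt.date, ...] = ()
    depths: tuple[str, ...] = DEPTH_CODES
    filter_fractions: tuple[float, ...] = (3.0, 0.8, 0.1)
    noise_sigma: float = 0.1
    seed: int = 0
    total_coverage: float = 1e6
    winter_lower_gap: bool = True  # no lower-zone sampling in Jul/Aug
    background_length_dist: tuple[float, float] = (8.0, 0.8)
    #: housekeeping KO terms carried (p = 0.5 per gene) by background
    #: contigs: taxonomically unassignable sequence still gets functional
    #: annotation, so every metagenome has KO-bearing contigs.
    background_ko_terms: tuple[str, ...] = ("K01990", "K02014", "K03088")

    def __post_init__(self) -> None:
        names = [p.name for p in self.otu_profiles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate OTU profile names")
        hosts = set(names)
        for virus in self.virus_profiles:
            if virus.host_otu not in hosts:
                raise ValueError(f"virus {virus.name}: unknown host {virus.host_otu}")
        self.validate_targets()

    def validate_targets(self) -> None:
        """Target abundances must leave room for the unassigned background
        at every (season, depth) stratum."""
        for season in SEASONS:
            for depth in self.depths:
                total = sum(p.target(season, depth) for p in self.otu_profiles)
                if total > 100.0:
                    raise ValueError(
                        f"cellular targets sum to {total}% at ({season}, {depth})"
                    )
        virus_max = sum(v.mean_share * _VIRUS_BAND[1] for v in self.virus_profiles)
        if virus_max > 100.0:
            raise ValueError(f"virus targets can reach {virus_max}% in the 0.1 um fraction")

    def sampled_strata(self) -> list[tuple[_dt.date, str, float]]:
        strata = []
        for date in self.dates:
            for depth in self.depths:
                if (
                    self.winter_lower_gap
                    and season_of(date) == "winter"
                    and depth.startswith("L")
                ):
                    continue  # the anoxic zone is not sampled in winter
                for fraction in self.filter_fractions:
                    strata.append((date, depth, fraction))
        return strata


@dataclass
class SimulationResult:
    """Samples plus the ground truth the pipeline should recover."""

    samples: list[MetagenomeSample]
    truth: pd.DataFrame                    # sample x OTU realized coverage share (%)
    virus_genomes: dict[str, str]          # virus name -> genome sequence
    virus_contigs: dict[str, list[str]]    # virus name -> emitted contig ids
    virus_sequences: dict[str, str]        # contig id -> sequence

    def virus_clusters(self) -> list[ViralCluster]:
        return [
            ViralCluster(cluster_id=name, member_ids=list(ids))
            for name, ids in self.virus_contigs.items()
            if ids
        ]


# ---------------------------------------------------------------------------
# Environmental model
# ---------------------------------------------------------------------------

def salinity_pct(depth_m: float) -> float:
    """Halocline-shaped salinity profile: brackish mixolimnion, sharp rise
    at the interface, ~4.2% at the bottom."""
    return 0.9 + 3.3 / (1.0 + math.exp(-(depth_m - 13.0) / 1.2))


def daylength_h(date: _dt.date) -> float:
    """Smooth polar photoperiod: 24 h around the December solstice, 0 h in
    midwinter."""
    doy = date.timetuple().tm_yday
    raw = 12.0 + 13.5 * math.cos(2.0 * math.pi * (doy - 355) / 365.25)
    return min(24.0, max(0.0, raw))


def sunlight_h(date: _dt.date) -> float:
    """Bright-sunshine hours: daylength discounted by a seasonally varying
    cloudiness factor (so the two variables are correlated but not
    collinear)."""
    doy = date.timetuple().tm_yday
    clear = 0.55 - 0.12 * math.cos(2.0 * math.pi * (doy - 30) / 365.25)
    return daylength_h(date) * clear


def air_temp_C(date: _dt.date) -> float:
    doy = date.timetuple().tm_yday
    return -9.0 + 10.0 * math.cos(2.0 * math.pi * (doy - 15) / 365.25)


def environment_for(depth_code: str, date: _dt.date) -> dict[str, float]:
    depth = DEPTH_M[depth_code]
    return {
        "depth_m": depth,
        "salinity_pct": round(salinity_pct(depth), 4),
        "daylength_h": round(daylength_h(date), 4),
        "sunlight_h": round(sunlight_h(date), 4),
        "air_temp_C": round(air_temp_C(date), 4),
    }


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _sample_id(date: _dt.date, depth: str, fraction: float) -> str:
    return f"{date.isoformat()}_{depth}_{fraction:g}um"


def _virus_share_series(
    scenario: LakeScenario, rng: np.random.Generator
) -> dict[tuple[str, _dt.date, str], float]:
    """Per-virus target share for every (virus, date, depth) stratum.

    The series is built as coupling * standardized-host-share plus
    independent noise, mapped affinely around ``mean_share`` and clipped to
    a bounded band, so its Pearson correlation with the host series
    approaches the configured coupling.
    """
    shares: dict[tuple[str, _dt.date, str], float] = {}
    by_name = {p.name: p for p in scenario.otu_profiles}
    for virus in scenario.virus_profiles:
        host = by_name[virus.host_otu]
        strata = [
            (date, depth)
            for date in scenario.dates
            for depth in scenario.depths
            if depth in host.depth_niche
            and not (
                scenario.winter_lower_gap
                and season_of(date) == "winter"
                and depth.startswith("L")
            )
        ]
        host_series = np.array(
            [host.target(season_of(date), depth) for date, depth in strata]
        )
        sd = host_series.std()
        zh = (host_series - host_series.mean()) / sd if sd > 0 else np.zeros_like(host_series)
        noise = rng.standard_normal(len(strata))
        c = virus.coupling
        z = c * zh + math.sqrt(max(0.0, 1.0 - c * c)) * noise
        multiplier = np.clip(1.0 + _VIRUS_AMPLITUDE * z, *_VIRUS_BAND)
        for (date, depth), m in zip(strata, multiplier):
            shares[(virus.name, date, depth)] = virus.mean_share * float(m)
    return shares


def _random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _emit_otu_contigs(
    profile: OTUProfile,
    share: float,
    sample_id: str,
    scenario: LakeScenario,
    rng: np.random.Generator,
    contigs: list[ContigRecord],
) -> float:
    """Append one OTU's contigs; returns the realized coverage."""
    lo, hi = profile.contig_count_range
    n = int(rng.integers(lo, hi + 1))
    mu, sigma = profile.contig_length_dist
    lengths = np.maximum(
        200, np.exp(rng.normal(mu, sigma, size=n)).astype(int)
    )
    target_cov = share / 100.0 * scenario.total_coverage
    base_depth = target_cov / float(lengths.sum())
    if scenario.noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, scenario.noise_sigma, size=n))
    else:
        noise = np.ones(n)
    realized = 0.0
    for idx in range(n):
        contig_id = f"{sample_id}|{profile.name.replace(' ', '_')}|c{idx}"
        depth = float(base_depth * noise[idx])
        length = int(lengths[idx])
        n_genes = max(1, int(round(length / 1000.0 * profile.gene_density)))
        genes = []
        for g in range(n_genes):
            has_lineage = rng.random() < profile.taxon_assignment_rate
            ko: frozenset[str] = frozenset()
            if profile.ko_terms:
                ko = frozenset({profile.ko_terms[int(rng.integers(len(profile.ko_terms)))]})
            genes.append(GeneRecord(
                gene_id=f"{contig_id}_g{g}",
                contig_id=contig_id,
                lineage=profile.lineage if has_lineage else None,
                ko_terms=ko,
            ))
        contigs.append(ContigRecord(contig_id, sample_id, length, depth, genes))
        realized += length * depth
    return realized


def simulate(scenario: LakeScenario) -> SimulationResult:
    """Generate the full sample collection plus ground truth.

    Per metagenome, each OTU's contig coverages are scaled so its coverage
    share equals its target abundance, then perturbed by multiplicative
    log-normal noise on read depth only; the ground-truth table records the
    *realized* (post-noise) shares, so a noise-free run recovers the targets
    exactly and any run can be checked against its own truth.
    """
    seed_seq = np.random.SeedSequence(scenario.seed)
    rng = np.random.default_rng(seed_seq)

    virus_genomes = {
        v.name: _random_genome(v.genome_length_bp, rng)
        for v in scenario.virus_profiles
    }
    virus_share = _virus_share_series(scenario, rng)

    samples: list[MetagenomeSample] = []
    truth_rows: dict[str, dict[str, float]] = {}
    virus_contigs: dict[str, list[str]] = {v.name: [] for v in scenario.virus_profiles}
    virus_sequences: dict[str, str] = {}

    for date, depth, fraction in scenario.sampled_strata():
        season = season_of(date)
        sid = _sample_id(date, depth, fraction)
        contigs: list[ContigRecord] = []
        realized: dict[str, float] = {}

        cellular_fraction = fraction in (3.0, 0.8)
        for profile in scenario.otu_profiles:
            share = profile.target(season, depth) if cellular_fraction else 0.0
            if share <= 0:
                continue
            realized[profile.name] = _emit_otu_contigs(
                profile, share, sid, scenario, rng, contigs)

        for virus in scenario.virus_profiles:
            in_fraction = (fraction == 0.1) if virus.virion_partitioned else True
            share = virus_share.get((virus.name, date, depth), 0.0)
            if not in_fraction or share <= 0:
                continue
            genome = virus_genomes[virus.name]
            contig_id = f"{sid}|{virus.name.replace(' ', '_')}|c0"
            target_cov = share / 100.0 * scenario.total_coverage
            depth_noise = (
                float(np.exp(rng.normal(0.0, scenario.noise_sigma)))
                if scenario.noise_sigma > 0 else 1.0
            )
            read_depth = target_cov / len(genome) * depth_noise
            n_genes = max(1, int(round(len(genome) / 1000.0)))
            genes = [
                GeneRecord(
                    gene_id=f"{contig_id}_g{g}",
                    contig_id=contig_id,
                    lineage=virus.lineage,
                )
                for g in range(n_genes)
            ]
            contigs.append(ContigRecord(contig_id, sid, len(genome), read_depth, genes))
            virus_contigs[virus.name].append(contig_id)
            virus_sequences[contig_id] = genome
            realized[virus.name] = len(genome) * read_depth

        # Unassigned background takes up the remaining target share, emitted
        # as contigs whose genes carry no lineage.
        cellular_total = sum(
            (p.target(season, depth) if cellular_fraction else 0.0)
            for p in scenario.otu_profiles
        )
        virus_total = 0.0
        for v in scenario.virus_profiles:
            in_frac = (fraction == 0.1) if v.virion_partitioned else True
            if in_frac:
                virus_total += virus_share.get((v.name, date, depth), 0.0)
        target_background = 100.0 - cellular_total - virus_total
        if target_background < 0:
            raise ValueError(f"targets exceed 100% in sample {sid}")
        if target_background > 0:
            mu, sigma = scenario.background_length_dist
            n = max(3, int(target_background / 5.0))
            lengths = np.maximum(200, np.exp(rng.normal(mu, sigma, size=n)).astype(int))
            target_cov = target_background / 100.0 * scenario.total_coverage
            base_depth = target_cov / float(lengths.sum())
            noise = (
                np.exp(rng.normal(0.0, scenario.noise_sigma, size=n))
                if scenario.noise_sigma > 0 else np.ones(n)
            )
            background_cov = 0.0
            for idx in range(n):
                contig_id = f"{sid}|background|c{idx}"
                length = int(lengths[idx])
                depth_value = float(base_depth * noise[idx])
                ko: frozenset[str] = frozenset()
                if scenario.background_ko_terms and rng.random() < 0.5:
                    ko = frozenset({scenario.background_ko_terms[
                        int(rng.integers(len(scenario.background_ko_terms)))]})
                genes = [GeneRecord(f"{contig_id}_g0", contig_id, None, ko)]
                contigs.append(ContigRecord(contig_id, sid, length, depth_value, genes))
                background_cov += length * depth_value
            realized["unassigned"] = background_cov

        meta = SampleMeta(
            sample_id=sid,
            date=date,
            depth_code=depth,
            filter_fraction_um=fraction,
            env=environment_for(depth, date),
        )
        sample = MetagenomeSample(meta=meta, contigs=contigs)
        total = sample.total_coverage()
        truth_rows[sid] = {name: cov / total * 100.0 for name, cov in realized.items()}
        samples.append(sample)

    truth = pd.DataFrame.from_dict(truth_rows, orient="index").fillna(0.0)
    truth.index.name = "sample_id"
    return SimulationResult(
        samples=samples,
        truth=truth,
        virus_genomes=virus_genomes,
        virus_contigs=virus_contigs,
        virus_sequences=virus_sequences,
    )


# ---------------------------------------------------------------------------
# CRISPR spacer planting
# ---------------------------------------------------------------------------

def plant_spacers(
    result: SimulationResult,
    virus_profiles: Sequence[VirusProfile],
    mutation_rate: float = 0.0,
    spacer_length: int = 32,
    spacers_per_virus: int = 20,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Draw CRISPR spacers as mutated substrings of donor virus genomes.

    Each spacer is a uniformly placed ``spacer_length``-bp substring of its
    source genome with independent per-base substitutions at
    ``mutation_rate``.  Returns the spacer sequences and a truth table
    (spacer_id, source virus, host taxon, realized identity %).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1]))
    host_of = {v.name: v.host_otu for v in virus_profiles}
    spacers: dict[str, str] = {}
    rows = []
    bases = "ACGT"
    for virus in virus_profiles:
        if not virus.spacer_donor:
            continue
        genome = result.virus_genomes[virus.name]
        if spacer_length > len(genome):
            raise ValueError(
                f"spacer length {spacer_length} exceeds genome of {virus.name}"
            )
        for idx in range(spacers_per_virus):
            start = int(rng.integers(0, len(genome) - spacer_length + 1))
            seq = list(genome[start: start + spacer_length])
            mutations = 0
            if mutation_rate > 0:
                for pos in range(spacer_length):
                    if rng.random() < mutation_rate:
                        current = seq[pos]
                        seq[pos] = bases[
                            (bases.index(current) + 1 + int(rng.integers(3))) % 4
                        ]
                        mutations += 1
            spacer_id = f"spacer|{virus.name.replace(' ', '_')}|{idx}"
            spacers[spacer_id] = "".join(seq)
            rows.append({
                "spacer_id": spacer_id,
                "source_virus": virus.name,
                "host_taxon": host_of[virus.name],
                "genome_start": start,
                "identity_pct": (spacer_length - mutations) / spacer_length * 100.0,
            })
    truth = pd.DataFrame(rows)
    return spacers, truth


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------

def _lineage(*labels: str) -> TaxLineage:
    return TaxLineage(tuple(labels))


def default_dates(n: int = 8, start_year: int = 2013) -> tuple[_dt.date, ...]:
    """A full seasonal cycle: summer, winter, spring, and the return to
    summer, sampled mid-month."""
    months = [(0, 12), (1, 1), (1, 2), (1, 7), (1, 8), (1, 10), (1, 11), (1, 12),
              (2, 1), (2, 2), (2, 7), (2, 8), (2, 10), (2, 11), (2, 12), (3, 1)]
    return tuple(
        _dt.date(start_year + dy, month, 15) for dy, month in months[:n]
    )


def default_scenario(
    seed: int = 0,
    noise_sigma: float = 0.1,
    taxon_assignment_rate: float = 0.8,
    dates: tuple[_dt.date, ...] | None = None,
) -> LakeScenario:
    """The canonical stratified-lake community.

    ~20 cellular OTUs: a dominant interface green sulfur bacterium
    (summer ~80% -> winter ~6% -> spring ~1%), a photic-zone cyanobacterium
    with a spring bloom, a summer picoeukaryote, aerobic heterotrophs in the
    mixolimnion, winter-responsive polysaccharide degraders, and
    depth-restricted anaerobes (sulfate reducers, fermenters, a methanogen)
    in the monimolimnion; plus four viruses, two of them CRISPR-spacer
    donors coupled to the interface phototroph.
    """
    rate = taxon_assignment_rate
    profiles = (
        OTUProfile(
            "Chlorobium",
            _lineage("Bacteria", "Chlorobi", "Chlorobia", "Chlorobiales",
                     "Chlorobiaceae", "Chlorobium"),
            depth_niche=("I",),
            season_response={"summer": 80.0, "winter": 6.0, "spring": 1.0},
            contig_count_range=(8, 14),
            taxon_assignment_rate=rate,
            ko_terms=("K00855", "K01007", "K17222"),  # rTCA / sulfide oxidation
        ),
        OTUProfile(
            "Synechococcus",
            _lineage("Bacteria", "Cyanobacteria", "Cyanophyceae",
                     "Synechococcales", "Synechococcaceae", "Synechococcus"),
            depth_niche=("U2", "U3"),
            season_response={"summer": 40.0, "winter": 10.0, "spring": 50.0},
            contig_count_range=(8, 14),
            taxon_assignment_rate=rate,
            ko_terms=("K01601", "K01602", "K02703"),  # RubisCO / PSII
        ),
        OTUProfile(
            "Micromonas",
            _lineage("Eukaryota", "Chlorophyta", "Mamiellophyceae",
                     "Mamiellales", "Mamiellaceae", "Micromonas"),
            depth_niche=("U1", "U2"),
            season_response={"summer": 10.0, "winter": 0.0, "spring": 8.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Pelagibacter",
            _lineage("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                     "Pelagibacterales", "Pelagibacteraceae", "Pelagibacter"),
            depth_niche=("U1", "U2", "U3"),
            season_response={"summer": 10.0, "winter": 12.0, "spring": 8.0},
            taxon_assignment_rate=rate,
            ko_terms=("K00958",),  # sulfite detox (aprAB-like)
        ),
        OTUProfile(
            "Loktanella",
            _lineage("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                     "Rhodobacterales", "Roseobacteraceae", "Loktanella"),
            depth_niche=("U1", "U2"),
            season_response={"summer": 5.0, "winter": 6.0, "spring": 5.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Flavobacteriaceae MAG-120531",
            _lineage("Bacteria", "Bacteroidetes", "Flavobacteriia",
                     "Flavobacteriales", "Flavobacteriaceae", "MAG-120531"),
            depth_niche=("U1", "U2", "U3"),
            season_response={"summer": 6.0, "winter": 8.0, "spring": 6.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Verrucomicrobiaceae SW10",
            _lineage("Bacteria", "Verrucomicrobia", "Verrucomicrobiae",
                     "Verrucomicrobiales", "Verrucomicrobiaceae", "SW10"),
            depth_niche=("U2", "U3"),
            season_response={"summer": 2.0, "winter": 8.0, "spring": 4.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Verrucomicrobiaceae BACL24",
            _lineage("Bacteria", "Verrucomicrobia", "Verrucomicrobiae",
                     "Verrucomicrobiales", "Verrucomicrobiaceae", "BACL24"),
            depth_niche=("U3", "I"),
            season_response={"summer": 1.5, "winter": 6.0, "spring": 3.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Porticoccaceae HTCC2207",
            _lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "Cellvibrionales", "Porticoccaceae", "HTCC2207"),
            depth_niche=("U1", "U2", "U3"),
            season_response={"summer": 4.0, "winter": 5.0, "spring": 4.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Halioglobus",
            _lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "Cellvibrionales", "Halieaceae", "Halioglobus"),
            depth_niche=("U2", "U3"),
            season_response={"summer": 3.0, "winter": 3.0, "spring": 4.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Yoonia",
            _lineage("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                     "Rhodobacterales", "Roseobacteraceae", "Yoonia"),
            depth_niche=("U1",),
            season_response={"summer": 3.0, "winter": 2.0, "spring": 4.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Methylophilaceae BACL14",
            _lineage("Bacteria", "Proteobacteria", "Betaproteobacteria",
                     "Methylophilales", "Methylophilaceae", "BACL14"),
            depth_niche=("U1", "U2"),
            season_response={"summer": 2.0, "winter": 2.0, "spring": 3.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Desulfobacterium",
            _lineage("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                     "Desulfobacterales", "Desulfobacteraceae", "Desulfobacterium"),
            depth_niche=("I", "L1", "L2", "L3"),
            season_response={"summer": 8.0, "winter": 6.0, "spring": 7.0},
            taxon_assignment_rate=rate,
            ko_terms=("K11180", "K11181"),  # dissimilatory sulfite reductase
        ),
        OTUProfile(
            "Desulfocapsa",
            _lineage("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                     "Desulfobulbales", "Desulfocapsaceae", "Desulfocapsa"),
            depth_niche=("L1", "L2"),
            season_response={"summer": 6.0, "winter": 5.0, "spring": 5.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Desulfatiglandaceae NaphS2",
            _lineage("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                     "Desulfatiglanales", "Desulfatiglandaceae", "NaphS2"),
            depth_niche=("L2", "L3"),
            season_response={"summer": 5.0, "winter": 6.0, "spring": 5.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Cloacimonadaceae JGIOTU-2",
            _lineage("Bacteria", "Cloacimonetes", "Cloacimonadia",
                     "Cloacimonadales", "Cloacimonadaceae", "JGIOTU-2"),
            depth_niche=("L2", "L3"),
            season_response={"summer": 6.0, "winter": 6.0, "spring": 6.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Atribacteraceae 34-128",
            _lineage("Bacteria", "Atribacteria", "Atribacteria_class",
                     "Atribacterales", "Atribacteraceae", "34-128"),
            depth_niche=("L3",),
            season_response={"summer": 6.0, "winter": 6.0, "spring": 6.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Methanothrix_A",
            _lineage("Archaea", "Euryarchaeota", "Methanomicrobia",
                     "Methanotrichales", "Methanotrichaceae", "Methanothrix_A"),
            depth_niche=("L3",),
            season_response={"summer": 4.0, "winter": 4.0, "spring": 4.0},
            taxon_assignment_rate=rate,
            ko_terms=("K00399",),  # methyl-CoM reductase
        ),
        OTUProfile(
            "Syntrophaceae UBA2210",
            _lineage("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                     "Syntrophales", "Syntrophaceae", "UBA2210"),
            depth_niche=("L1", "L2"),
            season_response={"summer": 3.0, "winter": 4.0, "spring": 3.0},
            taxon_assignment_rate=rate,
        ),
        OTUProfile(
            "Bacteroidaceae UBA4459",
            _lineage("Bacteria", "Bacteroidetes", "Bacteroidia",
                     "Bacteroidales", "Bacteroidaceae", "UBA4459"),
            depth_niche=("L1", "L2", "L3"),
            season_response={"summer": 4.0, "winter": 4.0, "spring": 4.0},
            taxon_assignment_rate=rate,
        ),
    )
    viruses = (
        VirusProfile("GSB phage A", host_otu="Chlorobium", coupling=0.7,
                     genome_length_bp=24_000, spacer_donor=True, mean_share=4.0),
        VirusProfile("GSB phage B", host_otu="Chlorobium", coupling=0.9,
                     genome_length_bp=18_000, spacer_donor=True, mean_share=3.0),
        VirusProfile("Cyanophage A", host_otu="Synechococcus", coupling=0.0,
                     genome_length_bp=30_000, spacer_donor=False, mean_share=5.0),
        VirusProfile("Phycodnavirus A", host_otu="Micromonas", coupling=0.3,
                     genome_length_bp=20_000, spacer_donor=False, mean_share=2.0),
    )
    return LakeScenario(
        otu_profiles=profiles,
        virus_profiles=viruses,
        dates=dates if dates is not None else default_dates(8),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def noise_free_scenario(seed: int = 0) -> LakeScenario:
    """The default design with noiseless depths and complete gene
    annotation: the pipeline must recover the ground truth exactly."""
    scenario = default_scenario(seed=seed, noise_sigma=0.0, taxon_assignment_rate=1.0)
    return scenario


def correlation_scenario(
    seed: int = 0, n_dates: int = 40, coupling: float = 0.9
) -> LakeScenario:
    """A long interface time series for host-virus correlation estimation:
    one dominant phototroph at the interface, one coupled virus, paired
    cellular (3.0 um) and virion (0.1 um) metagenomes per date."""
    host = OTUProfile(
        "Chlorobium",
        _lineage("Bacteria", "Chlorobi", "Chlorobia", "Chlorobiales",
                 "Chlorobiaceae", "Chlorobium"),
        depth_niche=("I",),
        season_response={"summer": 70.0, "winter": 6.0, "spring": 1.5},
    )
    virus = VirusProfile(
        "GSB phage B", host_otu="Chlorobium", coupling=coupling,
        genome_length_bp=15_000, spacer_donor=True, mean_share=4.0,
    )
    months = [12, 1, 2, 7, 8, 10, 11]
    dates = []
    year = 2006
    i = 0
    while len(dates) < n_dates:
        dates.append(_dt.date(year + i // len(months), months[i % len(months)], 15))
        i += 1
    return LakeScenario(
        otu_profiles=(host,),
        virus_profiles=(virus,),
        dates=tuple(dates),
        depths=("I",),
        filter_fractions=(3.0, 0.1),
        noise_sigma=0.05,
        seed=seed,
    )


def gradient_community(
    n_samples: int = 30,
    n_taxa: int = 8,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A community whose composition is a deterministic function of a single
    environmental gradient, for ordination recovery checks.

    Taxa respond to the gradient with Gaussian niches whose optima are
    spread along it; rows are closed to 100%.  Returns (abundance table,
    environment table with the gradient plus an independent noise
    variable).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9D]))
    gradient = np.linspace(0.0, 1.0, n_samples)
    optima = np.linspace(0.0, 1.0, n_taxa)
    width = 0.22
    response = np.exp(-((gradient[:, None] - optima[None, :]) ** 2) / (2 * width ** 2))
    if noise_sigma > 0:
        response = response * np.exp(rng.normal(0.0, noise_sigma, size=response.shape))
    table = response / response.sum(axis=1, keepdims=True) * 100.0
    index = [f"s{i:03d}" for i in range(n_samples)]
    abundance = pd.DataFrame(
        table, index=index, columns=[f"taxon_{j}" for j in range(n_taxa)]
    )
    abundance.index.name = "sample_id"
    env = pd.DataFrame(
        {
            "gradient": gradient,
            "noise_var": rng.standard_normal(n_samples),
        },
        index=index,
    )
    env.index.name = "sample_id"
    return abundance, env
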