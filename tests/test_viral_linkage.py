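"""Cluster abundance thresholds, spacer matching (with a brute-force
all-offsets Hamming oracle), cluster expansion, host assignment, and the
host-virus correlation."""

import datetime as dt

import numpy as np
import pytest

from meromix import viral_linkage as vl
from meromix.io_formats import ContigRecord, MetagenomeSample, SampleMeta
from meromix.synthetic_lake import plant_spacers


def depth_sample(sample_id, date, contig_depths, depth_code="I", fraction=0.1):
    contigs = [
        ContigRecord(cid, sample_id, 1000, depth)
        for cid, depth in contig_depths.items()
    ]
    meta = SampleMeta(sample_id, date, depth_code, fraction)
    return MetagenomeSample(meta=meta, contigs=contigs)


class TestClusterPeriodAbundance:
    def test_sum_above_threshold_is_abundant(self):
        cluster = vl.ViralCluster("CL1", ["v1", "v2"])
        sample = depth_sample("s1", dt.date(2006, 12, 10), {"v1": 3000.0, "v2": 1500.0})
        table, abundant = vl.cluster_period_abundance([cluster], [sample])
        assert table.loc["CL1", "Dec. 2006"] == pytest.approx(4500.0)
        assert bool(abundant["CL1"])

    def test_exactly_threshold_not_abundant(self):
        cluster = vl.ViralCluster("CL1", ["v1"])
        sample = depth_sample("s1", dt.date(2006, 12, 10), {"v1": 4000.0})
        _, abundant = vl.cluster_period_abundance([cluster], [sample])
        assert not bool(abundant["CL1"])

    def test_absent_period_is_zero(self):
        cluster = vl.ViralCluster("CL1", ["v1"])
        s1 = depth_sample("s1", dt.date(2006, 12, 10), {"v1": 100.0})
        s2 = depth_sample("s2", dt.date(2008, 11, 10), {"other": 5.0})
        table, _ = vl.cluster_period_abundance([cluster], [s1, s2])
        assert table.loc["CL1", "Nov. 2008"] == 0.0

    def test_pools_all_samples_in_period(self):
        cluster = vl.ViralCluster("CL1", ["v1"])
        s1 = depth_sample("s1", dt.date(2014, 7, 1), {"v1": 2500.0}, "U2")
        s2 = depth_sample("s2", dt.date(2014, 7, 20), {"v1": 2000.0}, "U3")
        table, abundant = vl.cluster_period_abundance([cluster], [s1, s2])
        assert table.loc["CL1", "Jul. 2014"] == pytest.approx(4500.0)
        assert bool(abundant["CL1"])


def hamming_oracle(spacer, contig, min_identity, min_fraction):
    """All-offsets ungapped scan, both strands, no seeding requirement."""
    found = set()
    for strand, query in (("+", spacer), ("-", vl.reverse_complement(spacer))):
        for offset in range(-len(query) + 1, len(contig)):
            lo, hi = max(0, offset), min(len(contig), offset + len(query))
            aligned = hi - lo
            if aligned <= 0:
                continue
            matches = sum(
                1 for j in range(lo, hi) if contig[j] == query[j - offset]
            )
            identity = matches / aligned * 100.0
            if identity >= min_identity and aligned / len(query) >= min_fraction:
                found.add((strand, lo, hi))
    return found


class TestMatchSpacers:
    def test_exact_containment_hit(self):
        contig = "T" * 50 + "ACGTACGTACGTACGTACGTACGTACGTACGT" + "G" * 50
        spacer = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        hits = vl.match_spacers({"sp1": spacer}, {"c1": contig})
        assert any(
            h.identity_pct == 100.0 and h.alignment_fraction == 1.0
            and (h.start, h.end) == (50, 82)
            for h in hits
        )

    def test_two_mismatches_below_cutoff(self):
        rng = np.random.default_rng(0)
        spacer = "".join(rng.choice(list("ACGT"), size=32))
        mutated = list(spacer)
        mutated[5] = "A" if mutated[5] != "A" else "C"
        mutated[20] = "A" if mutated[20] != "A" else "C"
        contig = "T" * 30 + "".join(mutated) + "G" * 30
        hits = vl.match_spacers({"sp1": spacer}, {"c1": contig})
        # 30/32 = 93.75% identity < 97%
        assert hits == []

    def test_agrees_with_hamming_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(15):
            contig = "".join(rng.choice(list("ACGT"), size=400))
            start = int(rng.integers(0, 368))
            spacer = list(contig[start: start + 32])
            n_mut = int(rng.integers(0, 3))
            for pos in rng.choice(32, size=n_mut, replace=False):
                spacer[pos] = "ACGT"[("ACGT".index(spacer[pos]) + 1) % 4]
            spacer = "".join(spacer)
            hits = vl.match_spacers({"sp": spacer}, {"c": contig})
            got = {(h.strand, h.start, h.end) for h in hits}
            expected = hamming_oracle(spacer, contig, 97.0, 0.97)
            # the seeded scan may only miss oracle hits lacking a 12-mer
            # exact seed; with <= 2 mutations in 32 bp a seed always exists
            assert got == expected, trial

    def test_strand_symmetry(self):
        rng = np.random.default_rng(6)
        contig = "".join(rng.choice(list("ACGT"), size=300))
        spacer = contig[100:132]
        fwd = vl.match_spacers({"sp": spacer}, {"c": contig})
        rev = vl.match_spacers({"sp": spacer}, {"c": vl.reverse_complement(contig)})
        assert len(fwd) == len(rev)
        n = len(contig)
        remapped = {(n - h.end, n - h.start) for h in rev}
        assert {(h.start, h.end) for h in fwd} == remapped

    def test_lowering_identity_never_removes_hits(self):
        rng = np.random.default_rng(7)
        contig = "".join(rng.choice(list("ACGT"), size=500))
        spacer = list(contig[200:232])
        spacer[3] = "ACGT"[("ACGT".index(spacer[3]) + 1) % 4]
        spacer = "".join(spacer)
        strict = vl.match_spacers({"sp": spacer}, {"c": contig}, min_identity=97.0)
        loose = vl.match_spacers({"sp": spacer}, {"c": contig}, min_identity=90.0)
        strict_keys = {(h.strand, h.start, h.end) for h in strict}
        loose_keys = {(h.strand, h.start, h.end) for h in loose}
        assert strict_keys <= loose_keys
        assert len(loose) >= len(strict)

    def test_short_spacer_errors(self):
        with pytest.raises(ValueError, match="seed"):
            vl.match_spacers({"sp": "ACGTACGT"}, {"c": "ACGT" * 30})


class TestExpandCluster:
    def _base(self):
        rng = np.random.default_rng(9)
        return "".join(rng.choice(list("ACGT"), size=400))

    def test_identical_contig_added(self):
        base = self._base()
        cluster = vl.ViralCluster("CL1", ["m1"])
        expanded = vl.expand_cluster(
            cluster, {"m1": base}, {"twin": base}, min_identity=98.0)
        assert "twin" in expanded.member_ids

    def test_below_identity_not_added(self):
        base = self._base()
        rng = np.random.default_rng(10)
        mutated = list(base)
        for pos in rng.choice(len(base), size=20, replace=False):  # 95% identity
            mutated[pos] = "ACGT"[("ACGT".index(mutated[pos]) + 1) % 4]
        expanded = vl.expand_cluster(
            vl.ViralCluster("CL1", ["m1"]), {"m1": base},
            {"cand": "".join(mutated)}, min_identity=98.0)
        assert "cand" not in expanded.member_ids

    def test_idempotent(self):
        base = self._base()
        candidates = {"twin": base, "unrelated": self._base()[::-1]}
        cluster = vl.ViralCluster("CL1", ["m1"])
        once = vl.expand_cluster(cluster, {"m1": base}, candidates, min_identity=98.0)
        twice = vl.expand_cluster(
            once, {"m1": base, "twin": base}, candidates, min_identity=98.0)
        assert once.member_ids == twice.member_ids


class TestAssignHosts:
    def test_two_taxa_reported_unranked(self):
        clusters = [vl.ViralCluster("CL1", ["v1", "v2"])]
        hits = [
            vl.SpacerHit("spA", "v1", 100.0, 1.0, 0, 32, "+"),
            vl.SpacerHit("spB", "v2", 100.0, 1.0, 5, 37, "-"),
        ]
        origin = {"spA": "Chlorobi", "spB": "Gammaproteobacteria"}
        hosts = vl.assign_hosts(hits, origin, clusters)
        assert hosts["CL1"] == {"Chlorobi", "Gammaproteobacteria"}

    def test_no_hits_empty_set(self):
        clusters = [vl.ViralCluster("CL1", ["v1"])]
        assert vl.assign_hosts([], {}, clusters) == {"CL1": set()}


class TestSpacerLinkageRecovery:
    def test_mutation_free_recall_is_total(self, noisy_result, default_scenario_fixture):
        scenario = default_scenario_fixture
        spacers, truth = plant_spacers(
            noisy_result, scenario.virus_profiles, mutation_rate=0.0, seed=1)
        hits = vl.match_spacers(spacers, noisy_result.virus_genomes)
        hit_pairs = {(h.spacer_id, h.target_contig) for h in hits}
        for spacer_id, virus in zip(truth["spacer_id"], truth["source_virus"]):
            assert (spacer_id, virus) in hit_pairs
        # and host assignment recovers exactly the donor hosts
        clusters = noisy_result.virus_clusters()
        contig_hits = vl.match_spacers(spacers, noisy_result.virus_sequences)
        origin = dict(zip(truth["spacer_id"], truth["host_taxon"]))
        hosts = vl.assign_hosts(contig_hits, origin, clusters)
        donors = {v.name for v in scenario.virus_profiles if v.spacer_donor}
        for virus in scenario.virus_profiles:
            if virus.name in donors:
                assert hosts[virus.name] == {virus.host_otu}
            else:
                assert hosts[virus.name] == set()

    def test_no_cross_virus_hits_without_shared_kmers(self, noisy_result,
                                                     default_scenario_fixture):
        """A spacer from one virus never matches another virus's genome when
        the genomes share no 20-mer (checked by brute force)."""
        scenario = default_scenario_fixture
        genomes = noisy_result.virus_genomes
        spacers, truth = plant_spacers(
            noisy_result, scenario.virus_profiles, mutation_rate=0.0, seed=2)
        names = list(genomes)
        kmers = {
            name: {genomes[name][i: i + 20] for i in range(len(genomes[name]) - 19)}
            for name in names
        }
        hits = vl.match_spacers(spacers, genomes)
        source = dict(zip(truth["spacer_id"], truth["source_virus"]))
        for hit in hits:
            if hit.target_contig != source[hit.spacer_id]:
                shared = kmers[hit.target_contig] & kmers[source[hit.spacer_id]]
                assert shared, "cross-virus hit without any shared 20-mer"


class TestCorrelation:
    def test_proportional_series(self):
        r, p = vl.host_virus_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            vl.host_virus_correlation([1, 2, 3], [5, 5, 5])

    def test_planted_coupling_recovered(self, correlation_result):
        """A virus planted at coupling 0.9 over 40 paired strata is
        estimated within the Fisher 95% CI of 0.9."""
        host, virus = {}, {}
        for sample in correlation_result.samples:
            key = (sample.meta.date, sample.meta.depth_code)
            for contig in sample.contigs:
                if "|Chlorobium|" in contig.contig_id:
                    host[key] = host.get(key, 0.0) + contig.coverage()
                if "|GSB_phage_B|" in contig.contig_id:
                    virus[key] = virus.get(key, 0.0) + contig.read_depth
        keys = sorted(set(host) & set(virus))
        assert len(keys) == 40
        r, p = vl.host_virus_correlation(
            [host[k] for k in keys], [virus[k] for k in keys])
        z = np.arctanh(0.9)
        half = 1.96 / np.sqrt(len(keys) - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
        assert lo <= r <= hi
        assert p < 1e-6
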