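from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from tetherscan import coverage, enrichment
from tetherscan.io import GenomicInterval


def _exact_binomial_tail(k, n, p):
    """Arbitrary-precision oracle: sum the pmf over i = k..n exactly."""
    pf = Fraction(p).limit_denominator(10**9)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


class TestProbeStartSites:
    def test_plus_strand_uses_interval_start(self):
        df = pd.DataFrame(
            {"gene_id": ["a"], "chrom": ["chr1"], "start": [100], "end": [200],
             "strand": ["+"]}
        )
        assert enrichment.probe_start_sites(df)["tss"].tolist() == [100]

    def test_minus_strand_uses_last_base(self):
        df = pd.DataFrame(
            {"gene_id": ["a"], "chrom": ["chr1"], "start": [100], "end": [200],
             "strand": ["-"]}
        )
        assert enrichment.probe_start_sites(df)["tss"].tolist() == [199]

    def test_order_preserved_and_missing_strand_error(self):
        df = pd.DataFrame(
            {"gene_id": list("abc"), "chrom": ["chr1"] * 3,
             "start": [300, 100, 200], "end": [400, 200, 300],
             "strand": ["+", "-", "+"]}
        )
        out = enrichment.probe_start_sites(df)
        assert out["gene_id"].tolist() == ["a", "b", "c"]
        assert out["tss"].tolist() == [300, 199, 200]
        bad = df.assign(strand=[None, "+", "-"])
        with pytest.raises(ValueError):
            enrichment.probe_start_sites(bad)


class TestRegulatoryDomains:
    genome = {"chr1": 2_000_000}

    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])

    def test_single_site_pure_extension(self):
        sites = self._sites([("g", "chr1", 500_000, "+")])
        config = enrichment.EnrichmentConfig(mode="extension")
        [d] = enrichment.make_regulatory_domains(sites, 100_000, self.genome, config)
        assert (d.start, d.end) == (400_000, 600_000)

    def test_extension_clipped_at_chromosome_start(self):
        sites = self._sites([("g", "chr1", 10, "+")])
        config = enrichment.EnrichmentConfig(mode="extension")
        [d] = enrichment.make_regulatory_domains(sites, 100_000, self.genome, config)
        assert d.start == 0

    def test_basal_mode_neighbours_abut_basal_boundaries(self):
        # two plus-strand sites 50 kb apart; 1 Mb extensions stop at the
        # neighbour's basal region (5 kb up / 1 kb down of its TSS)
        sites = self._sites(
            [("a", "chr1", 1_000_000, "+"), ("b", "chr1", 1_050_000, "+")]
        )
        config = enrichment.EnrichmentConfig(mode="basal")
        da, db = enrichment.make_regulatory_domains(
            sites, 1_000_000, self.genome, config
        )
        assert da.start == 0  # clipped at chromosome start
        assert da.end == 1_045_000  # b's basal start = 1_050_000 - 5_000
        assert db.start == 1_001_000  # a's basal end = 1_000_000 + 1_000
        assert db.end == 2_000_000

    def test_extension_mode_truncates_at_tss_midpoint(self):
        sites = self._sites(
            [("a", "chr1", 1_000_000, "+"), ("b", "chr1", 1_050_000, "+")]
        )
        config = enrichment.EnrichmentConfig(mode="extension")
        da, db = enrichment.make_regulatory_domains(
            sites, 100_000, self.genome, config
        )
        assert da.end == 1_025_001
        assert db.start == 1_025_000


class TestDomainUnionFraction:
    def test_simple_fraction(self):
        d = enrichment.RegulatoryDomain("g", "chr1", 100_000, 300_000, 200_000, 0)
        assert enrichment.domain_union_fraction([d], {"chr1": 2_000_000}) == 0.1

    def test_duplicate_domains_idempotent(self):
        d = enrichment.RegulatoryDomain("g", "chr1", 100_000, 300_000, 200_000, 0)
        one = enrichment.domain_union_fraction([d], {"chr1": 2_000_000})
        two = enrichment.domain_union_fraction([d, d], {"chr1": 2_000_000})
        assert one == two

    def test_empty_genome_is_error(self):
        with pytest.raises(ValueError):
            enrichment.domain_union_fraction([], {})

    def test_random_domains_match_boolean_array_oracle(self, rng):
        genome = {"chr1": 5000, "chr2": 3000}
        for _ in range(100):
            domains = []
            covered = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
            for i in range(int(rng.integers(1, 30))):
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                s = int(rng.integers(0, genome[chrom] - 100))
                e = s + int(rng.integers(1, 100))
                t = int(rng.integers(s, e))
                domains.append(
                    enrichment.RegulatoryDomain(f"g{i}", chrom, s, e, t, 0)
                )
                covered[chrom][s:e] = True
            expected = sum(int(v.sum()) for v in covered.values()) / sum(
                genome.values()
            )
            got = enrichment.domain_union_fraction(domains, genome)
            assert got == pytest.approx(expected, abs=1e-12)


class TestBinomialEnrichment:
    genome = {"chr1": 1000}

    def _domains(self, spans):
        return [
            enrichment.RegulatoryDomain(f"g{i}", "chr1", s, e, s, 0)
            for i, (s, e) in enumerate(spans)
        ]

    def test_no_hits_gives_p_value_one(self):
        t = enrichment.binomial_enrichment(
            [("chr1", 900)] * 5, self._domains([(0, 100)]), self.genome
        )
        assert t.k == 0 and t.p_value == 1.0

    def test_exact_enumeration_example(self):
        # n=10, p=0.5, k=8 -> (C(10,8)+C(10,9)+C(10,10)) / 2^10 = 56/1024
        summits = [("chr1", 10)] * 8 + [("chr1", 900)] * 2
        t = enrichment.binomial_enrichment(
            summits, self._domains([(0, 500)]), self.genome
        )
        assert (t.n, t.k, t.p) == (10, 8, 0.5)
        assert t.p_value == pytest.approx(56 / 1024, rel=1e-12)

    def test_random_small_instances_match_exact_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 31))
            cov = int(rng.integers(1, 999))
            k = int(rng.integers(0, n + 1))
            summits = [("chr1", 0)] * k + [("chr1", 999)] * (n - k)
            t = enrichment.binomial_enrichment(
                summits, self._domains([(0, cov)]), self.genome
            )
            assert t.k == k
            assert t.p_value == pytest.approx(
                _exact_binomial_tail(k, n, cov / 1000), rel=1e-12
            )

    def test_large_n_matches_exact_oracle(self, rng):
        n, k, cov = 585, 36, 123
        summits = [("chr1", 5)] * k + [("chr1", 980)] * (n - k)
        t = enrichment.binomial_enrichment(
            summits, self._domains([(0, cov)]), self.genome
        )
        assert t.p_value == pytest.approx(
            _exact_binomial_tail(k, n, cov / 1000), rel=1e-9
        )


class TestEmpiricalFdr:
    genome = {"chr1": 100_000, "chr2": 50_000}

    def _setup(self):
        domains = [
            enrichment.RegulatoryDomain("g", "chr1", 0, 10_000, 0, 0)
        ]
        return domains

    def test_observed_p_of_one_gives_fdr_one(self):
        domains = self._setup()
        t = enrichment.binomial_enrichment(
            [("chr2", 40_000)] * 5, domains, self.genome, name="t"
        )
        assert t.p_value == 1.0
        [out] = enrichment.empirical_fdr([t], {"t": domains}, self.genome, seed=3)
        assert out.empirical_fdr == 1.0

    def test_strong_enrichment_reported_below_one_percent(self):
        domains = self._setup()
        t = enrichment.binomial_enrichment(
            [("chr1", 5_000)] * 30, domains, self.genome, name="t"
        )
        [out] = enrichment.empirical_fdr([t], {"t": domains}, self.genome, seed=3)
        assert out.empirical_fdr < 0.01
        assert out.fdr_label == "<0.01"

    def test_reproducible_and_order_invariant(self):
        domains = self._setup()
        t1 = enrichment.binomial_enrichment(
            [("chr1", 5_000)] * 10 + [("chr2", 100)] * 10,
            domains, self.genome, name="a",
        )
        t2 = enrichment.binomial_enrichment(
            [("chr2", 100)] * 3, domains, self.genome, name="b"
        )
        sets = {"a": domains, "b": domains}
        fwd = enrichment.empirical_fdr([t1, t2], sets, self.genome, seed=11)
        rev = enrichment.empirical_fdr([t2, t1], sets, self.genome, seed=11)
        assert {o.name: o.empirical_fdr for o in fwd} == {
            o.name: o.empirical_fdr for o in rev
        }
        again = enrichment.empirical_fdr([t1, t2], sets, self.genome, seed=11)
        assert [o.empirical_fdr for o in again] == [o.empirical_fdr for o in fwd]


class TestProximityEnrichment:
    genome = {"chr1": 1_000_000}

    def _peaks(self, positions):
        return [
            coverage.Peak(f"p{i}", "chr1", pos - 10, pos + 10, pos)
            for i, pos in enumerate(positions)
        ]

    def test_all_summits_inside_windows_closed_form(self):
        anchors = [GenomicInterval("chr1", 500_000, 500_140)]
        peaks = self._peaks([450_000, 520_000, 590_000])
        t = enrichment.proximity_enrichment(anchors, peaks, self.genome, 100_000)
        assert t.k == t.n == 3
        assert t.p_value == pytest.approx(t.p**3, rel=1e-12)

    def test_no_summits_inside_gives_one(self):
        anchors = [GenomicInterval("chr1", 500_000, 500_140)]
        peaks = self._peaks([10_000, 900_000])
        t = enrichment.proximity_enrichment(anchors, peaks, self.genome, 100_000)
        assert t.k == 0 and t.p_value == 1.0

    def test_overlapping_anchor_windows_merged(self):
        anchors = [
            GenomicInterval("chr1", 500_000, 500_140),
            GenomicInterval("chr1", 510_000, 510_140),
        ]
        t = enrichment.proximity_enrichment(
            anchors, self._peaks([505_000]), self.genome, 100_000
        )
        # merged union: [400 070, 610 070) modulo midpoint arithmetic
        assert t.p < 0.22

    def test_no_anchors_is_error(self):
        with pytest.raises(ValueError):
            enrichment.proximity_enrichment([], self._peaks([1000]), self.genome)

    def test_planted_layout_contrast_bound_vs_unbound_anchors(self):
        """With TRE sites planted 10-50 kb from bound elements only, TRE
        binding positions are strongly enriched within 100 kb of bound
        anchors and not of unbound anchors."""
        from tetherscan import synthetic

        spec = synthetic.proximity_study_spec(seed=8)
        _, elements, motif_sites, _ = synthetic.generate_genome(spec)
        peaks = [
            coverage.Peak(r.id, r.chrom, r.start, r.end, (r.start + r.end) // 2)
            for r in motif_sites.itertuples()
        ]
        genome = spec.chrom_lengths

        def anchors(bound):
            sub = elements[elements.bound == bound]
            return [
                GenomicInterval(r.chrom, r.start, r.end)
                for r in sub.itertuples()
            ]

        t_bound = enrichment.proximity_enrichment(
            anchors(True), peaks, genome, 100_000
        )
        t_unbound = enrichment.proximity_enrichment(
            anchors(False), peaks, genome, 100_000
        )
        assert t_bound.p_value < 1e-6
        assert t_unbound.p_value > 0.05


class TestMultiSupport:
    def _query(self, start, end, pid="q"):
        return coverage.Peak(pid, "chr1", start, end, start)

    def test_query_overlapping_all_sets_retained(self):
        refs = {
            f"set{i}": [GenomicInterval("chr1", 100, 200)] for i in range(18)
        }
        retained, matrix = enrichment.count_multi_support(
            [self._query(150, 250)], refs, min_support=10
        )
        assert len(retained) == 1
        assert matrix.loc["q", "support"] == 18

    def test_query_overlapping_nothing_dropped(self):
        refs = {"set0": [GenomicInterval("chr1", 10_000, 10_100)]}
        retained, matrix = enrichment.count_multi_support(
            [self._query(100, 200)], refs, min_support=1
        )
        assert retained == []
        assert matrix.loc["q", "support"] == 0

    def test_slop_extends_overlap_reach(self):
        refs = {"set0": [GenomicInterval("chr1", 240, 300)]}
        retained, _ = enrichment.count_multi_support(
            [self._query(100, 200)], refs, min_support=1, slop=50
        )
        assert len(retained) == 1  # within 50 bp counts as overlap

    def test_random_matrix_matches_all_pairs_oracle(self, rng):
        for _ in range(30):
            queries = [
                self._query(int(s), int(s) + 50, f"q{i}")
                for i, s in enumerate(rng.integers(0, 3000, 10))
            ]
            refs = {}
            for r in range(5):
                refs[f"set{r}"] = [
                    GenomicInterval("chr1", int(s), int(s) + 50)
                    for s in rng.integers(0, 3000, 8)
                ]
            _, matrix = enrichment.count_multi_support(queries, refs, 1, slop=50)
            for q in queries:
                for rname, ivs in refs.items():
                    expected = int(
                        any(
                            iv.start < q.end + 50 and q.start - 50 < iv.end
                            for iv in ivs
                        )
                    )
                    assert matrix.loc[q.id, rname] == expected


class TestGenesNearPeaks:
    def test_summit_in_overlapping_domains_attributed_to_both(self):
        domains = [
            enrichment.RegulatoryDomain("a", "chr1", 0, 1000, 500, 0),
            enrichment.RegulatoryDomain("b", "chr1", 500, 1500, 1000, 0),
        ]
        out = enrichment.genes_near_peaks(domains, [("chr1", 700)])
        assert out == {"a": [("chr1", 700)], "b": [("chr1", 700)]}

    def test_no_summits_empty_map(self):
        domains = [enrichment.RegulatoryDomain("a", "chr1", 0, 1000, 500, 0)]
        assert enrichment.genes_near_peaks(domains, []) == {}
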