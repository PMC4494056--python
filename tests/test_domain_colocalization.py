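from __future__ import annotations

import numpy as np
import pytest

from hsreg.core_genomics import AlignmentChain, BindingSite, GenomicInterval, IntervalSet
from hsreg.domain_colocalization import (
    derive_human_specific_lads,
    domain_length_stats,
    place_in_domains,
    pmd_colocalization,
)
from hsreg.lineage_specificity import SiteClassification


def _site(start, tf="NANOG", sid=None):
    return BindingSite(tf, GenomicInterval("chr1", start, start + 100), site_id=sid)


class TestPlaceInDomains:
    def test_expected_count_published_inputs(self):
        # 167 sites at genome fraction 0.429 -> expected 71.6, rounded 72
        domains = IntervalSet([GenomicInterval("chr1", 0, 429_000)],
                              genome_size={"chr1": 1_000_000})
        sites = [_site(1000 + i * 500, sid=f"s{i}") for i in range(167)]
        result = place_in_domains(sites, domains, fraction=0.429)
        assert result.expected_inside == pytest.approx(71.643)
        assert round(result.expected_inside, 1) == 71.6
        assert result.expected_rounded == 72

    def test_fraction_bounds(self):
        domains = IntervalSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError):
            place_in_domains([_site(1000)], domains, fraction=1.0)

    def test_high_fraction_near_certain(self):
        domains = IntervalSet([GenomicInterval("chr1", 0, 999_999)],
                              genome_size={"chr1": 1_000_000})
        sites = [_site(1000 + i * 100, sid=f"s{i}") for i in range(10)]
        result = place_in_domains(sites, domains)
        assert result.n_inside == 10
        assert result.p_binomial > 0.99

    def test_linear_scaling_identity(self):
        domains = IntervalSet([GenomicInterval("chr1", 0, 400_000)],
                              genome_size={"chr1": 1_000_000})
        for n in (10, 20, 40):
            sites = [_site(1000 + i * 200, sid=f"s{i}") for i in range(n)]
            res = place_in_domains(sites, domains, fraction=0.4)
            assert res.expected_inside == pytest.approx(n * 0.4)

    def test_monte_carlo_inside_count(self):
        # 200 random midpoints on a 40%-covered genome, 20 seeds: the
        # mean inside-fraction concentrates near 0.4
        domains = IntervalSet([GenomicInterval("chr1", 0, 200_000),
                               GenomicInterval("chr1", 500_000, 700_000)],
                              genome_size={"chr1": 1_000_000})
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sites = [_site(int(p), sid=f"s{seed}_{i}")
                     for i, p in enumerate(rng.integers(100, 999_800, 200))]
            res = place_in_domains(sites, domains)
            fractions.append(res.n_inside / res.n_sites)
        se = np.sqrt(0.4 * 0.6 / (200 * 20))
        assert np.mean(fractions) == pytest.approx(0.4, abs=3 * se + 0.01)

    def test_midpoint_rule_matches_half_overlap_rule(self):
        # for 200-bp windows inside >=100-kb domains, midpoint-inside is
        # equivalent to >=50% window overlap
        domains = IntervalSet([GenomicInterval("chr1", 100_000, 200_000)],
                              genome_size={"chr1": 1_000_000})
        rng = np.random.default_rng(4)
        for start in rng.integers(99_000, 201_000, 300):
            site = _site(int(start))
            midpoint_in = domains.contains_point("chr1", site.midpoint)
            overlap = max(0, min(site.window.end, 200_000)
                          - max(site.window.start, 100_000))
            assert midpoint_in == (overlap >= site.window.length() / 2)


class TestDeriveHumanSpecificLads:
    def _setup(self):
        # mouse genome == human coordinates (identity chain, one block)
        chain = AlignmentChain(1, 1.0, "chr1", 2_000_000, "+", 0, 2_000_000,
                               "chr1", 2_000_000, "+", 0, 2_000_000,
                               [(2_000_000, 0, 0)])
        human_lads = IntervalSet(name="human_lads")
        planted_specific = []
        mouse_sets = {ct: IntervalSet(name=ct)
                      for ct in ("esc", "npc", "astrocyte", "mef")}
        pos = 10_000
        for i in range(20):
            lad = GenomicInterval("chr1", pos, pos + 40_000)
            human_lads.add(lad)
            if i < 12:  # planted human-specific: outside mouse LADs everywhere
                planted_specific.append(lad)
            else:       # covered by mouse LADs in all four cell types
                for ct in mouse_sets.values():
                    ct.add(GenomicInterval("chr1", pos - 1000, pos + 41_000))
            pos += 60_000
        return human_lads, [chain], mouse_sets, planted_specific

    def test_planted_recovery_exact(self):
        human_lads, chains, mouse_sets, planted = self._setup()
        out = derive_human_specific_lads(human_lads, chains, mouse_sets)
        got = {(h.interval.start, h.interval.end) for h in out}
        assert got == {(p.start, p.end) for p in planted}

    def test_single_cell_type_overlap_rejects(self):
        human_lads, chains, mouse_sets, planted = self._setup()
        # add an overlap in ONE cell type for the first planted LAD
        first = planted[0]
        mouse_sets["esc"].add(GenomicInterval("chr1", first.start, first.end))
        out = derive_human_specific_lads(human_lads, chains, mouse_sets)
        assert (first.start, first.end) not in {
            (h.interval.start, h.interval.end) for h in out}

    def test_requires_four_cell_types(self):
        human_lads, chains, mouse_sets, _ = self._setup()
        del mouse_sets["mef"]
        with pytest.raises(ValueError):
            derive_human_specific_lads(human_lads, chains, mouse_sets)

    def test_unliftable_lad_dropped(self):
        # chain covering only half the LAD -> below min_match -> dropped
        chain = AlignmentChain(1, 1.0, "chr1", 100_000, "+", 0, 100_000,
                               "chr1", 60_000, "+", 0, 60_000,
                               [(30_000, 40_000, 0), (30_000, 0, 0)])
        lads = IntervalSet([GenomicInterval("chr1", 20_000, 60_000)])
        mouse_sets = {ct: IntervalSet() for ct in ("a", "b", "c", "d")}
        assert derive_human_specific_lads(lads, [chain], mouse_sets) == []

    def test_output_subset_and_rerun_stable(self):
        human_lads, chains, mouse_sets, _ = self._setup()
        out1 = derive_human_specific_lads(human_lads, chains, mouse_sets)
        out2 = derive_human_specific_lads(human_lads, chains, mouse_sets)
        spans = {(iv.start, iv.end) for iv in human_lads}
        assert all((h.interval.start, h.interval.end) in spans for h in out1)
        assert [(h.interval.start, h.interval.end) for h in out1] == \
               [(h.interval.start, h.interval.end) for h in out2]


class TestDomainLengthStats:
    def test_published_fold_ratio(self):
        # mean lengths 361 kb vs 980 kb -> fold 2.7
        a = [GenomicInterval("chr1", 0, 361_000)] * 5
        b = [GenomicInterval("chr1", 0, 980_000)] * 5
        stats = domain_length_stats(a, b)
        assert stats["fold_ratio"] == 2.7

    def test_identical_sets_ratio_one(self):
        a = [GenomicInterval("chr1", 0, 500_000)] * 4
        stats = domain_length_stats(a, list(a))
        assert stats["fold_ratio"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            domain_length_stats([], [GenomicInterval("chr1", 0, 10)])

    def test_exponential_lengths_recovered(self):
        rng = np.random.default_rng(9)
        a = [GenomicInterval("chr1", 0, max(1, int(x)))
             for x in rng.exponential(100_000, 400)]
        b = [GenomicInterval("chr1", 0, max(1, int(x)))
             for x in rng.exponential(270_000, 400)]
        stats = domain_length_stats(a, b, test="welch")
        assert stats["mean_a"] == pytest.approx(100_000, rel=0.15)
        assert stats["mean_b"] == pytest.approx(270_000, rel=0.15)
        assert stats["p_value"] < 1e-6


class TestPmdColocalization:
    def test_published_fraction_arithmetic(self):
        assert round(100 * 257 / 290, 1) == 88.6
        assert round(100 * 482 / 826, 1) == 58.4

    def test_planted_fraction_recovered(self):
        pmds = IntervalSet([GenomicInterval("chr1", 0, 900_000)],
                           genome_size={"chr1": 1_000_000})
        rng = np.random.default_rng(12)
        classified = []
        n_inside_planted = 0
        for i in range(200):
            inside = rng.random() < 0.9
            pos = int(rng.integers(1_000, 899_000)) if inside \
                else int(rng.integers(900_500, 998_000))
            n_inside_planted += inside
            site = _site(pos, sid=f"s{i}")
            classified.append(SiteClassification(
                site.site_id, "NANOG", "human_specific", site=site))
        out = pmd_colocalization(classified, pmds)
        cell = out[("NANOG", "human_specific")]
        assert cell["n_inside"] == n_inside_planted
        assert cell["fraction_pct"] == pytest.approx(
            100 * n_inside_planted / 200, abs=0.1)
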