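"""z-score calling, fence stratification and spanning corroboration."""

import math

import numpy as np
import pytest

from cleavemap.caller import (
    DegenerateRatios,
    FenceResult,
    abundance_fence,
    call_sites,
    compute_ratios,
    corroborate,
)
from cleavemap.catalog import deduplicate
from cleavemap.digest import TRYPSIN, classify_peptide
from cleavemap.model import CleavemapError, ProteinRecord


def ratio_obs(obs_factory, protein, start, end, log2_ratio, base=20.0):
    """Observation with a prescribed log2(E/EQ) ratio."""
    eq = 2.0 ** base
    return obs_factory(
        protein, start, end, abundance_E=eq * 2.0 ** log2_ratio, abundance_EQ=eq
    )


@pytest.fixture
def protein():
    # 40 residues, tryptic sites sprinkled throughout.
    return ProteinRecord("P", "MKTAYRAAKAAGELWSDKGHMNKLVRTTSKAAEYRGGWSK")


class TestComputeRatios:
    def test_hand_computed_population(self, obs_factory, protein):
        # log2 ratios {0,0,0,0,10}: mean 2, sample sd sqrt(20).
        ratios = [0, 0, 0, 0, 10]
        observations = [
            ratio_obs(obs_factory, protein, 1 + i, 6 + i, r)
            for i, r in enumerate(ratios)
        ]
        records = compute_ratios(observations)
        assert records[0].z == pytest.approx(-2 / math.sqrt(20))
        assert records[-1].z == pytest.approx(8 / math.sqrt(20))
        assert records[-1].z == pytest.approx(1.789, abs=1e-3)

    def test_population_normalised(self, obs_factory, protein, rng):
        observations = [
            ratio_obs(
                obs_factory, protein, 1 + i, 10 + i, float(rng.normal(0, 2))
            )
            for i in range(25)
        ]
        zs = np.array([r.z for r in compute_ratios(observations)])
        assert abs(zs.mean()) < 1e-9
        assert abs(zs.std(ddof=1) - 1.0) < 1e-9

    def test_mean_ratio_scores_zero(self, obs_factory, protein):
        observations = [
            ratio_obs(obs_factory, protein, 1 + i, 8 + i, r)
            for i, r in enumerate([-3.0, 0.0, 3.0])
        ]
        assert compute_ratios(observations)[1].z == pytest.approx(0.0)

    def test_degenerate_distribution_raises(self, obs_factory, protein):
        observations = [
            ratio_obs(obs_factory, protein, 1 + i, 8 + i, 1.5)
            for i in range(4)
        ]
        with pytest.raises(DegenerateRatios):
            compute_ratios(observations)

    def test_too_few_coquantified_raises(self, obs_factory, protein):
        observations = [
            ratio_obs(obs_factory, protein, 1, 8, 0.0),
            ratio_obs(obs_factory, protein, 2, 9, 1.0),
        ]
        with pytest.raises(CleavemapError, match="at least 3"):
            compute_ratios(observations)

    def test_exclusives_sidelined_not_scored(self, obs_factory, protein):
        observations = [
            ratio_obs(obs_factory, protein, 1 + i, 8 + i, r)
            for i, r in enumerate([-1.0, 0.0, 1.0])
        ]
        observations.append(
            obs_factory(protein, 5, 12, abundance_E=500.0, abundance_EQ=None)
        )
        records = compute_ratios(observations)
        exclusive = records[-1]
        assert exclusive.exclusive_group == "E_only"
        assert exclusive.z is None
        scored = [r for r in records if r.z is not None]
        assert len(scored) == 3

    def test_abundance_reference_is_enriched_group(self, obs_factory, protein):
        obs = obs_factory(protein, 1, 8, abundance_E=4096.0, abundance_EQ=16.0)
        filler = [
            ratio_obs(obs_factory, protein, 2 + i, 9 + i, r)
            for i, r in enumerate([-1.0, 0.0, 1.0])
        ]
        records = compute_ratios([obs] + filler)
        assert records[0].log2_abundance == pytest.approx(12.0)


class TestFence:
    def test_hand_computed_quartiles(self, obs_factory, protein):
        observations = [
            obs_factory(protein, 1 + i, 8 + i, abundance_E=2.0 ** v,
                        abundance_EQ=1.0)
            for i, v in enumerate([10, 12, 14, 16, 18])
        ]
        fence = abundance_fence(compute_ratios(observations))
        assert fence.q1 == pytest.approx(12.0)
        assert fence.q3 == pytest.approx(16.0)
        assert fence.iqr == pytest.approx(4.0)
        assert fence.lower_fence == pytest.approx(6.0)
        assert fence.upper_fence == pytest.approx(22.0)

    def test_all_equal_collapses(self, obs_factory, protein):
        observations = [
            obs_factory(protein, 1 + i, 8 + i, abundance_E=1024.0,
                        abundance_EQ=2.0 ** (i / 10))
            for i in range(5)
        ]
        fence = abundance_fence(compute_ratios(observations))
        assert fence.iqr == pytest.approx(0.0)
        assert fence.lower_fence == fence.upper_fence == pytest.approx(10.0)

    def test_matches_interpolation_oracle(self, obs_factory, protein, rng):
        values = sorted(float(v) for v in rng.uniform(0, 100, size=37))

        def quantile(p):  # linear interpolation of order statistics
            h = (len(values) - 1) * p
            lo = int(math.floor(h))
            hi = min(lo + 1, len(values) - 1)
            return values[lo] + (h - lo) * (values[hi] - values[lo])

        observations = [
            obs_factory(protein, 1 + (i % 30), 8 + (i % 30),
                        abundance_E=2.0 ** v, abundance_EQ=2.0 ** (v - i * 1e-3))
            for i, v in enumerate(values)
        ]
        fence = abundance_fence(compute_ratios(observations), k=1.5)
        assert fence.q1 == pytest.approx(quantile(0.25))
        assert fence.q3 == pytest.approx(quantile(0.75))
        assert fence.lower_fence == pytest.approx(
            quantile(0.25) - 1.5 * (quantile(0.75) - quantile(0.25))
        )

    def test_too_few_records(self, obs_factory, protein):
        observations = [
            ratio_obs(obs_factory, protein, 1 + i, 8 + i, float(i))
            for i in range(3)
        ]
        with pytest.raises(CleavemapError, match="at least 4"):
            abundance_fence(compute_ratios(observations))


def build_population(obs_factory, protein, semi_specs, n_null=40, seed=5):
    """Observations: a null fully-specific population plus prescribed
    semi-specific peptides with strong E enrichment.

    ``semi_specs`` are (start, end, log2_ratio) with termini chosen by the
    caller to be semi-specific for trypsin.
    """
    rng = np.random.default_rng(seed)
    observations = []
    for i in range(n_null):
        start = 1 + (i % 20)
        # Null peptides: tiny ratio jitter around zero.
        observations.append(
            ratio_obs(obs_factory, protein, start, start + 7,
                      float(rng.normal(0, 0.05)))
        )
    for start, end, r in semi_specs:
        observations.append(ratio_obs(obs_factory, protein, start, end, r))
    return observations


class TestCallSites:
    def test_merging_across_flanking_peptides(self, obs_factory, protein):
        # A semi_c peptide ending at L14 and a semi_n peptide starting at
        # W15 both imply the non-tryptic bond 14-15 and must merge.
        semis = [(7, 14, 8.0), (15, 18, 8.0)]
        observations = build_population(obs_factory, protein, semis)
        records = compute_ratios(observations)
        specs = [classify_peptide(o, TRYPSIN) for o in observations]
        assert {s.peptide_class for s in specs[-2:]} == {"semi_c", "semi_n"}
        calls = call_sites(records, specs, z_threshold=2.0, enzyme="ENZ")
        merged = deduplicate(calls)
        entry = merged.entries[("P", 14, "ENZ")]
        assert len(entry.semi_evidence) == 2
        assert entry.p1_aa == "L" and entry.p1prime_aa == "W"

    def test_empty_records(self):
        assert call_sites([], [], 2.0, None) == []

    def test_threshold_monotonicity(self, obs_factory, protein, rng):
        # Six distinct non-tryptic bonds with z-scores spread over a range.
        spans = [(7, 14), (19, 21), (24, 25), (27, 29), (31, 33), (36, 38)]
        semis = [
            (s, e, float(r))
            for (s, e), r in zip(spans, rng.uniform(0, 10, size=6))
        ]
        observations = build_population(obs_factory, protein, semis)
        records = compute_ratios(observations)
        specs = [classify_peptide(o, TRYPSIN) for o in observations]
        n_calls = [
            len(call_sites(records, specs, z, None))
            for z in (0.5, 1.0, 2.0, 3.0, 5.0)
        ]
        assert n_calls == sorted(n_calls, reverse=True)

    def test_below_fence_retained_and_flagged(self, obs_factory, protein):
        semis = [(7, 14, 8.0)]
        observations = build_population(obs_factory, protein, semis)
        # Give the semi peptide a very low abundance.
        observations[-1].abundance_E = 2.0 ** 4 * 2.0 ** 8
        observations[-1].abundance_EQ = 2.0 ** 4
        records = compute_ratios(observations)
        specs = [classify_peptide(o, TRYPSIN) for o in observations]
        fence = abundance_fence(records)
        calls = call_sites(records, specs, 2.0, fence)
        assert len(calls) == 1
        assert calls[0].tier == "outlier_low"

    def test_merge_idempotence(self, obs_factory, protein, rng):
        semis_a = [(7, 14, 8.0), (15, 18, 7.0)]
        semis_b = [(7, 14, 8.0), (27, 29, 7.5)]

        def calls_for(semis, n_null=40):
            observations = build_population(obs_factory, protein, semis, n_null)
            records = compute_ratios(observations)
            specs = [classify_peptide(o, TRYPSIN) for o in observations]
            return call_sites(records, specs, 2.0, None, enzyme="E1")

        merged_separately = deduplicate(
            deduplicate(calls_for(semis_a)).calls()
            + deduplicate(calls_for(semis_b)).calls()
        )
        pooled = deduplicate(calls_for(semis_a) + calls_for(semis_b))
        assert set(merged_separately.entries) == set(pooled.entries)
        # Idempotence proper: re-deduplicating changes nothing.
        again = deduplicate(pooled.calls())
        assert set(again.entries) == set(pooled.entries)


class TestCorroborate:
    def test_spanner_attaches_to_contained_site(self, obs_factory, protein):
        semis = [(7, 14, 8.0)]
        observations = build_population(obs_factory, protein, semis)
        # Fully tryptic peptide 7..18 spans the called bond 14-15 and is
        # strongly EQ-enriched.
        spanner = ratio_obs(obs_factory, protein, 7, 18, -8.0)
        observations.append(spanner)
        records = compute_ratios(observations)
        specs = [classify_peptide(o, TRYPSIN) for o in observations]
        assert specs[-1].peptide_class == "fully"
        calls = call_sites(records, specs, 2.0, None)
        fully = [
            r for r, s in zip(records, specs) if s.peptide_class == "fully"
        ]
        calls, orphans = corroborate(calls, fully, 2.0)
        target = next(c for c in calls if c.p1_pos == 14)
        assert len(target.spanning_evidence) == 1
        assert orphans == []

    def test_no_fully_records_no_orphans(self, obs_factory, protein):
        semis = [(7, 14, 8.0)]
        observations = build_population(obs_factory, protein, semis)
        records = compute_ratios(observations)
        specs = [classify_peptide(o, TRYPSIN) for o in observations]
        calls = call_sites(records, specs, 2.0, None)
        calls, orphans = corroborate(calls, [], 2.0)
        assert orphans == []
        assert all(not c.spanning_evidence for c in calls)

    def test_uncovered_spanner_becomes_orphan(self, obs_factory, protein):
        observations = build_population(obs_factory, protein, [])
        spanner = ratio_obs(obs_factory, protein, 31, 40, -8.0)
        observations.append(spanner)
        records = compute_ratios(observations)
        specs = [classify_peptide(o, TRYPSIN) for o in observations]
        calls = call_sites(records, specs, 2.0, None)
        fully = [
            r for r, s in zip(records, specs) if s.peptide_class == "fully"
        ]
        calls, orphans = corroborate(calls, fully, 2.0)
        assert len(orphans) == 1
        assert orphans[0].interval == (31, 40)


class TestFenceResult:
    def test_tiering(self):
        fence = FenceResult(q1=10, q3=20, iqr=10, lower_fence=-5,
                            upper_fence=35, k=1.5)
        assert fence.tier(-10) == "outlier_low"
        assert fence.tier(15) == "typical"
        assert fence.tier(50) == "outlier_high"
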