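"""Quality tiers, dereplication, presence rule, prevalence and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbsdetect import (
    DetectionCall,
    MAGRecord,
    ScreenResult,
    abundance_summary,
    classify_quality,
    concordance_report,
    confirm_with_screen,
    core_threshold,
    dereplicate,
    detect_presence,
    generate_genome,
    mutate_genome,
    prevalence_and_core,
    quality_score,
)
from cbsdetect.detect import SpeciesCluster


class TestClassifyQuality:
    @pytest.mark.parametrize(
        "completeness,contamination,tier",
        [
            (91, 4, "HQ"),
            (90, 4, "MQ"),  # HQ completeness bound is strict
            (95, 5, "MQ"),  # HQ contamination bound is strict
            (50, 9.9, "MQ"),
            (49, 1, "discarded"),
            (60, 10, "discarded"),
            (100, 0, "HQ"),
        ],
    )
    def test_tier_boundaries(self, completeness, contamination, tier):
        assert classify_quality(completeness, contamination) == tier

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_quality(101, 0)
        with pytest.raises(ValueError):
            classify_quality(50, -1)


class TestQualityScore:
    def test_formula(self):
        mag = MAGRecord("m", "s", 95, 2, 10**5)
        assert quality_score(mag) == pytest.approx(95 - 10 + 2.5)

    def test_perfect_genome(self):
        assert quality_score(MAGRecord("m", "s", 100, 0, 1)) == pytest.approx(100.0)

    def test_contamination_lowers_score(self):
        clean = MAGRecord("m", "s", 80, 1, 10**4)
        dirty = MAGRecord("m", "s", 80, 3, 10**4)
        assert quality_score(dirty) < quality_score(clean)


class TestDereplicate:
    def _mags_and_genomes(self, n_ancestors, per_cluster, within_rate, length=20_000):
        mags, genomes = [], {}
        for a in range(n_ancestors):
            anc = generate_genome(length, 0.5, seed=700 + a, id=f"anc{a}")
            for j in range(per_cluster):
                mid = f"A{a}M{j}"
                if j == 0:
                    g = anc
                else:
                    g, _ = mutate_genome(anc, within_rate, seed=800 + 10 * a + j)
                genomes[mid] = g
                mags.append(MAGRecord(mid, f"s{j}", 95 - j, 1, 50_000))
        return mags, genomes

    def test_three_genome_example(self):
        """ANI(A,B)=0.97, A and B unrelated to C -> clusters {A,B}, {C}."""
        a = generate_genome(20_000, 0.5, seed=61, id="A")
        b, _ = mutate_genome(a, 0.03, seed=62, id="B")
        c = generate_genome(20_000, 0.5, seed=63, id="C")
        mags = [
            MAGRecord("A", "s1", 95, 1, 50_000),
            MAGRecord("B", "s2", 90, 1, 50_000),
            MAGRecord("C", "s3", 85, 1, 50_000),
        ]
        clusters = dereplicate(mags, {"A": a, "B": b, "C": c})
        parts = sorted(sorted(c.member_mag_ids) for c in clusters)
        assert parts == [["A", "B"], ["C"]]
        rep = {frozenset(c.member_mag_ids): c.representative_mag_id for c in clusters}
        assert rep[frozenset({"A", "B"})] == "A"  # highest quality score

    def test_all_distant_singletons(self):
        genomes = {
            f"g{i}": generate_genome(10_000, 0.5, seed=900 + i, id=f"g{i}")
            for i in range(4)
        }
        mags = [MAGRecord(f"g{i}", "s", 80, 1, 10_000) for i in range(4)]
        clusters = dereplicate(mags, genomes)
        assert len(clusters) == 4
        assert all(len(c.member_mag_ids) == 1 for c in clusters)

    def test_planted_partition_recovered(self):
        mags, genomes = self._mags_and_genomes(3, 3, within_rate=0.01)
        clusters = dereplicate(mags, genomes)
        assert len(clusters) == 3
        parts = {frozenset(c.member_mag_ids) for c in clusters}
        expected = {frozenset({f"A{a}M{j}" for j in range(3)}) for a in range(3)}
        assert parts == expected

    def test_partition_property(self):
        mags, genomes = self._mags_and_genomes(2, 3, within_rate=0.01)
        clusters = dereplicate(mags, genomes)
        seen = [m for c in clusters for m in c.member_mag_ids]
        assert sorted(seen) == sorted(m.mag_id for m in mags)

    def test_discarded_tier_rejected(self):
        mags = [MAGRecord("bad", "s", 30, 1, 1000)]
        g = generate_genome(5000, 0.5, seed=64, id="bad")
        with pytest.raises(ValueError):
            dereplicate(mags, {"bad": g})

    def test_missing_genome_rejected(self):
        mags = [MAGRecord("m", "s", 95, 1, 1000)]
        with pytest.raises(KeyError):
            dereplicate(mags, {})


class TestDetectPresence:
    @pytest.mark.parametrize(
        "b2,ani,expected",
        [
            (0.50, 0.95, True),  # both bounds inclusive
            (0.49, 0.99, False),
            (0.60, 0.949, False),
            (0.90, None, False),  # undefined ANI fails
            (1.0, 1.0, True),
        ],
    )
    def test_rule_boundaries(self, b2, ani, expected):
        assert detect_presence(b2, ani) is expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        b2=st.floats(0, 1),
        ani=st.floats(0, 1),
        db=st.floats(0, 1),
        da=st.floats(0, 1),
    )
    def test_threshold_monotone(self, b2, ani, db, da):
        """Raising B2 or ANI never flips a present call to absent."""
        before = detect_presence(b2, ani)
        after = detect_presence(min(1.0, b2 + db), min(1.0, ani + da))
        assert not (before and not after)


class TestConfirmWithScreen:
    def _call(self, b2=0.9):
        return DetectionCall("s", "c", b2, 0.99, True)

    def _screen(self, containment, p):
        return ScreenResult("c", 9000, containment, containment ** (1 / 21), 5.0, p)

    def test_confirmed(self):
        assert confirm_with_screen(self._call(), self._screen(0.96, 1e-30))

    def test_boundary_strict(self):
        assert not confirm_with_screen(self._call(), self._screen(0.95, 1e-30))

    def test_pvalue_ceiling(self):
        assert not confirm_with_screen(
            self._call(), self._screen(0.99, 1e-5), max_pvalue=1.47e-21
        )

    def test_absent_call_rejected(self):
        call = DetectionCall("s", "c", 0.1, None, False)
        with pytest.raises(ValueError):
            confirm_with_screen(call, self._screen(0.99, 1e-30))


class TestPrevalenceAndCore:
    def _study(self, n_samples, present_samples, cbs_id="CBS_m0"):
        clusters = [SpeciesCluster(cbs_id, ["m0"], "m0")]
        mags = [MAGRecord("m0", "s0", 95, 1, 10_000)]
        calls = [
            DetectionCall(f"s{i}", cbs_id, 0.9, 0.99, f"s{i}" in present_samples)
            for i in range(n_samples)
        ]
        return calls, clusters, mags

    def test_core_threshold_18_samples(self):
        assert core_threshold(18, 0.75) == 14

    def test_core_membership(self):
        present = {f"s{i}" for i in range(14)}
        calls, clusters, mags = self._study(18, present)
        table, core = prevalence_and_core(calls, clusters, mags)
        assert core == ["CBS_m0"]

    def test_below_core_threshold(self):
        present = {f"s{i}" for i in range(13)} - {"s0"} | {"s0"}  # 13 mapping + s0 assembly
        calls, clusters, mags = self._study(18, {f"s{i}" for i in range(1, 13)})
        table, core = prevalence_and_core(calls, clusters, mags)
        # 12 mapping-present + 1 assembly = 13 < 14
        assert core == []

    def test_assembly_evidence_overrides_failed_mapping(self):
        calls, clusters, mags = self._study(3, set())  # mapping fails everywhere
        table, core = prevalence_and_core(calls, clusters, mags)
        j = table.samples.index("s0")
        assert table.evidence[0, j] == "assembly"
        assert table.cells[0, j]
        assert table.cells.sum() == 1

    def test_cells_match_evidence(self):
        calls, clusters, mags = self._study(5, {"s2", "s3"})
        table, _ = prevalence_and_core(calls, clusters, mags)
        assert np.array_equal(table.cells, table.evidence != "absent")
        assert table.evidence[0, table.samples.index("s2")] == "mapping-only"

    def test_unknown_mag_sample_rejected(self):
        clusters = [SpeciesCluster("c", ["m0"], "m0")]
        mags = [MAGRecord("m0", "elsewhere", 95, 1, 10_000)]
        calls = [DetectionCall("s0", "c", 0.9, 0.99, True)]
        with pytest.raises(ValueError):
            prevalence_and_core(calls, clusters, mags)


class TestConcordance:
    def _screen(self, containment, p=1e-30):
        return ScreenResult("c", 1, containment, 0.99, 5.0, p)

    def test_counts_and_fraction(self):
        calls = [
            DetectionCall("s0", "c", 0.95, 0.99, True),
            DetectionCall("s1", "c", 0.65, 0.99, True),
            DetectionCall("s2", "c", 0.85, 0.99, True),
            DetectionCall("s3", "c", 0.55, 0.99, True),
            DetectionCall("s4", "c", 0.10, None, False),
        ]
        screens = {
            ("s0", "c"): self._screen(0.99),
            ("s1", "c"): self._screen(0.80),  # unconfirmed, B2 in [0.5, 0.7)
            ("s2", "c"): self._screen(0.85),  # unconfirmed, B2 in [0.7, 0.9)
            ("s3", "c"): self._screen(0.97),
        }
        rep = concordance_report(calls, screens)
        assert (rep.n_detected, rep.n_confirmed) == (4, 2)
        assert rep.fraction == pytest.approx(0.5)
        assert rep.unconfirmed_b2_strata == {"0.5-0.7": 1, "0.7-0.9": 1, ">=0.9": 0}

    def test_no_detections_not_applicable(self):
        rep = concordance_report([DetectionCall("s", "c", 0.1, None, False)], {})
        assert rep.n_detected == 0 and rep.fraction is None


class TestAbundanceSummary:
    def test_direct_statistics(self):
        fractions = {("s1", "a"): 0.1, ("s2", "a"): 0.2, ("s3", "a"): 0.3}
        df = abundance_summary(fractions, {"a": "Actinobacteria"})
        row = df.loc["Actinobacteria"]
        assert row["median"] == pytest.approx(20.0)
        assert row["iqr"] == pytest.approx(10.0)
        assert row["n_cbs"] == 1

    def test_sample_order_invariance(self):
        fr = {("s1", "a"): 0.1, ("s2", "a"): 0.4, ("s1", "b"): 0.5}
        tax = {"a": "P1", "b": "P2"}
        df1 = abundance_summary(fr, tax)
        df2 = abundance_summary(dict(reversed(list(fr.items()))), tax)
        assert df1.equals(df2)

    def test_unknown_cbs_rejected(self):
        with pytest.raises(KeyError):
            abundance_summary({("s", "x"): 0.1}, {})

    def test_empty_taxon_omitted(self):
        df = abundance_summary({("s", "a"): 0.1}, {"a": "P1", "b": "P2"})
        assert list(df.index) == ["P1"]
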