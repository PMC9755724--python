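import numpy as np
import pytest
from scipy import stats as sps

from exonevo import (
    RegionSpec,
    align_global,
    alignment_stats,
    classify_homology,
    conservation_ratio,
    identity_matrix,
    rank_by_similarity,
    region_homology_table,
)
from exonevo.seq_io import ExonInterval, ExonMap, ProteinRecord
from exonevo.simulate import (
    Region,
    SimulationConfig,
    make_preset,
    simulate_family,
    with_seed,
)
from conftest import random_protein


def _annotate(records, maps):
    return [(r, maps[r.record_id]) for r in records]


class TestRegionHomologyTable:
    def test_zero_rate_region_is_fully_identical(self, scheme):
        config = SimulationConfig(
            tree="(a:0.5,b:0.5,c:0.5)root;",
            architecture=(Region("frozen", 80, 0.0), Region("hot", 80, 0.5)),
            seed=4,
        )
        records, maps, _ = simulate_family(config)
        reference, *targets = _annotate(records, maps)
        rows = region_homology_table(
            reference, targets, [RegionSpec("frozen", ("frozen",))], scheme
        )
        assert len(rows) == 2
        assert all(r.identity_pct == 100.0 for r in rows)

    def test_hand_computed_identities_on_gapfree_family(self, scheme, rng):
        """k substitutions in an L-residue region give identity 100(L-k)/L."""
        base = random_protein(rng, 90) + random_protein(rng, 60)
        exon_map = ExonMap("x", (ExonInterval("A", 0, 90), ExonInterval("B", 90, 150)))
        ref = ProteinRecord("x", base)
        mutated = list(base)
        # 9 substitutions in region A, 0 in region B, all to a safe residue
        # cycle guaranteeing a mismatch.
        for pos in range(0, 90, 10):
            mutated[pos] = "W" if mutated[pos] != "W" else "Y"
        target = ProteinRecord("x", "".join(mutated))
        rows = region_homology_table(
            (ref, exon_map),
            [(target, exon_map)],
            [RegionSpec("A", ("A",)), RegionSpec("B", ("B",))],
            scheme,
        )
        by_region = {r.region_name: r for r in rows}
        assert by_region["A"].identity_pct == pytest.approx(100 * (90 - 9) / 90)
        assert by_region["B"].identity_pct == 100.0

    def test_unresolvable_region_skipped_silently(self, scheme, rng):
        ref = ProteinRecord("r", random_protein(rng, 100))
        ref_map = ExonMap("r", (ExonInterval("1", 0, 100),))
        t1 = ProteinRecord("t1", random_protein(rng, 100))
        rows = region_homology_table(
            (ref, ref_map),
            [(t1, ExonMap("t1", (ExonInterval("1", 0, 100),)))],
            [RegionSpec("1", ("1",)), RegionSpec("ghost", ("zz",))],
            scheme,
        )
        assert [r.region_name for r in rows] == ["1"]

    def test_no_resolvable_regions_is_an_error(self, scheme, rng):
        ref = ProteinRecord("r", random_protein(rng, 50))
        with pytest.raises(ValueError, match="no resolvable"):
            region_homology_table(
                (ref, None), [(ref, None)], [RegionSpec("z", ("z",))], scheme
            )


class TestIdentityMatrix:
    def test_identical_records_give_all_100(self, scheme, rng):
        seq = random_protein(rng, 60)
        records = [
            (ProteinRecord("a", seq), None),
            (ProteinRecord("b", seq), None),
        ]
        pim = identity_matrix(records, RegionSpec("full"), scheme)
        assert np.array_equal(pim.values, np.full((2, 2), 100.0))

    def test_entries_decrease_with_tree_distance(self, scheme):
        """A 4-taxon caterpillar: close pairs beat distant pairs."""
        config = SimulationConfig(
            tree="((a:0.05,b:0.05)ab:0.4,(c:0.05,d:0.05)cd:0.4)root;",
            architecture=(Region("R", 200, 0.5),),
            seed=9,
        )
        records, maps, _ = simulate_family(config)
        pim = identity_matrix(_annotate(records, maps), RegionSpec("full"), scheme)
        idx = {lab: i for i, lab in enumerate(pim.labels)}
        close = pim.values[idx["a"], idx["b"]]
        far = pim.values[idx["a"], idx["c"]]
        assert close > far

    def test_fewer_than_two_usable_records_rejected(self, scheme, rng):
        records = [(ProteinRecord("a", random_protein(rng, 30)), None)]
        with pytest.raises(ValueError, match="at least 2"):
            identity_matrix(records, RegionSpec("full"), scheme)

    def test_symmetry_and_diagonal(self, scheme):
        records, maps, _ = simulate_family(
            make_preset("vertebrate_4a", seed=2)
        )
        pim = identity_matrix(_annotate(records, maps), RegionSpec("full"), scheme)
        assert np.allclose(pim.values, pim.values.T)
        assert np.all(np.diag(pim.values) == 100.0)


class TestClassifyHomology:
    def _stats(self, identity, window_identity):
        from exonevo.align import AlignmentStats

        return AlignmentStats(
            length=100,
            n_identical=int(identity),
            n_similar=int(identity),
            n_gap_columns=0,
            identity_pct=identity,
            similarity_pct=identity,
            gaps_pct=0.0,
            max_window_identity=window_identity,
            window=30,
        )

    def test_full_identity_is_significant(self):
        assert classify_homology(self._stats(100, 100)).status == "significant"

    def test_scattered_low_identity_is_nonsignificant(self):
        call = classify_homology(self._stats(15, 25))
        assert call.status == "nonsignificant"
        assert "identity" in call.reason and "scattered" in call.reason

    def test_concentrated_block_rescues_moderate_identity(self, scheme, rng):
        """25% overall identity in one identical 30aa block is significant."""
        block = random_protein(rng, 30)
        a = block + random_protein(rng, 90)
        b = block + random_protein(rng, 90)
        st = alignment_stats(align_global(a, b, scheme), scheme)
        assert st.identity_pct >= 20.0
        assert st.max_window_identity == 100.0
        assert classify_homology(st).status == "significant"

    def test_monotone_in_both_statistics(self):
        base = classify_homology(self._stats(25, 45))
        assert base.status == "significant"
        for identity, window in [(30, 45), (25, 60), (90, 90)]:
            assert classify_homology(self._stats(identity, window)).status == "significant"


class TestConservationRatio:
    def test_equal_lists_give_100(self):
        assert conservation_ratio([50, 60], [50, 60]).rounded == 100

    def test_direct_arithmetic(self):
        assert conservation_ratio([10], [40]).value == pytest.approx(25.0)

    def test_scale_invariance(self):
        a, b = [24.0, 26.0, 28.0], [91.0, 93.0, 92.0]
        r1 = conservation_ratio(a, b)
        r2 = conservation_ratio([2 * x for x in a], [2 * x for x in b])
        assert r1.value == pytest.approx(r2.value)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            conservation_ratio([10], [0])


class TestRankBySimilarity:
    def test_database_member_query_ranks_itself_first(self, scheme, rng):
        db = [ProteinRecord(f"r{i}", random_protein(rng, 80)) for i in range(5)]
        hits = rank_by_similarity(db[2], db, scheme, include_exons=False)
        assert hits[0].record_id == "r2"
        assert hits[0].identity_pct == 100.0

    def test_extension_carriers_rank_above_noncarriers(self, scheme, rng):
        """Query = a 104aa extension present only in clade A."""
        extension = random_protein(rng, 104)
        db = []
        for i in range(3):  # clade A: carries the extension
            db.append(
                ProteinRecord(
                    f"A{i}", random_protein(rng, 150) + extension + random_protein(rng, 80)
                )
            )
        for i in range(3):  # clade B: no extension
            db.append(ProteinRecord(f"B{i}", random_protein(rng, 334)))
        hits = rank_by_similarity(extension, db, scheme, include_exons=False)
        assert [h.record_id[0] for h in hits] == ["A"] * 3 + ["B"] * 3

    def test_exon_level_hits_recover_carriers(self, scheme, rng):
        """An exon-8-like segment is found exactly in the taxa that carry it."""
        exon8 = random_protein(rng, 40)
        db = []
        carriers = set()
        for i in range(6):
            head, tail = random_protein(rng, 60), random_protein(rng, 60)
            if i % 2 == 0:
                residues = head + exon8 + tail
                intervals = (
                    ExonInterval("7", 0, 60),
                    ExonInterval("8", 60, 100),
                    ExonInterval("9", 100, 160),
                )
                carriers.add(f"r{i}")
            else:
                residues = head + tail
                intervals = (ExonInterval("7", 0, 60), ExonInterval("9", 60, 120))
            db.append(
                (ProteinRecord(f"r{i}", residues), ExonMap(f"r{i}", intervals))
            )
        hits = rank_by_similarity(exon8, db, scheme)
        found = {h.record_id for h in hits if h.region == "8" and h.identity_pct >= 95}
        assert found == carriers

    def test_empty_database_rejected(self, scheme, rng):
        with pytest.raises(ValueError):
            rank_by_similarity(random_protein(rng, 10), [], scheme)


class TestRateIdentityMonotonicity:
    def test_mean_identity_decreases_across_rate_grid(self, scheme):
        """Spearman -1 between per-region rate and mean clade identity."""
        rhos = []
        for seed in range(5):
            config = SimulationConfig(
                tree="(a:0.5,b:0.5,c:0.5,d:0.5)root;",
                architecture=(
                    Region("slow", 120, 0.02),
                    Region("medium", 120, 0.15),
                    Region("fast", 120, 0.60),
                ),
                seed=300 + seed,
            )
            records, maps, _ = simulate_family(config)
            annotated = _annotate(records, maps)
            means = []
            for name in ("slow", "medium", "fast"):
                pim = identity_matrix(annotated, RegionSpec(name, (name,)), scheme)
                mask = ~np.eye(len(pim.labels), dtype=bool)
                means.append(pim.values[mask].mean())
            rhos.append(sps.spearmanr([0.02, 0.15, 0.60], means).statistic)
        assert all(r == pytest.approx(-1.0) for r in rhos)
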