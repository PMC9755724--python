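import numpy as np
import pytest

from exonevo import align_global, alignment_stats
from exonevo.seq_io import validate_annotation
from exonevo.simulate import (
    ExonizationEvent,
    Region,
    SimulationConfig,
    make_preset,
    simulate_family,
    with_seed,
)


def _closed_form_identity(rate, path_length):
    """Expected pairwise identity for the 20-state substitution chain."""
    return 1 / 20 + (19 / 20) * np.exp(-rate * path_length)


class TestDeterminism:
    def test_identical_config_gives_identical_output(self):
        config = make_preset("vertebrate_4a", seed=8)
        r1, m1, t1 = simulate_family(config)
        r2, m2, t2 = simulate_family(config)
        assert r1 == r2
        assert m1 == m2
        assert t1.branch_substitutions == t2.branch_substitutions

    def test_different_seeds_differ(self):
        base = make_preset("vertebrate_4a", seed=8)
        r1, _, _ = simulate_family(base)
        r2, _, _ = simulate_family(with_seed(base, 9))
        assert r1 != r2


class TestZeroRate:
    def test_all_leaves_identical_to_each_other(self, scheme):
        config = SimulationConfig(
            tree="(a:1.0,b:1.0,c:1.0)root;",
            architecture=(Region("R1", 100, 0.0), Region("R2", 50, 0.0)),
            seed=1,
        )
        records, maps, truth = simulate_family(config)
        assert len({r.residues for r in records}) == 1
        st = alignment_stats(
            align_global(records[0], records[1], scheme), scheme
        )
        assert st.identity_pct == 100.0
        assert truth.branch_substitutions == {
            name: {} for name in truth.branch_substitutions
        }


class TestEmittedAnnotations:
    def test_exon_maps_tile_the_emitted_proteins(self):
        records, maps, _ = simulate_family(
            make_preset("primate_4a", seed=3)
        )
        for record in records:
            report = validate_annotation(record, maps[record.record_id])
            assert report.ok and not report.warnings

    def test_region_identity_ordering_follows_rates(self, scheme):
        """MTBD-like > N-terminal-like > insert identity, every replicate."""
        base = SimulationConfig(
            tree="(a:1.0,b:1.0,c:1.0,d:1.0)root;",
            architecture=(
                Region("MTBD", 250, 0.01),
                Region("Nterm", 170, 0.05),
                Region("insert", 251, 0.30),
            ),
            seed=0,
        )
        for seed in range(10):
            records, maps, _ = simulate_family(with_seed(base, seed))
            means = {}
            for name in ("MTBD", "Nterm", "insert"):
                ids = []
                for i in range(len(records)):
                    for j in range(i + 1, len(records)):
                        iv = maps[records[i].record_id][name]
                        jv = maps[records[j].record_id][name]
                        a = records[i].residues[iv.start : iv.end]
                        b = records[j].residues[jv.start : jv.end]
                        ids.append(np.mean([x == y for x, y in zip(a, b)]))
                means[name] = np.mean(ids)
            assert means["MTBD"] > means["Nterm"] > means["insert"]


class TestClosedFormCalibration:
    def test_pairwise_identity_matches_jc20_closed_form(self):
        """Gap-free identity matches 1/20 + (19/20)exp(-2rt) within 3 SE."""
        t = 0.5
        for rate, length in [(0.05, 2000), (0.2, 2000), (0.5, 2000)]:
            config = SimulationConfig(
                tree=f"(x:{t},y:{t})root;",
                architecture=(Region("R", length, rate),),
                seed=int(rate * 1000),
            )
            (rx, ry), _, _ = simulate_family(config)
            observed = np.mean([a == b for a, b in zip(rx.residues, ry.residues)])
            expected = _closed_form_identity(rate, 2 * t)
            se = np.sqrt(expected * (1 - expected) / length)
            assert abs(observed - expected) <= 3 * se


class TestExonization:
    def test_exactly_descendants_carry_the_insert(self):
        config = make_preset("exonization_recovery", seed=21)
        records, maps, truth = simulate_family(config)
        assert truth.carriers["4a"] == {"A", "B"}
        for record in records:
            has_4a = "4a" in maps[record.record_id]
            assert has_4a == (record.record_id in {"A", "B"})

    def test_insert_length_near_configured_mean(self):
        lengths = []
        for seed in range(10):
            config = make_preset("exonization_recovery", seed=seed)
            _, _, truth = simulate_family(config)
            (_, _, length), = truth.events_applied
            lengths.append(length)
        assert abs(np.mean(lengths) - 251) < 10

    def test_independent_inserts_share_no_homology(self, scheme):
        """Two separate exonization events yield noise-floor cross identity."""
        config = SimulationConfig(
            tree="((a:0.1,b:0.1)ab:0.1,(c:0.1,d:0.1)cd:0.1)root;",
            architecture=(Region("L", 150, 0.02), Region("R", 150, 0.02)),
            exonization_events=(
                ExonizationEvent("ab", 251, 5, "L", region_name="ins1"),
                ExonizationEvent("cd", 251, 5, "L", region_name="ins2"),
            ),
            seed=6,
        )
        records, maps, truth = simulate_family(config)
        a = next(r for r in records if r.record_id == "a")
        c = next(r for r in records if r.record_id == "c")
        iv_a, iv_c = maps["a"]["ins1"], maps["c"]["ins2"]
        st = alignment_stats(
            align_global(
                a.residues[iv_a.start : iv_a.end],
                c.residues[iv_c.start : iv_c.end],
                scheme,
            ),
            scheme,
        )
        assert st.identity_pct < 20.0

    def test_unknown_branch_or_region_rejected(self):
        with pytest.raises(ValueError, match="unknown branch"):
            simulate_family(
                SimulationConfig(
                    tree="(a:1,b:1)root;",
                    architecture=(Region("R", 10, 0.1),),
                    exonization_events=(ExonizationEvent("zz", 50, 1, "R"),),
                )
            )
        with pytest.raises(ValueError, match="unknown region"):
            simulate_family(
                SimulationConfig(
                    tree="(a:1,b:1)root;",
                    architecture=(Region("R", 10, 0.1),),
                    exonization_events=(ExonizationEvent("a", 50, 1, "QQ"),),
                )
            )


class TestPresets:
    def test_primate_preset_keeps_big_exon_identity_high(self, scheme):
        from exonevo import RegionSpec, identity_matrix

        records, maps, _ = simulate_family(make_preset("primate_4a"))
        pim = identity_matrix(
            [(r, maps[r.record_id]) for r in records],
            RegionSpec("4a", ("4a",)),
            scheme,
        )
        off = pim.values[~np.eye(len(pim.labels), dtype=bool)]
        assert off.min() > 85.0

    def test_vertebrate_preset_separates_mtbd_from_big_exon(self, scheme):
        from exonevo import RegionSpec, identity_matrix

        records, maps, _ = simulate_family(make_preset("vertebrate_4a"))
        annotated = [(r, maps[r.record_id]) for r in records]
        pim_4a = identity_matrix(annotated, RegionSpec("4a", ("4a",)), scheme)
        pim_mtbd = identity_matrix(annotated, RegionSpec("MTBD", ("MTBD",)), scheme)
        mask = ~np.eye(len(pim_4a.labels), dtype=bool)
        assert pim_4a.values[mask].max() < 30.0
        assert pim_mtbd.values[mask].min() > 70.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="martian"):
            make_preset("martian")
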