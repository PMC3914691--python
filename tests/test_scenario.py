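"""Karyotype event engine: dominance algebra, centromere bookkeeping,
rule-based scenario validation and event-ledger accounting."""

import numpy as np
import pytest

from paleograss.core import EvolutionEvent
from paleograss.scenario import (
    EventLedger,
    KChrom,
    ProtoKaryotype,
    ScenarioError,
    apply_event,
    build_event_ledger,
    load_fixture_scenarios,
    score_scenarios,
    validate_scenario,
)


def kary(*chroms):
    return ProtoKaryotype([KChrom(n, [d]) for n, d in chroms])


def ev(kind, **operands):
    return EvolutionEvent(kind, "ancestral", 0.0, operands)


class TestApplyEvent:
    def test_fusion_d_plus_s_gives_d_with_segments(self):
        k = apply_event(kary(("X", "D"), ("Y", "S")), ev("CCF", chroms=["X", "Y"], name="Z"))
        z = k.get("Z")
        assert z.dominance == "D"
        assert z.segments == ["D", "S"]

    def test_fusion_d_plus_d_supradominant(self):
        k = apply_event(kary(("X", "D"), ("Y", "D")), ev("TCF", chroms=["X", "Y"], name="Z"))
        assert k.get("Z").dominance == "D"
        assert k.get("Z").segments == ["D", "D"]

    def test_fusion_s_plus_s_stays_sensitive(self):
        k = apply_event(kary(("X", "S"), ("Y", "S")), ev("CCF", chroms=["X", "Y"], name="Z"))
        assert k.get("Z").dominance == "S"

    def test_fusion_keeps_one_functional_centromere(self):
        k = apply_event(kary(("X", "D"), ("Y", "S")), ev("CCF", chroms=["X", "Y"], name="Z"))
        assert k.get("Z").centromere_functional

    def test_centromeric_fission_inactivates_both_products(self):
        k = apply_event(
            kary(("X", "D")), ev("fission", chrom="X", products=["X1", "X2"], mode="centromeric")
        )
        assert not k.get("X1").centromere_functional
        assert not k.get("X2").centromere_functional

    def test_arm_fission_keeps_parent_centromere(self):
        k = apply_event(kary(("X", "S")), ev("fission", chrom="X", products=["X", "Xf"], mode="arm"))
        assert k.get("X").centromere_functional
        assert not k.get("Xf").centromere_functional

    def test_self_fusion_rejected(self):
        with pytest.raises(ScenarioError):
            apply_event(kary(("X", "D")), ev("CCF", chroms=["X", "X"], name="Z"))

    def test_absent_chromosome_rejected(self):
        with pytest.raises(ScenarioError):
            apply_event(kary(("X", "D")), ev("fission", chrom="Q"))

    def test_wgd_from_sensitive_parent_flags_dominant_child(self):
        viol = {}
        apply_event(
            kary(("X", "S")),
            ev("WGD", copies={"X": [["X", "S"], ["Y", "D"]]}),
            violations=viol,
        )
        assert ("R-c", "Y") in viol

    def test_chromosome_count_bookkeeping(self):
        k = kary(("A", "D"), ("B", "D"))
        k = apply_event(k, ev("WGD", copies={
            "A": [["A", "D"], ["A'", "S"]], "B": [["B", "D"], ["B'", "S"]]}))
        assert len(k.chromosomes) == 4
        k = apply_event(k, ev("CCF", chroms=["A", "B"], name="AB"))
        assert len(k.chromosomes) == 3
        k = apply_event(k, ev("fission", chrom="AB", products=["A1", "A2"]))
        assert len(k.chromosomes) == 4  # n0 + WGD - fusions + fissions

    def test_no_event_sequence_recovers_dominance(self):
        # random event sequences never map an ever-sensitive chromosome to D
        rng = np.random.default_rng(55)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            k = ProtoKaryotype([KChrom(f"C{i}", [rng.choice(["D", "S"])]) for i in range(n)])
            ever_s = {c.name for c in k.chromosomes if c.dominance == "S"}
            fusion_counter = 0
            for _ in range(int(rng.integers(1, 9))):
                names = k.names()
                if len(names) < 2:
                    break
                kind = rng.choice(["CCF", "TCF", "fission"])
                if kind == "fission":
                    tgt = str(rng.choice(names))
                    k = apply_event(k, ev("fission", chrom=tgt, products=[f"{tgt}a", f"{tgt}b"]))
                else:
                    i, j = rng.choice(len(names), 2, replace=False)
                    fusion_counter += 1
                    k = apply_event(
                        k, ev(kind, chroms=[names[int(i)], names[int(j)]], name=f"F{fusion_counter}_{i}_{j}")
                    )
            for c in k.chromosomes:
                assert c.dominance in ("D", "S")
                if c.ever_sensitive and not any(s == "D" for s in c.segments):
                    assert c.dominance == "S"


class TestLedger:
    def test_printed_large_scale_totals(self):
        events = {
            "rice": [{"kind": "gene_movement", "count": 177}],
            "brachypodium": [
                {"kind": "CCF", "count": 7},
                {"kind": "CI", "count": 6},
                {"kind": "gene_movement", "count": 82},
            ],
            "sorghum": [
                {"kind": "CCF", "count": 2},
                {"kind": "CI", "count": 5},
                {"kind": "gene_movement", "count": 135},
            ],
            "maize": [
                {"kind": "CCF", "count": 7},
                {"kind": "TCF", "count": 10},
                {"kind": "CI", "count": 34},
                {"kind": "gene_movement", "count": 1673},
            ],
        }
        ledger = build_event_ledger(events)
        assert ledger.total("CCF") == 16
        assert ledger.total("TCF") == 10
        assert ledger.total("CI") == 45
        assert ledger.large_scale_total == 71
        assert ledger.gene_movement_total == 2067

    def test_totals_equal_per_lineage_sums(self):
        ledger = build_event_ledger({"a": [{"kind": "CI", "count": 3}], "b": [{"kind": "CI", "count": 4}]})
        assert ledger.total("CI") == sum(per["CI"] for per in ledger.counts.values())

    def test_empty_events_all_zero(self):
        ledger = build_event_ledger({"a": []})
        assert ledger.large_scale_total == 0 and ledger.gene_movement_total == 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ScenarioError):
            build_event_ledger({"a": [{"kind": "teleportation"}]})

    def test_simulator_events_accepted(self):
        evs = [
            EvolutionEvent("inversion", "rice", 10.0, {}),
            EvolutionEvent("transposition", "rice", 9.0, {"size": 3}),
        ]
        ledger = build_event_ledger({"rice": evs})
        assert ledger.total("CI") == 1
        assert ledger.gene_movement_total == 3


@pytest.fixture(scope="module")
def ranked():
    fixtures, observed = load_fixture_scenarios()
    return score_scenarios(fixtures, observed)


class TestScenarios:
    def test_n7_scenario_accepted_with_one_fission_two_fusions(self, ranked):
        best = ranked[0]
        assert best.scenario_id == "scenario3_n7"
        assert best.violations == [] and best.structural_errors == []
        assert best.ledger.total("fission") == 1
        assert best.ledger.total("CCF") + best.ledger.total("TCF") == 2
        assert best.parsimony_score == 3

    def test_n5_scenario1_sensitive_ancestor_violation(self, ranked):
        ev1 = next(e for e in ranked if e.scenario_id == "scenario1_n5")
        assert any(rule == "R-c" for rule, _ in ev1.violations)
        assert ev1.parsimony_score == 8  # five fissions + three fusions

    def test_n5_scenario2_centromere_violation(self, ranked):
        ev2 = next(e for e in ranked if e.scenario_id == "scenario2_n5")
        rules = {rule for rule, _ in ev2.violations}
        assert "R-a" in rules
        msgs = " ".join(m for _, m in ev2.violations)
        assert "A7" in msgs and "A10" in msgs

    def test_n6_scenarios_rejected(self, ranked):
        for sid in ("scenario4_n6", "scenario5_n6"):
            e = next(x for x in ranked if x.scenario_id == sid)
            assert len(e.violations) >= 1

    def test_stable_tie_preserves_input_order(self):
        fixtures, observed = load_fixture_scenarios()
        sid, anc, evs = fixtures[2]  # the accepted n=7 candidate
        dup = [("first", anc, evs), ("second", anc, evs)]
        ranked = score_scenarios(dup, observed)
        assert [e.scenario_id for e in ranked] == ["first", "second"]

    def test_chromosome_count_mismatch_is_structural(self):
        fixtures, observed = load_fixture_scenarios()
        sid, anc, evs = fixtures[2]
        evaluation = validate_scenario(anc, evs[:2], observed, "truncated")
        assert evaluation.structural_errors
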