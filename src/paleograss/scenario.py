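"""Karyotype-evolution rules, scenario validation and event accounting.

Candidate ancestral karyotypes are evaluated against five evolutionary
rules: (1) a WGD splits every chromosome pair into one dominant (D) and
one sensitive (S) copy; (2) dominance bias shows up as deletion and
shuffling from S blocks (tested upstream); (3) shuffling mechanisms are
outside this engine's scope; (4) modern chromosomes arise through fusions
that leave exactly one functional centromere (functional monocentric
neochromosomes); (5) fusion dominance follows the algebra
D + D = D (supradominant), D + S = D, S + S = S, and a chromosome that was
ever sensitive can never recover dominance.

``validate_scenario`` replays a candidate's event list from its ancestor
and collects rule violations against the observed post-WGD karyotype:

* ``R-a`` - a terminal chromosome lacks a functional centromere;
* ``R-b`` - dominance algebra broken (S+S giving D, D+D giving S, or a WGD
  pair not labelled one D / one S);
* ``R-c`` - an ancestrally sensitive chromosome observed as dominant;
* ``R-d`` - terminal dominance / segment composition contradicting the
  observed labels.

Scenarios are ranked by (violations, parsimony = fissions + fusions,
ancestor chromosome count descending).
"""

from __future__ import annotations

import copy
import json
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .core import EvolutionEvent


class ScenarioError(ValueError):
    pass


@dataclass
class KChrom:
    name: str
    segments: list[str]  # per-segment dominance, ordered
    centromere_functional: bool = True
    ever_sensitive: bool = False

    @property
    def dominance(self) -> str:
        """Fusion algebra folded over segments: any D segment dominates."""
        return "D" if "D" in self.segments else "S"


@dataclass
class ProtoKaryotype:
    chromosomes: list[KChrom] = field(default_factory=list)

    def get(self, name: str) -> KChrom:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ScenarioError(f"event references absent chromosome {name!r}")

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


@dataclass
class EventLedger:
    counts: dict = field(default_factory=lambda: defaultdict(lambda: defaultdict(int)))

    KINDS = ("CCF", "TCF", "CI", "translocation", "gene_movement", "fission")

    def add(self, lineage: str, kind: str, n: int = 1) -> None:
        if kind not in self.KINDS:
            raise ScenarioError(f"unknown ledger event kind {kind!r}")
        self.counts[lineage][kind] += n

    def total(self, kind: str) -> int:
        return sum(per[kind] for per in self.counts.values())

    @property
    def large_scale_total(self) -> int:
        return self.total("CCF") + self.total("TCF") + self.total("CI")

    @property
    def gene_movement_total(self) -> int:
        return self.total("gene_movement")

    def as_dict(self) -> dict:
        out = {lin: dict(per) for lin, per in self.counts.items()}
        out["totals"] = {k: self.total(k) for k in self.KINDS}
        out["totals"]["large_scale"] = self.large_scale_total
        return out


@dataclass
class ScenarioEvaluation:
    scenario_id: str
    violations: list[tuple[str, str]]
    ledger: EventLedger
    parsimony_score: int
    structural_errors: list[str]
    final: ProtoKaryotype
    ancestor_n: int

    @property
    def accepted(self) -> bool:
        return not self.violations and not self.structural_errors


_KIND_ALIASES = {"inversion": "CI", "transposition": "gene_movement", "gene_movement": "gene_movement"}


def apply_event(
    karyotype: ProtoKaryotype,
    event: EvolutionEvent,
    violations: Optional[dict] = None,
) -> ProtoKaryotype:
    """Apply one karyotype event, enforcing centromere and dominance rules.

    Returns a new karyotype; ``violations`` (when given) collects rule
    breaches keyed by (rule, subject) so each fires once.
    """
    k = copy.deepcopy(karyotype)
    op = event.operands
    viol = violations if violations is not None else {}

    if event.kind == "WGD":
        new_chroms: list[KChrom] = []
        for chrom in list(k.chromosomes):
            spec = op.get("copies", {}).get(chrom.name)
            if spec is None:
                spec = [[chrom.name, "D"], [f"{chrom.name}'", "S"]]
            (n1, d1), (n2, d2) = spec
            if {d1, d2} != {"D", "S"}:
                viol.setdefault(("R-b", chrom.name), f"WGD of {chrom.name} labelled {d1}/{d2}, not one D one S")
            for nm, dom in ((n1, d1), (n2, d2)):
                ever_s = chrom.ever_sensitive or chrom.dominance == "S" or dom == "S"
                if (chrom.ever_sensitive or chrom.dominance == "S") and dom == "D":
                    viol.setdefault(
                        ("R-c", nm),
                        f"sensitive ancestor {chrom.name} cannot produce dominant {nm}",
                    )
                new_chroms.append(
                    KChrom(nm, [dom] * max(1, len(chrom.segments)), chrom.centromere_functional, ever_s)
                )
        k.chromosomes = new_chroms
        return k

    if event.kind in ("CCF", "TCF"):
        a_name, b_name = op["chroms"]
        if a_name == b_name:
            raise ScenarioError("cannot fuse a chromosome with itself")
        a, b = k.get(a_name), k.get(b_name)
        result_dom = "D" if "D" in (a.dominance, b.dominance) else "S"
        declared = op.get("result_dominance")
        if declared is not None and declared != result_dom:
            viol.setdefault(
                ("R-b", op.get("name", a_name)),
                f"fusion {a.dominance}+{b.dominance} declared {declared}, algebra gives {result_dom}",
            )
        merged = KChrom(
            op.get("name", f"{a_name}+{b_name}"),
            a.segments + b.segments,
            a.centromere_functional or b.centromere_functional,
            a.ever_sensitive or b.ever_sensitive if result_dom == "S" else (a.ever_sensitive and b.ever_sensitive),
        )
        k.chromosomes = [c for c in k.chromosomes if c.name not in (a_name, b_name)]
        k.chromosomes.append(merged)
        return k

    if event.kind == "fission":
        chrom = k.get(op["chrom"])
        n1, n2 = op.get("products", (f"{chrom.name}a", f"{chrom.name}b"))
        mode = op.get("mode", "centromeric")
        at = op.get("at", max(1, len(chrom.segments) // 2))
        if not 0 < at <= len(chrom.segments) or (at == len(chrom.segments) and len(chrom.segments) > 1):
            at = max(1, min(at, len(chrom.segments)))
        seg1, seg2 = chrom.segments[:at], chrom.segments[at:] or [chrom.segments[-1]]
        if mode == "centromeric":
            f1 = f2 = False  # a centromeric break leaves partial, nonfunctional centromeres
        else:
            f1, f2 = chrom.centromere_functional, False  # arm break: acentric fragment
        p1 = KChrom(n1, seg1, f1, chrom.ever_sensitive)
        p2 = KChrom(n2, seg2, f2, chrom.ever_sensitive)
        k.chromosomes = [c for c in k.chromosomes if c.name != chrom.name] + [p1, p2]
        return k

    if event.kind == "translocation":
        frag = k.get(op["frag"])
        target = k.get(op["to"])
        # a gene-scale fragment is absorbed without changing segment structure
        k.chromosomes = [c for c in k.chromosomes if c.name != frag.name]
        if frag.dominance == "S":
            target.ever_sensitive = target.ever_sensitive  # fragment cannot sensitize a chromosome
        return k

    if event.kind in ("inversion", "transposition"):
        return k  # intra-chromosomal: no karyotype-level change

    raise ScenarioError(f"event kind {event.kind!r} not applicable to a karyotype")


def build_event_ledger(events_by_lineage: Mapping[str, Iterable]) -> EventLedger:
    """Count events per lineage and kind.

    Accepts :class:`EvolutionEvent` objects or ``{"kind": ..., "count": ...}``
    dicts; simulator kinds are mapped onto ledger kinds (inversion -> CI,
    transposition -> gene_movement); other simulator-only kinds (deletion,
    tandem duplication, segmental deletion, WGD) are not rearrangement ledger
    entries and are skipped.
    """
    ledger = EventLedger()
    skip = {"deletion", "tandem_duplication", "segmental_deletion", "WGD"}
    for lineage in sorted(events_by_lineage):
        ledger.counts[lineage]  # materialise lineage even if empty
        for ev in events_by_lineage[lineage]:
            if isinstance(ev, EvolutionEvent):
                kind, count = ev.kind, ev.operands.get("count", ev.operands.get("size", 1))
            else:
                kind, count = ev["kind"], ev.get("count", 1)
            if kind in skip:
                continue
            kind = _KIND_ALIASES.get(kind, kind)
            if kind == "gene_movement":
                ledger.add(lineage, kind, int(count))
            else:
                ledger.add(lineage, kind, 1 if isinstance(ev, EvolutionEvent) else int(count))
    return ledger


def validate_scenario(
    ancestor: ProtoKaryotype,
    events: Sequence[EvolutionEvent],
    observed: Mapping[str, Mapping],
    scenario_id: str = "scenario",
) -> ScenarioEvaluation:
    """Replay ``events`` from ``ancestor`` and test the result against the
    observed post-WGD karyotype (name -> {dominance, segments?,
    centromere_functional})."""
    viol: dict[tuple[str, str], str] = {}
    k = copy.deepcopy(ancestor)
    ledger = EventLedger()
    for ev in events:
        k = apply_event(k, ev, viol)
        kind = _KIND_ALIASES.get(ev.kind, ev.kind)
        if kind in EventLedger.KINDS:
            ledger.add(ev.lineage, kind, int(ev.operands.get("count", 1)) if kind == "gene_movement" else 1)

    structural: list[str] = []
    if len(k.chromosomes) != len(observed):
        structural.append(
            f"chromosome count mismatch: produced {len(k.chromosomes)}, observed {len(observed)}"
        )
    for chrom in k.chromosomes:
        obs = observed.get(chrom.name)
        if obs is None:
            structural.append(f"produced chromosome {chrom.name} not in observed karyotype")
            continue
        if not chrom.centromere_functional:
            viol.setdefault(("R-a", chrom.name), f"{chrom.name} lacks a functional centromere")
        if obs.get("centromere_functional", True) != chrom.centromere_functional and chrom.centromere_functional:
            viol.setdefault(("R-d", chrom.name), f"{chrom.name} centromere state contradicts observation")
        if chrom.ever_sensitive and obs["dominance"] == "D":
            viol.setdefault(("R-c", chrom.name), f"ancestrally sensitive {chrom.name} observed dominant")
        if chrom.dominance != obs["dominance"]:
            viol.setdefault(
                ("R-d", chrom.name),
                f"{chrom.name} produced {chrom.dominance}, observed {obs['dominance']}",
            )
        obs_seg = obs.get("segments")
        if obs_seg is not None and sorted(obs_seg) != sorted(chrom.segments):
            viol.setdefault(
                ("R-d", f"{chrom.name}/segments"),
                f"{chrom.name} segments {chrom.segments} vs observed {obs_seg}",
            )
    parsimony = ledger.total("fission") + ledger.total("CCF") + ledger.total("TCF")
    violations = sorted((rule, msg) for (rule, _), msg in viol.items())
    return ScenarioEvaluation(scenario_id, violations, ledger, parsimony, structural, k, len(ancestor.chromosomes))


def score_scenarios(
    candidates: Sequence[tuple[str, ProtoKaryotype, Sequence[EvolutionEvent]]],
    observed: Mapping[str, Mapping],
) -> list[ScenarioEvaluation]:
    """Evaluate and rank candidate scenarios.

    Sort key: violation count ascending, parsimony ascending, ancestor
    chromosome count descending; ties keep input order (stable sort).
    """
    if not candidates:
        raise ScenarioError("no candidate scenarios")
    evals = [validate_scenario(anc, evs, observed, sid) for sid, anc, evs in candidates]
    evals.sort(key=lambda e: (len(e.violations) + len(e.structural_errors), e.parsimony_score, -e.ancestor_n))
    return evals


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture_scenarios() -> tuple[list[tuple[str, ProtoKaryotype, list[EvolutionEvent]]], dict]:
    """Load the five packaged candidate scenarios (n = 5/5/7/6/6 ancestors)
    and the observed post-WGD karyotype they are judged against."""
    text = resources.files("paleograss").joinpath("fixtures/scenarios.json").read_text()
    data = json.loads(text)
    observed = data["observed"]
    out = []
    for sc in data["scenarios"]:
        ancestor = ProtoKaryotype(
            [KChrom(c["name"], list(c.get("segments", [c.get("dominance", "D")]))) for c in sc["ancestor"]]
        )
        events = [
            EvolutionEvent(e["kind"], e.get("lineage", "ancestral"), float(e.get("time", 0.0)), e.get("operands", {}))
            for e in sc["events"]
        ]
        out.append((sc["id"], ancestor, events))
    return out, observed
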