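"""Classifier for three biomolecule-preservation scenarios.

Three mechanisms can explain how DNA persists in sediments for centuries
despite the lability of free DNA:

a. **adsorption/complexation** — extracellular DNA is sheltered by
   electrostatic adsorption to mineral surfaces or complexation with
   organic/inorganic substances.  DNA of different source organisms is
   chemically equivalent, so under this mechanism DNA decay constants
   should be indistinguishable across organism groups.
b. **chemical reactivity** — each compound degrades according to its own
   intrinsic chemistry.  DNA is more reactive than resistant cell-wall
   compounds, so within a group DNA should decay significantly faster
   than the group's degradation-resistant biomarkers.
c. **biotic exclusion (physical shielding)** — DNA enclosed in resistant
   cellular structures (e.g. algaenan-containing cell walls, lignified
   tissue) is physically protected and decays in step with the shielding
   compound: within-group DNA and resistant-compound decay constants are
   indistinguishable while DNA decay still differs between groups.

The classifier turns this narrative framework into an explicit ordered
decision rule over Wilcoxon rank-sum contrasts of fitted decay constants.
The rule order, the significance level, and the use of failure-to-reject
as "similar" are operational choices documented in the methods note; with
fewer than 4 decay constants per group, non-rejection is weak evidence and
the call is flagged as low-power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .stats import wilcoxon_rank_sum

SCENARIOS = (
    "adsorption_complexation",
    "chemical_reactivity",
    "biotic_exclusion",
    "indeterminate",
)


@dataclass
class ScenarioCall:
    """The preservation scenario best supported for one organism group."""

    organism_group: str
    scenario: str
    alpha: float = 0.05
    evidence: list[dict] = field(default_factory=list)
    reason: str = ""
    low_power: bool = False


def classify_group(organism_group: str, k_dna, k_resistant,
                   k_dna_other_groups: dict, alpha: float = 0.05,
                   seed: int | None = None) -> ScenarioCall:
    """Decide the preservation scenario for one organism group.

    Parameters
    ----------
    k_dna : decay constants of the group's DNA marker (one per station or
        lake; >= 2 required).
    k_resistant : decay constants of the group's degradation-resistant
        compound (lipid biomarker or macromolecule); may be empty/None,
        in which case the call is indeterminate.
    k_dna_other_groups : mapping of other organism groups to their DNA
        decay-constant lists.
    alpha : significance level of each Wilcoxon contrast.

    Decision rule, in order:

    i.   all cross-group DNA contrasts nonsignificant → DNA behaves
         identically regardless of source → ``adsorption_complexation``;
    ii.  within-group DNA decays significantly *faster* than the resistant
         compound → ``chemical_reactivity``;
    iii. within-group DNA indistinguishable from the resistant compound
         while cross-group DNA differs → ``biotic_exclusion``;
    iv.  otherwise (e.g. DNA significantly slower than the resistant
         compound) → ``indeterminate``.
    """
    k_dna = list(np.asarray(k_dna, dtype=float))
    if len(k_dna) < 2:
        raise ValueError("need >= 2 DNA decay constants")
    evidence: list[dict] = []
    sizes = [len(k_dna)] + [len(v) for v in k_dna_other_groups.values()]

    cross_significant = False
    for other, ks in k_dna_other_groups.items():
        if len(ks) < 2:
            raise ValueError(f"group {other!r} needs >= 2 decay constants")
        res = wilcoxon_rank_sum(k_dna, ks, seed=seed, alpha=alpha)
        evidence.append({
            "contrast": f"DNA[{organism_group}] vs DNA[{other}]",
            "statistic": res.statistic, "p_value": res.p_value,
            "significant": res.significant,
        })
        cross_significant = cross_significant or res.significant

    if not cross_significant:
        return ScenarioCall(
            organism_group, "adsorption_complexation", alpha, evidence,
            reason="DNA decay constants indistinguishable across organism groups",
            low_power=min(sizes) < 4,
        )

    if k_resistant is None or len(k_resistant) == 0:
        return ScenarioCall(
            organism_group, "indeterminate", alpha, evidence,
            reason="no resistant-compound decay constants available",
            low_power=min(sizes) < 4,
        )
    k_resistant = list(np.asarray(k_resistant, dtype=float))
    if len(k_resistant) < 2:
        return ScenarioCall(
            organism_group, "indeterminate", alpha, evidence,
            reason="fewer than 2 resistant-compound decay constants",
            low_power=True,
        )
    sizes.append(len(k_resistant))
    res = wilcoxon_rank_sum(k_dna, k_resistant, seed=seed, alpha=alpha)
    dna_faster = float(np.mean(k_dna)) > float(np.mean(k_resistant))
    evidence.append({
        "contrast": f"DNA[{organism_group}] vs resistant[{organism_group}]",
        "statistic": res.statistic, "p_value": res.p_value,
        "significant": res.significant,
    })
    low_power = min(sizes) < 4

    if res.significant and dna_faster:
        return ScenarioCall(
            organism_group, "chemical_reactivity", alpha, evidence,
            reason="DNA decays significantly faster than the group's "
                   "resistant compound", low_power=low_power)
    if not res.significant:
        return ScenarioCall(
            organism_group, "biotic_exclusion", alpha, evidence,
            reason="DNA decay indistinguishable from the group's resistant "
                   "compound while differing across groups",
            low_power=low_power)
    return ScenarioCall(
        organism_group, "indeterminate", alpha, evidence,
        reason="DNA decays significantly more slowly than the resistant "
               "compound; no scenario fits", low_power=low_power)


REPORT_SCHEMA = {
    "type": "object",
    "required": ["alpha", "scenarios"],
    "properties": {
        "alpha": {"type": "number"},
        "scenarios": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["organism_group", "scenario", "evidence",
                             "reason", "low_power"],
            },
        },
    },
}


def scenario_report(calls: list[ScenarioCall]) -> tuple[dict, str]:
    """Machine-readable (JSON-able dict) plus human-readable report."""
    if not calls:
        raise ValueError("need at least one scenario call")
    payload = {
        "alpha": calls[0].alpha,
        "scenarios": [asdict(c) for c in calls],
    }
    lines = ["Preservation scenario calls", "=" * 27]
    for c in calls:
        lines.append(f"\n{c.organism_group}: {c.scenario}"
                     + (" [low power]" if c.low_power else ""))
        lines.append(f"  rationale: {c.reason}")
        for e in c.evidence:
            star = "*" if e["significant"] else " "
            lines.append(f"  {star} {e['contrast']}: W={e['statistic']:.3g}, "
                         f"p={e['p_value']:.4g}")
    return payload, "\n".join(lines)


def validate_report(payload: dict) -> bool:
    """Check a report dict against the documented schema (JSON-able too)."""
    json.dumps(payload)
    if set(REPORT_SCHEMA["required"]) - set(payload):
        return False
    for call in payload["scenarios"]:
        req = REPORT_SCHEMA["properties"]["scenarios"]["items"]["required"]
        if set(req) - set(call):
            return False
        if call["scenario"] not in SCENARIOS:
            return False
    return True
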