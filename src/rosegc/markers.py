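"""Enantiomeric/diastereomeric excess and rose-oil authenticity markers.

The excess of a two-member stereoisomer group is computed from peak areas as

    EE = (PA_major − PA_minor) / (PA_major + PA_minor)

reported unsigned in [0, 1] together with the identity of the major isomer
(taken from library elution rank).  Marker rules translate the observed
patterns into per-marker verdicts: authentic *R. damascena* oil shows a
dominant (−)-rose oxide, a single citronellyl acetate enantiomer and a
single β-damascenone diastereomer, while *P. graveolens* adulterant shows a
slight (+)-rose-oxide excess and both isomers of the other two groups.
Verdicts express consistency with these patterns, never species identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import QuantResult
from .io import AnalyteLibrary, PeakTable

__all__ = [
    "EnantiomerPair",
    "MarkerFinding",
    "MarkerReport",
    "DEFAULT_MARKER_RULES",
    "pair_isomers",
    "enantiomeric_excess",
    "marker_report",
]


@dataclass
class EnantiomerPair:
    """Peak areas of a two-member enantiomer/diastereomer group."""

    group: str
    pa_first: float  # area of the first-eluting isomer
    pa_second: float
    first_name: str = ""
    second_name: str = ""

    @property
    def total(self) -> float:
        return self.pa_first + self.pa_second

    @property
    def pa_major(self) -> float:
        return max(self.pa_first, self.pa_second)

    @property
    def pa_minor(self) -> float:
        return min(self.pa_first, self.pa_second)

    @property
    def major_identity(self) -> str:
        if self.pa_first >= self.pa_second:
            return self.first_name or f"{self.group} (isomer 1)"
        return self.second_name or f"{self.group} (isomer 2)"

    @property
    def major_rank(self) -> int:
        return 1 if self.pa_first >= self.pa_second else 2


def pair_isomers(peak_table: PeakTable, library: AnalyteLibrary) -> list[EnantiomerPair]:
    """Collect both members of every stereoisomer group from an assigned table.

    A member without an assigned peak contributes zero area.  Groups with more
    than two library members are rejected (all groups of this method are
    binary).
    """
    column = peak_table.metadata.get("column_id")
    if column is None:
        raise ValueError("peak table metadata lacks 'column_id'")
    pairs: list[EnantiomerPair] = []
    for group, members in sorted(library.groups(column).items()):
        if len(members) != 2:
            raise ValueError(
                f"group {group!r} has {len(members)} members; only binary groups supported"
            )
        first, second = members
        p1 = peak_table.get(first.name)
        p2 = peak_table.get(second.name)
        pairs.append(
            EnantiomerPair(
                group=group,
                pa_first=p1.area if p1 is not None else 0.0,
                pa_second=p2.area if p2 is not None else 0.0,
                first_name=first.name,
                second_name=second.name,
            )
        )
    return pairs


def enantiomeric_excess(pair: EnantiomerPair) -> float:
    """EE/DE = (PA_major − PA_minor)/(PA_major + PA_minor), in [0, 1].

    Undefined (rejected) when both areas are zero — an absent group is
    indeterminate, not racemic.
    """
    if pair.total <= 0:
        raise ValueError(f"group {pair.group!r}: both isomer areas are zero; EE undefined")
    return (pair.pa_major - pair.pa_minor) / pair.total


#: Default marker rules.  The method's own qualitative observations carry no
#: numeric cut-offs, so the thresholds are configuration, not claims:
#: EE >= single_isomer_min_ee reads as "only one isomer present",
#: EE <= both_present_max_ee as "both isomers present".
DEFAULT_MARKER_RULES: dict = {
    "rose_oxide": {"expected_major_rank": 2},  # (−)-rose oxide elutes second
    "citronellyl_acetate": {"single_isomer_min_ee": 0.98, "both_present_max_ee": 0.90},
    "beta_damascenone": {"single_isomer_min_ee": 0.98, "both_present_max_ee": 0.90},
}

CONSISTENT = "consistent_with_r_damascena"
ADULTERATION = "suggests_adulteration"
INDETERMINATE = "indeterminate"


@dataclass
class MarkerFinding:
    group: str
    verdict: str
    ee: float | None = None
    major_identity: str | None = None
    note: str = ""


@dataclass
class MarkerReport:
    findings: dict[str, MarkerFinding] = field(default_factory=dict)
    citronellol_geraniol_ratio: float | None = None

    @property
    def overall(self) -> str:
        verdicts = [f.verdict for f in self.findings.values()]
        if any(v == ADULTERATION for v in verdicts):
            return ADULTERATION
        if verdicts and all(v == CONSISTENT for v in verdicts):
            return CONSISTENT
        return INDETERMINATE


def _gate(pair: EnantiomerPair, quant_results: list[QuantResult] | None) -> str | None:
    """Return a blocking note when the group's quantification is below LoQ."""
    if quant_results is None:
        return None
    members = {pair.first_name, pair.second_name}
    relevant = [r for r in quant_results if r.analyte in members]
    if not relevant:
        return f"no quantification available for {pair.group}"
    if all(r.flag == "below_loq" for r in relevant):
        return f"{pair.group} below LoQ"
    return None


def marker_report(
    pairs: list[EnantiomerPair],
    quant_results: list[QuantResult] | None = None,
    rules: dict | None = None,
) -> MarkerReport:
    """Evaluate authenticity markers from stereoisomer pairs.

    When *quant_results* are supplied, a marker whose underlying peaks were
    not quantifiable (below LoQ) is reported indeterminate rather than judged
    from noise-level areas.  The citronellol/geraniol concentration ratio is
    attached when both quantifications are present.
    """
    rules = DEFAULT_MARKER_RULES if rules is None else rules
    by_group = {p.group: p for p in pairs}
    report = MarkerReport()

    for group, rule in rules.items():
        pair = by_group.get(group)
        blocked = _gate(pair, quant_results) if pair is not None else None
        if pair is None or pair.total <= 0 or blocked:
            report.findings[group] = MarkerFinding(
                group, INDETERMINATE, note=blocked or "no isomer peaks detected"
            )
            continue
        ee = enantiomeric_excess(pair)
        finding = MarkerFinding(group, INDETERMINATE, ee=ee, major_identity=pair.major_identity)
        if "expected_major_rank" in rule:
            if pair.major_rank == rule["expected_major_rank"]:
                finding.verdict = CONSISTENT
            else:
                finding.verdict = ADULTERATION
                finding.note = f"major isomer is {pair.major_identity}"
        else:
            if ee >= rule["single_isomer_min_ee"]:
                finding.verdict = CONSISTENT
            elif ee <= rule["both_present_max_ee"]:
                finding.verdict = ADULTERATION
                finding.note = "both isomers present"
            else:
                finding.note = "excess between configured thresholds"
        report.findings[group] = finding

    if quant_results is not None:
        conc = {r.analyte: r.concentration for r in quant_results if r.concentration}
        citronellol = sum(v for k, v in conc.items() if "citronellol" in k and "acetate" not in k)
        geraniol = sum(v for k, v in conc.items() if k == "geraniol")
        if citronellol and geraniol:
            report.citronellol_geraniol_ratio = citronellol / geraniol
    return report
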