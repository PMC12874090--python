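"""Conserved-residue curation of HMM hits.

Residue rules are anchored to 1-based positions in a named ungapped
reference sequence and mapped onto candidates through one global
alignment; a gap at a rule position fails the rule, so fragments cannot
pass.  Pattern rules (the twin ferredoxin-type cysteine cluster of hgcB)
are counted on the raw candidate sequence with greedy non-overlapping
left-to-right matching.  Rules ship as an editable TSV so real anchor
sequences can replace synthetic ones without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from hgscan.core_align import (
    GAP,
    AlignParams,
    Alignment,
    ProteinRecord,
    global_align,
)
from hgscan.errors import InputError
from hgscan.profile_hmm import FAMILIES, HmmHit


@dataclass(frozen=True)
class ResidueRule:
    family: str
    reference_id: str
    position: int  # 1-based index into the ungapped reference
    allowed: frozenset[str]
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError(f"rule {self.label}: position must be >= 1")
        if not self.allowed:
            raise InputError(f"rule {self.label}: empty allowed set")


@dataclass(frozen=True)
class PatternRule:
    family: str
    pattern: str  # template like "CX2CX2CX3C"
    min_count: int
    label: str

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise InputError(f"rule {self.label}: min_count must be >= 1")

    def regex(self) -> re.Pattern[str]:
        return re.compile(_template_to_regex(self.pattern))


@dataclass(frozen=True)
class FamilyRules:
    residue_rules: tuple[ResidueRule, ...]
    pattern_rules: tuple[PatternRule, ...]
    reference_id: str | None


@dataclass(frozen=True)
class RuleSet:
    families: dict[str, FamilyRules] = field(default_factory=dict)

    def __getitem__(self, family: str) -> FamilyRules:
        return self.families[family]

    def __contains__(self, family: str) -> bool:
        return family in self.families


@dataclass(frozen=True)
class ValidationResult:
    record_id: str
    sample_id: str
    family: str
    passed: bool
    failed_rules: tuple[str, ...]
    positions_checked: tuple[tuple[str, str], ...]  # (rule label, residue or '-')


def _template_to_regex(template: str) -> str:
    """'CX2CX2CX3C' -> 'C..C..C...C' (Xn = n arbitrary residues)."""
    out: list[str] = []
    i = 0
    while i < len(template):
        ch = template[i]
        if ch == "X":
            i += 1
            digits = ""
            while i < len(template) and template[i].isdigit():
                digits += template[i]
                i += 1
            out.append("." * (int(digits) if digits else 1))
        elif ch.isalpha():
            out.append(re.escape(ch))
            i += 1
        else:
            raise InputError(f"bad pattern template {template!r}")
    return "".join(out)


def load_rules(path) -> RuleSet:
    """Read a rule TSV (family, rule_type, reference_id, position, allowed, pattern, min_count, label)."""
    residue: dict[str, list[ResidueRule]] = {f: [] for f in FAMILIES}
    pattern: dict[str, list[PatternRule]] = {f: [] for f in FAMILIES}
    anchors: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            fam = fields[idx["family"]]
            kind = fields[idx["rule_type"]]
            label = fields[idx["label"]]
            if kind == "residue":
                rule = ResidueRule(
                    family=fam,
                    reference_id=fields[idx["reference_id"]],
                    position=int(fields[idx["position"]]),
                    allowed=frozenset(fields[idx["allowed"]]),
                    label=label,
                )
                residue[fam].append(rule)
                prev = anchors.setdefault(fam, rule.reference_id)
                if prev != rule.reference_id:
                    raise InputError(f"family {fam}: multiple reference anchors in rule file")
            elif kind == "pattern":
                pattern[fam].append(
                    PatternRule(
                        family=fam,
                        pattern=fields[idx["pattern"]],
                        min_count=int(fields[idx["min_count"]]),
                        label=label,
                    )
                )
            else:
                raise InputError(f"unknown rule_type {kind!r} in {path}")
    return RuleSet(
        families={
            f: FamilyRules(tuple(residue[f]), tuple(pattern[f]), anchors.get(f))
            for f in FAMILIES
        }
    )


def default_rulesets() -> RuleSet:
    """The shipped curation rules: hgcA C93; hgcB twice CX2CX2CX3C; merA
    C207/C212/Y264/Y-or-F605/C628/C629; merB C96/D99/C117/C159; rpoB none."""
    path = resources.files("hgscan.data").joinpath("default_rules.tsv")
    with resources.as_file(path) as p:
        return load_rules(p)


def map_reference_position(aln: Alignment, position: int) -> str:
    """Candidate residue aligned to the position-th reference residue, or '-'.

    The alignment must have the reference as sequence a and the candidate
    as sequence b.  Mapping is by reference coordinates, so insertions in
    the candidate do not shift it.
    """
    if position < 1:
        raise InputError("reference position must be >= 1")
    seen = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != GAP:
            seen += 1
            if seen == position:
                return cb
    raise InputError(f"position {position} beyond reference length {seen}")


def check_residue_rules(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    rules: list[ResidueRule] | tuple[ResidueRule, ...],
    params: AlignParams | None = None,
) -> ValidationResult:
    """Evaluate all residue rules of one family with a single global alignment."""
    for rule in rules:
        if rule.reference_id != reference.id:
            raise InputError(
                f"rule {rule.label} anchored to {rule.reference_id!r}, "
                f"got reference {reference.id!r}"
            )
    aln = global_align(reference, candidate, params)
    failed: list[str] = []
    checked: list[tuple[str, str]] = []
    for rule in rules:
        residue = map_reference_position(aln, rule.position)
        checked.append((rule.label, residue))
        if residue == GAP or residue not in rule.allowed:
            failed.append(rule.label)
    return ValidationResult(
        record_id=candidate.id,
        sample_id=candidate.sample_id,
        family=rules[0].family if rules else "",
        passed=not failed,
        failed_rules=tuple(failed),
        positions_checked=tuple(checked),
    )


def check_pattern_rule(candidate: ProteinRecord, rule: PatternRule) -> tuple[int, bool]:
    """Count non-overlapping left-to-right template occurrences in the raw sequence."""
    count = sum(1 for _ in rule.regex().finditer(candidate.sequence))
    return count, count >= rule.min_count


def validate_hits(
    hits: list[HmmHit],
    catalog: dict[str, ProteinRecord],
    rulesets: RuleSet,
    references: dict[str, ProteinRecord],
    params: AlignParams | None = None,
) -> list[ValidationResult]:
    """Apply each hit family's rules; families with no rules pass automatically."""
    results: list[ValidationResult] = []
    for hit in hits:
        if hit.record_id not in catalog:
            raise InputError(f"hit references unknown record id {hit.record_id!r}")
        if hit.family not in rulesets:
            raise InputError(f"no ruleset for family {hit.family!r}")
        rec = catalog[hit.record_id]
        fam_rules = rulesets[hit.family]
        failed: list[str] = []
        checked: list[tuple[str, str]] = []
        if fam_rules.residue_rules:
            ref = references.get(hit.family)
            if ref is None:
                raise InputError(f"no anchor reference supplied for family {hit.family!r}")
            res = check_residue_rules(rec, ref, fam_rules.residue_rules, params)
            failed.extend(res.failed_rules)
            checked.extend(res.positions_checked)
        for prule in fam_rules.pattern_rules:
            count, ok = check_pattern_rule(rec, prule)
            checked.append((prule.label, str(count)))
            if not ok:
                failed.append(prule.label)
        results.append(
            ValidationResult(
                record_id=hit.record_id,
                sample_id=hit.sample_id,
                family=hit.family,
                passed=not failed,
                failed_rules=tuple(failed),
                positions_checked=tuple(checked),
            )
        )
    return results
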