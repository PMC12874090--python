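"""Seeded generators for reference families, sample catalogs, and environment tables.

Ground-truth-labeled inputs for the pipeline: reference families carry the
curation-rule residues planted at their anchor positions and
lineage-specific marker mutations so lineages are separable; catalogs mix
valid records (rule sites protected), rule-ablated records (exactly one
named rule broken, with a chemically conservative substitution so the HMM
still scores them well), and background decoys.  Environment tables have
the monotone depth structure the correlation analysis expects: dMeHg,
AOU and nutrients increase with depth while temperature, oxygen and cell
counts decrease; dTHg stays flat with noise.

All outputs are deterministic functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hgscan.core_align import AA_LETTERS, ProteinRecord
from hgscan.errors import InputError
from hgscan.motif_screen import FamilyRules, RuleSet, default_rulesets
from hgscan.profile_hmm import MSA

HG_FAMILIES = ("hgcA", "hgcB", "merA", "merB")

# chemically conservative but rule-breaking substitutions
_ABLATION_SUB = {"C": "S", "D": "N", "Y": "H", "F": "L"}

# 0-based start offsets at which the two hgcB cysteine clusters are planted
_PATTERN_STARTS = (10, 40)
_PATTERN_C_OFFSETS = (0, 3, 6, 10)  # CX2CX2CX3C
_PATTERN_SPAN = 11


@dataclass(frozen=True)
class FamilyDesign:
    family: str
    length: int
    lineages: tuple[tuple[str, int], ...]  # (lineage label, n references)
    inter_reference_divergence: float = 0.08
    n_marker_sites: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inter_reference_divergence <= 0.3:
            raise InputError("inter_reference_divergence must be in [0, 0.3]")
        if self.n_references < 2:
            raise InputError("need at least 2 references per family")

    @property
    def n_references(self) -> int:
        return sum(n for _, n in self.lineages)


@dataclass(frozen=True)
class FamilyBuild:
    """A generated reference family with everything downstream stages need."""

    design: FamilyDesign
    references: tuple[tuple[ProteinRecord, str], ...]  # (record, lineage)
    msa: MSA
    anchor: ProteinRecord
    protected_positions: tuple[int, ...]  # 0-based; never mutated
    rule_residues: tuple[tuple[str, int, str], ...]  # (rule label, 0-based pos, planted)


@dataclass(frozen=True)
class CatalogDesign:
    stations: tuple[str, ...] = ("S1", "S2", "S3")
    depths_m: tuple[float, ...] = (200.0, 500.0, 1000.0, 1500.0)
    valid_counts: dict = field(
        default_factory=lambda: {
            "hgcA": {200.0: 5, 500.0: 10, 1000.0: 15, 1500.0: 20},
            "merA": {200.0: 6, 500.0: 11, 1000.0: 16, 1500.0: 19},
            "merB": {200.0: 5, 500.0: 9, 1000.0: 14, 1500.0: 18},
            "hgcB": {200.0: 8, 500.0: 8, 1000.0: 8, 1500.0: 8},
        }
    )
    n_ablated: int = 5  # per Hg family per sample
    n_decoys: int = 200  # per sample
    n_rpob: int = 500  # per sample
    mutation_rate: float = 0.05
    decoy_length_range: tuple[int, int] = (150, 700)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 0.2:
            raise InputError("mutation_rate must be in [0, 0.2]")
        for fam, per_depth in self.valid_counts.items():
            if any(n < 0 for n in per_depth.values()):
                raise InputError(f"negative valid count for {fam}")

    def sample_id(self, station: str, depth: float) -> str:
        return f"{station}_{int(depth)}m"


def default_family_designs(seed: int = 0) -> dict[str, FamilyDesign]:
    """Desk-scale family designs; lengths cover every anchored rule position."""
    specs = {
        "hgcA": (160, (("Nitrospina", 4), ("Deltaproteobacteria", 3), ("Alphaproteobacteria", 2))),
        "hgcB": (90, (("Nitrospina", 4), ("Deltaproteobacteria", 2))),
        "merA": (660, (("Gammaproteobacteria", 4), ("Alphaproteobacteria", 3), ("Betaproteobacteria", 2))),
        "merB": (210, (("Alphaproteobacteria", 3), ("Betaproteobacteria", 2), ("Actinobacteria", 2))),
        "rpoB": (280, (("Bacteria", 6),)),
    }
    return {
        fam: FamilyDesign(family=fam, length=length, lineages=lineages, seed=seed + i)
        for i, (fam, (length, lineages)) in enumerate(specs.items())
    }


def _family_protected(family: str, rules: FamilyRules, length: int) -> tuple[list[int], list[tuple[str, int, str]]]:
    """0-based protected positions and planted rule residues for one family."""
    protected: list[int] = []
    planted: list[tuple[str, int, str]] = []
    for rule in rules.residue_rules:
        pos0 = rule.position - 1
        if pos0 >= length:
            raise InputError(
                f"rule {rule.label}: position {rule.position} exceeds design length {length}"
            )
        protected.append(pos0)
        planted.append((rule.label, pos0, sorted(rule.allowed)[-1]))
    if rules.pattern_rules:
        if _PATTERN_STARTS[-1] + _PATTERN_SPAN > length:
            raise InputError(f"{family}: design too short for planted patterns")
        for start in _PATTERN_STARTS:
            for off in _PATTERN_C_OFFSETS:
                protected.append(start + off)
    return protected, planted


def make_reference_family(design: FamilyDesign, rules: FamilyRules) -> FamilyBuild:
    """Generate a labeled reference set, its (ungapped) MSA, and the rule anchor.

    The anchor is the seed sequence itself, named ``<family>_ref`` to match
    the shipped rule file; references derive from it by lineage marker
    mutations plus random substitutions that never touch rule positions.
    """
    rng = np.random.default_rng(design.seed)
    letters = list(AA_LETTERS)
    protected, planted = _family_protected(design.family, rules, design.length)
    seed_seq = list(rng.choice(letters, size=design.length))
    for _, pos0, residue in planted:
        seed_seq[pos0] = residue
    for start in (_PATTERN_STARTS if rules.pattern_rules else ()):
        for off in _PATTERN_C_OFFSETS:
            seed_seq[start + off] = "C"
    protected_set = set(protected)

    free = [i for i in range(design.length) if i not in protected_set]
    rng.shuffle(free)
    marker_sites: dict[str, list[int]] = {}
    cursor = 0
    for lineage, _ in design.lineages:
        marker_sites[lineage] = sorted(free[cursor : cursor + design.n_marker_sites])
        cursor += design.n_marker_sites
    if cursor > len(free):
        raise InputError(f"{design.family}: not enough free sites for lineage markers")
    mutable = sorted(free[cursor:])

    references: list[tuple[ProteinRecord, str]] = []
    rows: list[tuple[str, str]] = []
    k = 0
    for lineage, n_refs in design.lineages:
        for _ in range(n_refs):
            seq = seed_seq.copy()
            lineage_shift = 1 + sum(ord(c) for c in lineage) % 17
            for site in marker_sites[lineage]:
                current = seq[site]
                seq[site] = letters[(letters.index(current) + lineage_shift) % 20]
            # exact mutation count so the pairwise identity bound
            # (>= 1 - 2*divergence, minus marker sites) holds deterministically
            n_mut = int(round(design.inter_reference_divergence * len(mutable)))
            for site in rng.choice(len(mutable), size=n_mut, replace=False):
                site = mutable[int(site)]
                seq[site] = _mutate_residue(seq[site], rng, letters)
            ref_id = f"{design.family}_r{k:02d}"
            sequence = "".join(seq)
            references.append((ProteinRecord(ref_id, "reference", sequence), lineage))
            rows.append((ref_id, sequence))
            k += 1
    anchor = ProteinRecord(f"{design.family}_ref", "reference", "".join(seed_seq))
    return FamilyBuild(
        design=design,
        references=tuple(references),
        msa=MSA(rows=tuple(rows)),
        anchor=anchor,
        protected_positions=tuple(sorted(protected_set)),
        rule_residues=tuple(planted),
    )


def _mutate_residue(current: str, rng: np.random.Generator, letters: list[str]) -> str:
    """A uniformly random residue different from the current one."""
    idx = int(rng.integers(19))
    cur = letters.index(current)
    return letters[idx if idx < cur else idx + 1]


def build_default_families(seed: int = 0, rulesets: RuleSet | None = None) -> dict[str, FamilyBuild]:
    rulesets = rulesets or default_rulesets()
    return {
        fam: make_reference_family(design, rulesets[fam])
        for fam, design in default_family_designs(seed).items()
    }


def _mutated_copy(
    build: FamilyBuild,
    rng: np.random.Generator,
    mutation_rate: float,
    letters: list[str],
) -> tuple[list[str], str]:
    """A valid-class sequence: a mutated reference with rule sites protected."""
    idx = int(rng.integers(len(build.references)))
    ref, lineage = build.references[idx]
    seq = list(ref.sequence)
    if mutation_rate > 0:
        protected = set(build.protected_positions)
        hit = np.flatnonzero(rng.random(len(seq)) < mutation_rate)
        for site in hit:
            if int(site) not in protected:
                seq[int(site)] = _mutate_residue(seq[int(site)], rng, letters)
    return seq, lineage


def _pattern_count(sequence: str, rules: FamilyRules) -> int:
    rule = rules.pattern_rules[0]
    return sum(1 for _ in rule.regex().finditer(sequence))


def make_catalog(
    cat_design: CatalogDesign,
    families: dict[str, FamilyBuild],
    rulesets: RuleSet | None = None,
) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame]:
    """Per-sample catalogs plus a ground-truth table.

    Classes: ``valid`` (passes all rules by construction), ``ablated``
    (fails exactly the named rule), ``decoy`` (i.i.d. uniform background).
    rpoB records are all valid-class.  Truth columns: record_id,
    sample_id, class, family, lineage, ablated_rule.
    """
    rulesets = rulesets or default_rulesets()
    rng = np.random.default_rng(cat_design.seed)
    letters = list(AA_LETTERS)
    catalogs: dict[str, list[ProteinRecord]] = {}
    truth_rows: list[dict] = []

    for station in cat_design.stations:
        for depth in cat_design.depths_m:
            sid = cat_design.sample_id(station, depth)
            records: list[ProteinRecord] = []

            for fam in HG_FAMILIES:
                build = families[fam]
                fam_rules = rulesets[fam]
                n_valid = cat_design.valid_counts[fam][depth]
                for k in range(n_valid):
                    seq, lineage = _mutated_copy(build, rng, cat_design.mutation_rate, letters)
                    rec = ProteinRecord(f"{sid}|{fam}|valid|{k:03d}", sid, "".join(seq))
                    records.append(rec)
                    truth_rows.append(
                        dict(record_id=rec.id, sample_id=sid, klass="valid",
                             family=fam, lineage=lineage, ablated_rule="")
                    )
                all_rules = [r.label for r in fam_rules.residue_rules] + [
                    r.label for r in fam_rules.pattern_rules
                ]
                for k in range(cat_design.n_ablated):
                    label = all_rules[k % len(all_rules)]
                    seq, lineage = _ablated_copy(
                        build, fam_rules, label, rng, cat_design.mutation_rate, letters
                    )
                    rec = ProteinRecord(f"{sid}|{fam}|ablated|{k:03d}", sid, "".join(seq))
                    records.append(rec)
                    truth_rows.append(
                        dict(record_id=rec.id, sample_id=sid, klass="ablated",
                             family=fam, lineage=lineage, ablated_rule=label)
                    )

            build = families["rpoB"]
            for k in range(cat_design.n_rpob):
                seq, lineage = _mutated_copy(build, rng, cat_design.mutation_rate, letters)
                rec = ProteinRecord(f"{sid}|rpoB|valid|{k:03d}", sid, "".join(seq))
                records.append(rec)
                truth_rows.append(
                    dict(record_id=rec.id, sample_id=sid, klass="valid",
                         family="rpoB", lineage=lineage, ablated_rule="")
                )

            lo, hi = cat_design.decoy_length_range
            for k in range(cat_design.n_decoys):
                L = int(rng.integers(lo, hi + 1))
                seq = "".join(rng.choice(letters, size=L))
                rec = ProteinRecord(f"{sid}|decoy|{k:03d}", sid, seq)
                records.append(rec)
                truth_rows.append(
                    dict(record_id=rec.id, sample_id=sid, klass="decoy",
                         family="", lineage="", ablated_rule="")
                )
            catalogs[sid] = records

    truth = pd.DataFrame(truth_rows).rename(columns={"klass": "class"})
    return catalogs, truth


def _ablated_copy(
    build: FamilyBuild,
    fam_rules: FamilyRules,
    rule_label: str,
    rng: np.random.Generator,
    mutation_rate: float,
    letters: list[str],
) -> tuple[list[str], str]:
    """A valid-style sequence with exactly the named rule broken."""
    for _ in range(50):
        seq, lineage = _mutated_copy(build, rng, mutation_rate, letters)
        residue_rule = next(
            (r for r in fam_rules.residue_rules if r.label == rule_label), None
        )
        if residue_rule is not None:
            pos0 = residue_rule.position - 1
            seq[pos0] = _ABLATION_SUB.get(seq[pos0], "G")
            if seq[pos0] not in residue_rule.allowed:
                return seq, lineage
            continue
        # pattern rule: destroy the second planted cluster's first cysteine
        seq[_PATTERN_STARTS[1] + _PATTERN_C_OFFSETS[0]] = "S"
        if _pattern_count("".join(seq), fam_rules) < fam_rules.pattern_rules[0].min_count:
            return seq, lineage
        # a spurious cluster arose from random mutations; redraw
    raise InputError(f"could not ablate rule {rule_label} after 50 attempts")


def make_env_table(
    stations=("S1", "S2", "S3"),
    depths_m=(200.0, 500.0, 1000.0, 1500.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Station x depth environmental profiles with planted monotone structure."""
    if len(depths_m) < 3:
        raise InputError("environment table needs at least 3 depths")
    rng = np.random.default_rng(seed)
    n = len(depths_m)
    rows = []
    for station in stations:
        profiles = {
            "temperature_C": _monotone(rng, n, 25.0, 3.0),
            "oxygen_umol_kg": _monotone(rng, n, 210.0, 55.0),
            "AOU_umol_kg": _monotone(rng, n, 5.0, 180.0),
            "NO3_uM": _monotone(rng, n, 0.1, 40.0),
            "PO4_uM": _monotone(rng, n, 0.05, 3.0),
            "SiO2_uM": _monotone(rng, n, 2.0, 150.0),
            "dMeHg_pM": _monotone(rng, n, 0.004, 0.04),
            "cells_per_mL": _monotone(rng, n, 4.0e5, 0.3e5),
        }
        dthg = rng.uniform(0.4, 0.7, size=n)
        for i, depth in enumerate(depths_m):
            rows.append(
                {
                    "sample_id": f"{station}_{int(depth)}m",
                    "station": station,
                    "depth_m": float(depth),
                    **{k: float(v[i]) for k, v in profiles.items()},
                    "dTHg_pM": float(dthg[i]),
                    "dMeHg_pM": float(profiles["dMeHg_pM"][i]),
                }
            )
    env = pd.DataFrame(rows)
    env["dMeHg_over_dTHg"] = env["dMeHg_pM"] / env["dTHg_pM"]
    cols = [
        "sample_id", "station", "depth_m", "temperature_C", "oxygen_umol_kg",
        "AOU_umol_kg", "NO3_uM", "PO4_uM", "SiO2_uM", "dTHg_pM", "dMeHg_pM",
        "dMeHg_over_dTHg", "cells_per_mL",
    ]
    return env[cols]


def _monotone(rng: np.random.Generator, n: int, start: float, end: float) -> np.ndarray:
    """Strictly monotone profile from start to end with random spacing."""
    steps = rng.uniform(0.3, 1.0, size=n - 1)
    frac = np.concatenate([[0.0], np.cumsum(steps)])
    frac /= frac[-1]
    return start + (end - start) * frac
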