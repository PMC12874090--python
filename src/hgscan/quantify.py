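"""Abundance tables normalized to rpoB, lineage assignment, proportions.

Validated per-sample counts of the mercury genes are expressed as a
percentage of the sample's rpoB marker count.  Lineage assignment places
each record with its best-scoring labeled reference under global
alignment; assignments with a score margin below 5 are flagged ambiguous
but keep the argmax lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from hgscan.core_align import AlignParams, ProteinRecord, align_score
from hgscan.errors import InputError
from hgscan.motif_screen import ValidationResult

AMBIGUOUS_MARGIN = 5.0


@dataclass(frozen=True)
class SampleContext:
    sample_id: str
    station: str
    depth_m: float

    def __post_init__(self) -> None:
        if self.depth_m <= 0:
            raise InputError(f"sample {self.sample_id}: depth must be positive")


@dataclass(frozen=True)
class LineageAssignment:
    record_id: str
    family: str
    lineage: str
    best_reference_id: str
    score: float
    margin: float

    @property
    def ambiguous(self) -> bool:
        return self.margin < AMBIGUOUS_MARGIN


def count_validated(
    results: list[ValidationResult],
    contexts: dict[str, SampleContext],
    families: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Per-sample per-family counts of passing records over the full grid.

    Samples with zero passing hits still appear with count 0.
    """
    for res in results:
        if res.sample_id not in contexts:
            raise InputError(f"record {res.record_id}: unknown sample {res.sample_id!r}")
    counts: dict[tuple[str, str], int] = {
        (sid, fam): 0 for sid in contexts for fam in families
    }
    for res in results:
        if res.passed and res.family in families:
            counts[(res.sample_id, res.family)] += 1
    rows = [
        {"sample_id": sid, "family": fam, "validated_count": n}
        for (sid, fam), n in counts.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["sample_id", "family"], kind="mergesort").reset_index(drop=True)


def relative_abundance(counts: pd.DataFrame, rpob_counts: dict[str, int]) -> pd.DataFrame:
    """Attach rpoB counts and the rpoB-normalized percentage to a count table."""
    out = counts.copy()
    missing = [sid for sid in out["sample_id"].unique() if sid not in rpob_counts]
    if missing:
        raise InputError(f"no rpoB count for sample(s): {', '.join(sorted(missing))}")
    zero = sorted(sid for sid, n in rpob_counts.items() if n <= 0)
    if zero:
        raise InputError(f"rpoB count is zero for sample(s): {', '.join(zero)}")
    out["rpob_count"] = out["sample_id"].map(rpob_counts).astype(int)
    out["relative_pct"] = 100.0 * out["validated_count"] / out["rpob_count"]
    return out


def assign_lineage(
    record: ProteinRecord,
    labeled_references: list[tuple[ProteinRecord, str]],
    family: str,
    params: AlignParams | None = None,
) -> LineageAssignment:
    """Best labeled reference by global-alignment score; ties by ascending id."""
    if not labeled_references:
        raise InputError(f"no labeled references for family {family!r}")
    scored = sorted(
        ((align_score(ref, record, params), ref, lineage) for ref, lineage in labeled_references),
        key=lambda t: (-t[0], t[1].id),
    )
    best_score, best_ref, best_lineage = scored[0]
    margin = best_score - scored[1][0] if len(scored) > 1 else float("inf")
    return LineageAssignment(
        record_id=record.id,
        family=family,
        lineage=best_lineage,
        best_reference_id=best_ref.id,
        score=best_score,
        margin=margin,
    )


def lineage_proportions(
    assignments: list[LineageAssignment],
    contexts: dict[str, SampleContext] | None = None,
    record_samples: dict[str, str] | None = None,
    stratify_by_depth: bool = False,
) -> pd.DataFrame:
    """Per-family lineage percentages; optionally broken down by station and depth."""
    if not assignments:
        return pd.DataFrame(columns=["family", "lineage", "n_records", "pct_of_family"])
    rows = []
    for a in assignments:
        row = {"family": a.family, "lineage": a.lineage, "record_id": a.record_id}
        if stratify_by_depth:
            if record_samples is None or contexts is None:
                raise InputError("depth stratification needs record->sample and sample contexts")
            ctx = contexts[record_samples[a.record_id]]
            row["station"] = ctx.station
            row["depth_m"] = ctx.depth_m
        rows.append(row)
    df = pd.DataFrame(rows)
    group = ["family", "station", "depth_m"] if stratify_by_depth else ["family"]
    counts = (
        df.groupby(group + ["lineage"], sort=True)
        .size()
        .rename("n_records")
        .reset_index()
    )
    totals = counts.groupby(group)["n_records"].transform("sum")
    counts["pct_of_family"] = 100.0 * counts["n_records"] / totals
    return counts
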