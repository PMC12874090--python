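"""Pairwise global protein alignment, identity, and greedy dereplication.

Alignment is affine-gap Needleman-Wunsch (end gaps penalized) over BLOSUM62
with 'X' scoring 0 against everything; a gap run of length L costs
``gap_open + (L - 1) * gap_extend``.  Percent identity uses the CD-HIT
convention: identical columns divided by the length of the shorter
unaligned sequence.  Dereplication is greedy incremental clustering by
descending length, each sequence joining the first representative at or
above the identity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from hgscan.errors import InputError

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA_LETTERS + "X"
GAP = "-"

_ALLOWED = frozenset(ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein from one sample."""

    id: str
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise InputError(
                f"record {self.id!r}: unknown residue character(s) "
                f"{''.join(sorted(bad))!r} (expected uppercase {ALPHABET})"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring parameters (protein defaults)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InputError("gap penalties must be <= 0")
        if abs(self.gap_open) < abs(self.gap_extend):
            raise InputError("|gap_open| must be >= |gap_extend|")


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment with identity bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    identity: float


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]
    identities: tuple[float, ...]  # identity of each member to the representative


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    threshold: float


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    base = substitution_matrices.load(matrix_name)
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in AA_LETTERS:
        for b in AA_LETTERS:
            mat[a, b] = base[a, b]
    # 'X' scores 0 against everything, including itself
    for a in ALPHABET:
        mat["X", a] = 0.0
        mat[a, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _count_identical(aligned_a: str, aligned_b: str) -> int:
    # 'X' never counts as identical
    return sum(
        1 for ca, cb in zip(aligned_a, aligned_b) if ca == cb and ca != GAP and ca != "X"
    )


def percent_identity(aln: Alignment, len_a: int, len_b: int) -> float:
    """Identity under the shorter-sequence denominator, in [0, 1]."""
    if min(len_a, len_b) <= 0:
        raise InputError("sequence lengths must be positive")
    return aln.n_identical / min(len_a, len_b)


def global_align(a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None) -> Alignment:
    """Optimal affine-gap global alignment of two protein records.

    Deterministic: the first alignment in the aligner's fixed traceback
    order is returned.
    """
    params = params or AlignParams()
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    result = aligner.align(a.sequence, b.sequence)
    best = result[0]
    aligned_a, aligned_b = best[0], best[1]
    n_id = _count_identical(aligned_a, aligned_b)
    identity = n_id / min(a.length, b.length)
    return Alignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best.score),
        n_identical=n_id,
        identity=identity,
    )


def align_score(a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None) -> float:
    """Optimal global-alignment score only (no traceback)."""
    params = params or AlignParams()
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    return float(aligner.score(a.sequence, b.sequence))


def dereplicate(
    records: list[ProteinRecord],
    threshold: float = 0.9,
    params: AlignParams | None = None,
) -> ClusterSet:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed by descending length (ties by ascending id);
    each joins the first existing cluster whose representative is at or
    above the threshold, else founds a new cluster.  Representatives are
    therefore the longest member of each cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    params = params or AlignParams()
    order = sorted(records, key=lambda r: (-r.length, r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    idents: list[list[float]] = []
    for rec in order:
        placed = False
        for i, rep in enumerate(reps):
            if rec.id == rep.id and rec is rep:  # pragma: no cover - defensive
                continue
            aln = global_align(rep, rec, params)
            if aln.identity >= threshold:
                members[i].append(rec.id)
                idents[i].append(aln.identity)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
            idents.append([1.0])
    clusters = tuple(
        Cluster(rep.id, tuple(m), tuple(v)) for rep, m, v in zip(reps, members, idents)
    )
    return ClusterSet(clusters=clusters, threshold=threshold)
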