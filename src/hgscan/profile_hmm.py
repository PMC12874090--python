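"""Per-family profile HMMs: build from a reference alignment, score, calibrate.

The model is a small match/insert/delete profile scored locally along the
model (uniform entry and exit over match states, hmmsearch-style) with
free flanking states absorbing sequence overhangs, so background scores
are length-stable.  Columns with less than 50% gaps become match states;
emissions use Laplace +1 pseudocounts; transitions are estimated from the
alignment's gap structure with +1 pseudocounts over the full 3x3 state
transition set per position.  Scores are log-odds in bits against an
i.i.d. background model.  E-values come from a maximum-likelihood Gumbel
fit to Viterbi scores of seeded background sequences, scaled by the size
of the searched catalog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from hgscan.core_align import AA_LETTERS, GAP, ProteinRecord
from hgscan.errors import CalibrationError, InputError, ProfileBuildError

FAMILIES = ("hgcA", "hgcB", "merA", "merB", "rpoB")

_AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
_X_INDEX = 20  # 'X': background-equivalent emission, log-odds contribution 0

# state indices within the per-position 3x3 transition table
_M, _I, _D = 0, 1, 2


@dataclass(frozen=True)
class MSA:
    """A multiple alignment of reference sequences ('-' gaps)."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise InputError("profile building needs at least 2 aligned sequences")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise InputError("aligned sequences must all have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific profile with pseudocounted probabilities.

    transitions[j, s, t] is P(state s at position j -> state t), where a
    transition to M or D advances to position j+1 and a transition to I
    stays at j; position 0 is the begin state and a transition to M at
    position n_match is the end transition.
    """

    family: str
    n_match: int
    match_emissions: np.ndarray  # (n_match + 1, 20); row 0 unused
    insert_emissions: np.ndarray  # (20,)
    transitions: np.ndarray  # (n_match + 1, 3, 3)
    background: np.ndarray  # (20,)

    def __post_init__(self) -> None:
        if self.n_match < 1:
            raise ProfileBuildError("profile must have at least one match state")
        for name, vec in (("insert", self.insert_emissions), ("background", self.background)):
            if abs(vec.sum() - 1.0) > 1e-9 or (vec <= 0).any():
                raise ProfileBuildError(f"{name} emission vector not a positive distribution")
        if np.abs(self.match_emissions[1:].sum(axis=1) - 1.0).max() > 1e-9:
            raise ProfileBuildError("match emissions not normalized")
        if np.abs(self.transitions.sum(axis=2) - 1.0).max() > 1e-9:
            raise ProfileBuildError("transitions not normalized")


@dataclass(frozen=True)
class EvalueCalibration:
    """Empirical Gumbel score-to-E-value map for one profile."""

    mu: float
    lam: float  # Gumbel scale; > 0
    n_null: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise CalibrationError("Gumbel scale must be positive")
        if self.n_null < 100:
            raise CalibrationError("calibration needs at least 100 null sequences")

    def evalue(self, bit_score: float, database_size: int) -> float:
        return float(database_size) * float(
            gumbel_r.sf(bit_score, loc=self.mu, scale=self.lam)
        )


@dataclass(frozen=True)
class HmmHit:
    record_id: str
    sample_id: str
    family: str
    bit_score: float
    evalue: float


def encode_sequence(sequence: str) -> np.ndarray:
    idx = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence):
        idx[i] = _AA_INDEX.get(ch, _X_INDEX)
    return idx


def build_profile(msa: MSA, family: str) -> ProfileModel:
    """Estimate a profile from an MSA (match columns = < 50% gaps)."""
    n_rows = len(msa.rows)
    cols = np.array([[c for c in seq] for _, seq in msa.rows])
    gap_frac = (cols == GAP).mean(axis=0)
    if (gap_frac == 1.0).all():
        raise ProfileBuildError("all-gap alignment")
    match_cols = np.flatnonzero(gap_frac < 0.5)
    if match_cols.size == 0:
        raise ProfileBuildError("no column qualifies as a match state")
    n_match = int(match_cols.size)
    is_match = np.zeros(msa.n_columns, dtype=bool)
    is_match[match_cols] = True

    match_counts = np.zeros((n_match + 1, 20))
    insert_counts = np.zeros(20)
    bg_counts = np.zeros(20)
    trans_counts = np.zeros((n_match + 1, 3, 3))

    for _, seq in msa.rows:
        state, pos = _M, 0  # begin
        for c, ch in enumerate(seq):
            residue = ch != GAP
            if residue:
                ai = _AA_INDEX.get(ch, None)
                if ai is not None:
                    bg_counts[ai] += 1
            if is_match[c]:
                nxt = _M if residue else _D
                trans_counts[pos, state, nxt] += 1
                pos += 1
                state = nxt
                if residue and ai is not None:
                    match_counts[pos, ai] += 1
            elif residue:
                trans_counts[pos, state, _I] += 1
                state = _I
                if ai is not None:
                    insert_counts[ai] += 1
        trans_counts[pos, state, _M] += 1  # end transition

    match_em = (match_counts + 1.0) / (match_counts.sum(axis=1, keepdims=True) + 20.0)
    match_em[0] = 0.0  # row 0 is the (non-emitting) begin position
    insert_em = (insert_counts + 1.0) / (insert_counts.sum() + 20.0)
    background = (bg_counts + 1.0) / (bg_counts.sum() + 20.0)
    transitions = (trans_counts + 1.0) / (trans_counts.sum(axis=2, keepdims=True) + 3.0)

    return ProfileModel(
        family=family,
        n_match=n_match,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=transitions,
        background=background,
    )


_NEG = -1.0e30


def _scoring_arrays(profile: ProfileModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Log2 emission-ratio and transition arrays plus the entry/exit cost.

    Scoring is local in the model: a free flanking state absorbs any
    sequence prefix at background cost, alignment may enter at any match
    state (uniform cost -log2(n_match)) and exit from any match state at
    the same cost into a free suffix flank.  Interior inserts and deletes
    use the estimated transition probabilities.  This keeps background
    scores essentially length-independent, which a single Gumbel
    calibration requires.
    """
    n = profile.n_match
    m_em = np.zeros((n + 1, 21))
    m_em[1:, :20] = np.log2(profile.match_emissions[1:] / profile.background)
    i_em = np.full((n + 1, 21), _NEG)
    if n > 1:
        i_em[1 : n, :20] = np.log2(profile.insert_emissions / profile.background)
        i_em[1 : n, 20] = 0.0
    t = np.log2(profile.transitions)
    entry = -math.log2(n)
    return m_em, i_em, t, entry


@njit(cache=True)
def _viterbi_kernel(seq, m_em, i_em, t, entry):  # pragma: no cover - compiled
    n = m_em.shape[0] - 1
    L = seq.shape[0]
    vM = np.full(n + 1, _NEG)
    vI = np.full(n + 1, _NEG)
    vD = np.full(n + 1, _NEG)
    nM = np.empty(n + 1)
    nI = np.empty(n + 1)
    nD = np.empty(n + 1)
    best_exit = _NEG
    for i in range(L):
        x = seq[i]
        nI[0] = _NEG
        nI[n] = _NEG
        for j in range(1, n):
            best = vM[j] + t[j, _M, _I]
            alt = vI[j] + t[j, _I, _I]
            if alt > best:
                best = alt
            alt = vD[j] + t[j, _D, _I]
            if alt > best:
                best = alt
            nI[j] = best + i_em[j, x]
        nM[0] = _NEG
        for j in range(1, n + 1):
            best = entry  # fresh entry from the free prefix flank
            alt = vM[j - 1] + t[j - 1, _M, _M]
            if alt > best:
                best = alt
            alt = vI[j - 1] + t[j - 1, _I, _M]
            if alt > best:
                best = alt
            alt = vD[j - 1] + t[j - 1, _D, _M]
            if alt > best:
                best = alt
            nM[j] = best + m_em[j, x]
            row_exit = nM[j] + entry
            if row_exit > best_exit:
                best_exit = row_exit
        nD[0] = _NEG
        for j in range(1, n + 1):
            best = nM[j - 1] + t[j - 1, _M, _D]
            alt = nI[j - 1] + t[j - 1, _I, _D]
            if alt > best:
                best = alt
            alt = nD[j - 1] + t[j - 1, _D, _D]
            if alt > best:
                best = alt
            nD[j] = best
        vM, nM = nM, vM
        vI, nI = nI, vI
        vD, nD = nD, vD
    return best_exit


@njit(cache=True, inline="always")
def _lse2(a, b):  # pragma: no cover - compiled
    if a < b:
        a, b = b, a
    if a <= _NEG:
        return _NEG
    return a + math.log1p(2.0 ** (b - a)) / 0.6931471805599453


@njit(cache=True)
def _forward_kernel(seq, m_em, i_em, t, entry):  # pragma: no cover - compiled
    n = m_em.shape[0] - 1
    L = seq.shape[0]
    vM = np.full(n + 1, _NEG)
    vI = np.full(n + 1, _NEG)
    vD = np.full(n + 1, _NEG)
    nM = np.empty(n + 1)
    nI = np.empty(n + 1)
    nD = np.empty(n + 1)
    acc_exit = _NEG
    for i in range(L):
        x = seq[i]
        nI[0] = _NEG
        nI[n] = _NEG
        for j in range(1, n):
            acc = _lse2(vM[j] + t[j, _M, _I], vI[j] + t[j, _I, _I])
            acc = _lse2(acc, vD[j] + t[j, _D, _I])
            nI[j] = acc + i_em[j, x]
        nM[0] = _NEG
        row_acc = _NEG
        for j in range(1, n + 1):
            acc = _lse2(entry, vM[j - 1] + t[j - 1, _M, _M])
            acc = _lse2(acc, vI[j - 1] + t[j - 1, _I, _M])
            acc = _lse2(acc, vD[j - 1] + t[j - 1, _D, _M])
            nM[j] = acc + m_em[j, x]
            row_acc = _lse2(row_acc, nM[j] + entry)
        acc_exit = _lse2(acc_exit, row_acc)
        nD[0] = _NEG
        for j in range(1, n + 1):
            acc = _lse2(nM[j - 1] + t[j - 1, _M, _D], nI[j - 1] + t[j - 1, _I, _D])
            acc = _lse2(acc, nD[j - 1] + t[j - 1, _D, _D])
            nD[j] = acc
        vM, nM = nM, vM
        vI, nI = nI, vI
        vD, nD = nD, vD
    return acc_exit


def score_sequence(profile: ProfileModel, rec: ProteinRecord) -> tuple[float, float]:
    """(Viterbi, forward) log-odds in bits against the background model."""
    m_em, i_em, t, entry = _scoring_arrays(profile)
    seq = encode_sequence(rec.sequence)
    return (
        float(_viterbi_kernel(seq, m_em, i_em, t, entry)),
        float(_forward_kernel(seq, m_em, i_em, t, entry)),
    )


def viterbi_scores(profile: ProfileModel, records: list[ProteinRecord]) -> np.ndarray:
    """Viterbi bit scores for a batch of records (arrays prepared once)."""
    m_em, i_em, t, entry = _scoring_arrays(profile)
    out = np.empty(len(records))
    for i, rec in enumerate(records):
        out[i] = _viterbi_kernel(encode_sequence(rec.sequence), m_em, i_em, t, entry)
    return out


def sample_background_sequences(
    background: np.ndarray, lengths: np.ndarray, rng: np.random.Generator
) -> list[str]:
    letters = np.array(list(AA_LETTERS))
    return ["".join(rng.choice(letters, size=int(L), p=background)) for L in lengths]


def calibrate_evalue(
    profile: ProfileModel,
    null_length_distribution,
    n_null: int = 500,
    seed: int = 0,
) -> EvalueCalibration:
    """Fit a Gumbel law to Viterbi scores of i.i.d. background sequences.

    Null lengths are resampled from ``null_length_distribution`` (typically
    the searched catalog's length distribution).
    """
    if n_null < 100:
        raise CalibrationError("n_null must be >= 100")
    pool = np.asarray(list(null_length_distribution), dtype=np.int64)
    if pool.size == 0 or (pool <= 0).any():
        raise InputError("null length distribution must be non-empty positive lengths")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(pool, size=n_null, replace=True)
    seqs = sample_background_sequences(profile.background, lengths, rng)
    records = [ProteinRecord(f"null{i}", "null", s) for i, s in enumerate(seqs)]
    scores = viterbi_scores(profile, records)
    if float(np.std(scores)) == 0.0:
        raise CalibrationError("degenerate null score variance")
    mu, lam = gumbel_r.fit(scores)
    return EvalueCalibration(mu=float(mu), lam=float(lam), n_null=n_null, seed=seed)


def search_catalog(
    profile: ProfileModel,
    calib: EvalueCalibration,
    catalog: list[ProteinRecord],
    evalue_threshold: float,
) -> list[HmmHit]:
    """All catalog records with E-value at or below the threshold.

    The E-value database size is the searched catalog's size.  Hits are
    sorted by ascending E-value, then record id.
    """
    if evalue_threshold <= 0:
        raise InputError("E-value threshold must be positive")
    if not catalog:
        return []
    n_db = len(catalog)
    scores = viterbi_scores(profile, catalog)
    evalues = n_db * gumbel_r.sf(scores, loc=calib.mu, scale=calib.lam)
    hits = [
        HmmHit(rec.id, rec.sample_id, profile.family, float(s), float(e))
        for rec, s, e in zip(catalog, scores, evalues)
        if e <= evalue_threshold
    ]
    hits.sort(key=lambda h: (h.evalue, h.record_id))
    return hits


# ---------------------------------------------------------------------------
# plain-text serialization (format-versioned, bit-exact round trip)

_FORMAT_LINE = "hgscan-profile 1"


def _fmt_vector(vec: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in vec)


def write_profile(profile: ProfileModel, path) -> None:
    lines = [
        _FORMAT_LINE,
        f"family {profile.family}",
        f"n_match {profile.n_match}",
        f"alphabet {AA_LETTERS}",
        "background " + _fmt_vector(profile.background),
        "insert_emissions " + _fmt_vector(profile.insert_emissions),
        "match_emissions",
    ]
    for j in range(1, profile.n_match + 1):
        lines.append(_fmt_vector(profile.match_emissions[j]))
    lines.append("transitions")
    for j in range(profile.n_match + 1):
        lines.append(_fmt_vector(profile.transitions[j].ravel()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_profile(path) -> ProfileModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _FORMAT_LINE:
        raise InputError(f"{path}: not a recognized profile file")
    header: dict[str, str] = {}
    i = 1
    while not lines[i].startswith("match_emissions"):
        key, _, value = lines[i].partition(" ")
        header[key] = value
        i += 1
    n = int(header["n_match"])
    m_em = np.zeros((n + 1, 20))
    i += 1
    for j in range(1, n + 1):
        m_em[j] = np.array(lines[i].split(), dtype=float)
        i += 1
    if lines[i] != "transitions":
        raise InputError(f"{path}: malformed profile (expected transitions block)")
    i += 1
    trans = np.zeros((n + 1, 3, 3))
    for j in range(n + 1):
        trans[j] = np.array(lines[i].split(), dtype=float).reshape(3, 3)
        i += 1
    return ProfileModel(
        family=header["family"],
        n_match=n,
        match_emissions=m_em,
        insert_emissions=np.array(header["insert_emissions"].split(), dtype=float),
        transitions=trans,
        background=np.array(header["background"].split(), dtype=float),
    )
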