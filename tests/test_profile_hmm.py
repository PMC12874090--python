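import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from hgscan.core_align import ProteinRecord
from hgscan.errors import CalibrationError, InputError, ProfileBuildError
from hgscan.profile_hmm import (
    MSA,
    EvalueCalibration,
    _scoring_arrays,
    build_profile,
    calibrate_evalue,
    encode_sequence,
    read_profile,
    sample_background_sequences,
    score_sequence,
    search_catalog,
    viterbi_scores,
    write_profile,
)

from conftest import make_record, random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def msa_of(*rows):
    return MSA(rows=tuple((f"r{i}", s) for i, s in enumerate(rows)))


class TestBuildProfile:
    def test_identical_ungapped_rows(self):
        p = build_profile(msa_of("ACDE", "ACDE", "ACDE"), "hgcA")
        assert p.n_match == 4
        for j, res in enumerate("ACDE", start=1):
            assert AA[np.argmax(p.match_emissions[j])] == res
            # 3 observations of one residue: (3+1)/(3+20)
            assert p.match_emissions[j].max() == pytest.approx(4 / 23)

    def test_majority_gap_column_is_not_match(self):
        p = build_profile(msa_of("A-C", "AAC", "A-C"), "hgcA")
        assert p.n_match == 2  # middle column is 66% gaps

    def test_half_gap_column_is_not_match(self):
        p = build_profile(msa_of("A-C", "AAC", "A-C", "AAC"), "hgcA")
        assert p.n_match == 2  # exactly 50% gaps: excluded by the < 50% rule

    def test_laplace_pseudocount_formula(self):
        # match column with 2 residues observed out of 3 rows
        p = build_profile(msa_of("AC", "A-", "AC"), "hgcA")
        assert p.match_emissions[2][AA.index("C")] == pytest.approx((2 + 1) / (2 + 20))
        assert p.match_emissions[2][AA.index("W")] == pytest.approx(1 / 22)

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ProfileBuildError):
            build_profile(msa_of("--", "--"), "hgcA")

    def test_probability_vectors_normalized(self, hgca_profile):
        p = hgca_profile
        assert np.abs(p.match_emissions[1:].sum(axis=1) - 1).max() < 1e-9
        assert abs(p.insert_emissions.sum() - 1) < 1e-9
        assert abs(p.background.sum() - 1) < 1e-9
        assert np.abs(p.transitions.sum(axis=2) - 1).max() < 1e-9
        assert (p.match_emissions[1:] > 0).all()

    def test_ragged_msa_rejected(self):
        with pytest.raises(InputError):
            msa_of("AC", "ACD")


# ---------------------------------------------------------------------------
# scoring

def oracle_forward_two_state(profile, sequence):
    """Hand enumeration of every scoring path for a 2-match-state profile
    and a length-2 sequence, under the local entry/exit semantics."""
    assert profile.n_match == 2 and len(sequence) == 2
    m_em, i_em, t, entry = _scoring_arrays(profile)
    x = encode_sequence(sequence)
    M, I, D = 0, 1, 2
    paths = [
        # N emits x0; enter M_j emits x1; exit
        entry + m_em[1, x[1]] + entry,
        entry + m_em[2, x[1]] + entry,
        # enter M_j emits x0; exit; C emits x1
        entry + m_em[1, x[0]] + entry,
        entry + m_em[2, x[0]] + entry,
        # enter M_1 emits x0; M_1 -> M_2 emits x1; exit
        entry + m_em[1, x[0]] + t[1, M, M] + m_em[2, x[1]] + entry,
    ]
    return math.log2(sum(2.0**p for p in paths))


class TestScoring:
    def test_forward_at_least_viterbi(self, hgca_profile):
        rng = np.random.default_rng(0)
        for L in (10, 50, 200):
            rec = make_record(random_protein(rng, L))
            v, f = score_sequence(hgca_profile, rec)
            assert f >= v
            assert math.isfinite(v) and math.isfinite(f)

    def test_forward_matches_path_enumeration(self):
        profile = build_profile(msa_of("CW", "CW", "CF"), "hgcA")
        assert profile.n_match == 2
        rng = np.random.default_rng(3)
        for seq in ("CW", "WC", "AA", random_protein(rng, 2)):
            _, fwd = score_sequence(profile, make_record(seq))
            assert fwd == pytest.approx(oracle_forward_two_state(profile, seq), abs=1e-9)

    def test_reference_scores_above_its_shuffles(self, families, hgca_profile):
        rid, seq = families["hgcA"].msa.rows[0]
        v_ref, _ = score_sequence(hgca_profile, make_record(seq))
        rng = np.random.default_rng(8)
        shuffled = []
        for _ in range(20):
            arr = list(seq)
            rng.shuffle(arr)
            v, _ = score_sequence(hgca_profile, make_record("".join(arr)))
            shuffled.append(v)
        assert v_ref > np.median(shuffled)

    def test_x_residue_scores_finite(self, hgca_profile):
        v, f = score_sequence(hgca_profile, make_record("XXXXAXXCXX"))
        assert math.isfinite(v) and math.isfinite(f)

    def test_self_profile_beats_null_99th_percentile(self):
        rng = np.random.default_rng(12)
        seq = random_protein(rng, 60)
        profile = build_profile(msa_of(seq, seq, seq), "hgcA")
        v_self, _ = score_sequence(profile, make_record(seq))
        nulls = viterbi_scores(
            profile,
            [make_record(random_protein(rng, 60), f"n{i}") for i in range(200)],
        )
        assert v_self > np.percentile(nulls, 99)


# ---------------------------------------------------------------------------
# calibration and search

class TestCalibration:
    def test_evalue_monotone_in_score(self, hgca_profile):
        calib = calibrate_evalue(hgca_profile, [100, 150, 200], n_null=100, seed=0)
        assert calib.evalue(50.0, 1000) < calib.evalue(10.0, 1000)

    def test_threshold_application(self):
        calib = EvalueCalibration(mu=0.0, lam=1.0, n_null=100, seed=0)
        # a hit at E = 1e-6 passes 1e-5 but fails 1e-10
        evalue = 1e-6
        assert evalue <= 1e-5
        assert not evalue <= 1e-10

    def test_self_consistency_at_e1(self, hgca_profile):
        n_null = 500
        calib = calibrate_evalue(hgca_profile, [160] * 10, n_null=n_null, seed=21)
        rng = np.random.default_rng(22)
        seqs = sample_background_sequences(
            hgca_profile.background, np.full(n_null, 160), rng
        )
        scores = viterbi_scores(
            hgca_profile, [make_record(s, f"n{i}") for i, s in enumerate(seqs)]
        )
        evalues = n_null * gumbel_r.sf(scores, calib.mu, calib.lam)
        # expect ~1 null with E <= 1; allow 3*sqrt(1)
        assert np.sum(evalues <= 1.0) <= 4

    def test_too_few_nulls_rejected(self, hgca_profile):
        with pytest.raises(CalibrationError):
            calibrate_evalue(hgca_profile, [100], n_null=50, seed=0)

    def test_bad_length_distribution(self, hgca_profile):
        with pytest.raises(InputError):
            calibrate_evalue(hgca_profile, [], n_null=100, seed=0)


@pytest.fixture(scope="module")
def planted_catalog(families):
    """Reference-derived sequences (<=10% mutations) plus pure decoys."""
    rng = np.random.default_rng(33)
    records = []
    for k in range(30):
        ref, _ = families["hgcA"].references[k % len(families["hgcA"].references)]
        seq = list(ref.sequence)
        for pos in rng.choice(len(seq), size=len(seq) // 10, replace=False):
            seq[pos] = random_protein(rng, 1)
        records.append(make_record("".join(seq), f"planted{k:02d}"))
    for k in range(300):
        records.append(
            make_record(random_protein(rng, int(rng.integers(100, 400))), f"decoy{k:03d}")
        )
    return records


@pytest.fixture(scope="module")
def calib(hgca_profile, planted_catalog):
    return calibrate_evalue(
        hgca_profile, [r.length for r in planted_catalog], n_null=500, seed=5
    )


class TestSearch:
    def test_planted_all_recovered(self, hgca_profile, calib, planted_catalog):
        hits = search_catalog(hgca_profile, calib, planted_catalog, 1e-5)
        hit_ids = {h.record_id for h in hits}
        assert {f"planted{k:02d}" for k in range(30)} <= hit_ids

    def test_no_decoy_hits(self, hgca_profile, calib, planted_catalog):
        hits = search_catalog(hgca_profile, calib, planted_catalog, 1e-5)
        assert not any(h.record_id.startswith("decoy") for h in hits)

    def test_threshold_nesting(self, hgca_profile, calib, planted_catalog):
        for t1, t2 in ((1e-10, 1e-5), (1e-5, 1e-2), (1e-8, 1.0)):
            h1 = {h.record_id for h in search_catalog(hgca_profile, calib, planted_catalog, t1)}
            h2 = {h.record_id for h in search_catalog(hgca_profile, calib, planted_catalog, t2)}
            assert h1 <= h2

    def test_sorted_by_evalue_then_id(self, hgca_profile, calib, planted_catalog):
        hits = search_catalog(hgca_profile, calib, planted_catalog, 1.0)
        keys = [(h.evalue, h.record_id) for h in hits]
        assert keys == sorted(keys)

    def test_empty_catalog(self, hgca_profile, calib):
        assert search_catalog(hgca_profile, calib, [], 1e-5) == []

    def test_bad_threshold(self, hgca_profile, calib, planted_catalog):
        with pytest.raises(InputError):
            search_catalog(hgca_profile, calib, planted_catalog, 0.0)


# ---------------------------------------------------------------------------
# serialization

def test_profile_roundtrip_bit_exact(tmp_path, profiles):
    for fam, profile in profiles.items():
        p1 = tmp_path / f"{fam}.txt"
        p2 = tmp_path / f"{fam}.again.txt"
        write_profile(profile, p1)
        restored = read_profile(p1)
        write_profile(restored, p2)
        assert p1.read_text() == p2.read_text()
        assert restored.family == profile.family
        assert np.array_equal(restored.match_emissions, profile.match_emissions)
        assert np.array_equal(restored.transitions, profile.transitions)


def test_profile_reader_rejects_garbage(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("not a profile\n")
    with pytest.raises(InputError):
        read_profile(path)
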