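from __future__ import annotations

import numpy as np
import pytest

from vesipred import (
    ProfileFormatError,
    PSSMProfile,
    SyntheticDatasetSpec,
    normalize_pssm,
    parse_pssm,
    read_fasta,
    read_profile_tsv,
    simulate_profiles,
    write_profile_tsv,
    write_pssm,
)
from vesipred.profile_io import AA_ORDER


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">a\nACDE\n")
        seqs = read_fasta(p)
        assert len(seqs) == 1
        assert seqs[0].id == "a"
        assert seqs[0].residues == "ACDE"

    def test_order_preserved_and_uppercased(self, tmp_path):
        p = tmp_path / "three.fasta"
        p.write_text(">x\nacd\n>y\nWVY\n>z\nmkl\n")
        seqs = read_fasta(p)
        assert [s.id for s in seqs] == ["x", "y", "z"]
        assert seqs[0].residues == "ACD"
        assert seqs[2].residues == "MKL"

    def test_illegal_residue_names_record_and_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nAC1E\n")
        with pytest.raises(ProfileFormatError, match=r"'a'.*position 3"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ProfileFormatError):
            read_fasta(p)

    def test_permissive_maps_ambiguity_codes_to_x(self, tmp_path):
        p = tmp_path / "amb.fasta"
        p.write_text(">a\nACXBZU\n")
        with pytest.raises(ProfileFormatError):
            read_fasta(p)
        seqs = read_fasta(p, permissive=True)
        assert seqs[0].residues == "ACXXXX"


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _ascii_pssm(rows: list[list[int]], residues: str = None, extra_cols=None) -> str:
    residues = residues or "A" * len(rows)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted",
        "            " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER),
    ]
    for i, row in enumerate(rows):
        right = extra_cols[i] if extra_cols else [0] * 20
        lines.append(
            f"{i + 1:5d} {residues[i]} "
            + " ".join(str(v) for v in row)
            + " "
            + " ".join(str(v) for v in right)
            + " 0.36 0.12"
        )
    lines += ["", "                      K         Lambda"]
    return "\n".join(lines) + "\n"


class TestParsePSSM:
    # hand-written 4-residue fixture with distinctive integers
    FIXTURE_ROWS = [
        [(i * 7 + j * 3) % 11 - 3 for j in range(20)] for i in range(4)
    ]

    def test_fixture_values_match_field_by_field(self, tmp_path):
        p = tmp_path / "fix.pssm"
        p.write_text(_ascii_pssm(self.FIXTURE_ROWS, residues="MKLV"))
        prof = parse_pssm(p)
        assert prof.scores.shape == (4, 20)
        assert not prof.normalized
        assert prof.residues == "MKLV"
        for i in range(4):
            for j in range(20):
                assert prof.scores[i, j] == self.FIXTURE_ROWS[i][j]

    def test_trailing_percentage_columns_discarded(self, tmp_path):
        # 21st-40th columns differ from 1st-20th; only the first 20 kept
        extra = [[99] * 20 for _ in range(4)]
        p = tmp_path / "fix40.pssm"
        p.write_text(_ascii_pssm(self.FIXTURE_ROWS, extra_cols=extra))
        prof = parse_pssm(p)
        assert prof.scores.max() <= 7
        np.testing.assert_array_equal(prof.scores, np.array(self.FIXTURE_ROWS))

    def test_truncated_row_errors_with_line_number(self, tmp_path):
        text = _ascii_pssm(self.FIXTURE_ROWS)
        lines = text.splitlines()
        lines[5] = " ".join(lines[5].split()[:12])  # truncate the 3rd body row
        p = tmp_path / "trunc.pssm"
        p.write_text("\n".join(lines))
        with pytest.raises(ProfileFormatError, match=r":6:"):
            parse_pssm(p)

    def test_empty_body_rejected(self, tmp_path):
        p = tmp_path / "empty.pssm"
        p.write_text("Last position-specific scoring matrix\n\n")
        with pytest.raises(ProfileFormatError, match="no PSSM matrix rows"):
            parse_pssm(p)

    def test_parse_write_parse_round_trip(self, tmp_path):
        p1 = tmp_path / "a.pssm"
        p1.write_text(_ascii_pssm(self.FIXTURE_ROWS, residues="ACDE"))
        prof = parse_pssm(p1)
        p2 = tmp_path / "b.pssm"
        write_pssm(prof, p2)
        again = parse_pssm(p2)
        np.testing.assert_array_equal(prof.scores, again.scores)
        assert again.residues == "ACDE"

    def test_tsv_round_trip(self, tmp_path):
        prof = PSSMProfile(id="t", scores=np.arange(40.0).reshape(2, 20))
        path = tmp_path / "t.tsv"
        write_profile_tsv(prof, path)
        again = read_profile_tsv(path)
        np.testing.assert_array_equal(prof.scores, again.scores)
        assert again.id == "t"
        assert not again.normalized


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_logistic_at_zero_is_half(self):
        prof = PSSMProfile(id="z", scores=np.zeros((3, 20)))
        assert np.allclose(normalize_pssm(prof).scores, 0.5)

    def test_symmetric_entries_sum_to_one(self):
        scores = np.zeros((1, 20))
        scores[0, 0], scores[0, 1] = -2.5, 2.5
        out = normalize_pssm(PSSMProfile(id="s", scores=scores)).scores
        assert out[0, 0] + out[0, 1] == pytest.approx(1.0)

    def test_large_negatives_land_near_zero(self):
        prof = PSSMProfile(id="n", scores=np.full((5, 20), -8.0))
        out = normalize_pssm(prof).scores
        assert ((out > 0) & (out < 0.01)).all()

    def test_double_normalization_forbidden(self):
        prof = normalize_pssm(PSSMProfile(id="d", scores=np.zeros((2, 20))))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_pssm(prof)

    def test_monotone_elementwise(self, rng):
        x = rng.normal(0, 3, size=(6, 20))
        y = x + np.abs(rng.normal(0, 1, size=(6, 20))) + 1e-6
        nx_ = normalize_pssm(PSSMProfile(id="x", scores=x)).scores
        ny = normalize_pssm(PSSMProfile(id="y", scores=y)).scores
        assert (nx_ < ny).all()


# ---------------------------------------------------------------------------
# Synthetic profiles
# ---------------------------------------------------------------------------

class TestSimulateProfiles:
    def test_reproducible_given_seed(self):
        spec = SyntheticDatasetSpec(n_positive=3, n_negative=4, seed=1)
        a, la = simulate_profiles(spec)
        b, lb = simulate_profiles(spec)
        assert len(a) == len(b) == 7
        np.testing.assert_array_equal(la, lb)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.scores, pb.scores)

    def test_different_seeds_differ(self):
        a, _ = simulate_profiles(SyntheticDatasetSpec(3, 3, seed=1))
        b, _ = simulate_profiles(SyntheticDatasetSpec(3, 3, seed=2))
        assert any(
            pa.scores.shape != pb.scores.shape or not np.array_equal(pa.scores, pb.scores)
            for pa, pb in zip(a, b)
        )

    def test_counts_and_labels(self):
        profiles, labels = simulate_profiles(
            SyntheticDatasetSpec(n_positive=3, n_negative=7, seed=0)
        )
        assert len(profiles) == 10
        assert labels.sum() == 3
        assert labels[:3].all() and not labels[3:].any()

    def test_null_spec_gives_matched_column_means(self):
        # with no class effects the shifted-column means agree to sampling noise
        spec = SyntheticDatasetSpec(
            n_positive=150, n_negative=150, class_shift=0.0, transition_bias=0.0,
            seed=3,
        )
        profiles, labels = simulate_profiles(spec)
        pos_means = np.concatenate(
            [p.scores[:, :5].ravel() for p, l in zip(profiles, labels) if l == 1]
        )
        neg_means = np.concatenate(
            [p.scores[:, :5].ravel() for p, l in zip(profiles, labels) if l == 0]
        )
        # raw scores have sd ~3; the two class means differ by << 1
        assert abs(pos_means.mean() - neg_means.mean()) < 0.1

    def test_class_shift_moves_designated_columns(self):
        spec = SyntheticDatasetSpec(n_positive=80, n_negative=80, class_shift=2.0,
                                    transition_bias=0.0, seed=4)
        profiles, labels = simulate_profiles(spec)
        pos = np.concatenate([p.scores[:, :5].ravel() for p, l in zip(profiles, labels) if l])
        neg = np.concatenate([p.scores[:, :5].ravel() for p, l in zip(profiles, labels) if not l])
        assert pos.mean() - neg.mean() > 1.0

    def test_transition_bias_raises_argmax_repeats(self):
        spec = SyntheticDatasetSpec(n_positive=60, n_negative=60, class_shift=0.0,
                                    transition_bias=0.8, seed=6)
        profiles, labels = simulate_profiles(spec)

        def repeat_rate(ps):
            reps = tot = 0
            for p in ps:
                am = np.argmax(p.scores, axis=1)
                reps += (am[1:] == am[:-1]).sum()
                tot += len(am) - 1
            return reps / tot

        pos_rate = repeat_rate([p for p, l in zip(profiles, labels) if l])
        neg_rate = repeat_rate([p for p, l in zip(profiles, labels) if not l])
        assert pos_rate > 0.6
        assert neg_rate < 0.2

    def test_min_length_guard(self):
        with pytest.raises(ValueError, match="minimum profile length"):
            SyntheticDatasetSpec(n_positive=1, n_negative=1, length_range=(5, 20))

    def test_scores_within_blosum_like_range(self):
        profiles, _ = simulate_profiles(SyntheticDatasetSpec(5, 5, seed=9))
        for p in profiles:
            assert p.scores.min() >= -10 and p.scores.max() <= 13
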