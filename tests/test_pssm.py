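"""ASCII profile parsing and the three 400-D evolutionary encoders."""

import numpy as np
import pytest

from druggability.pssm import (
    PSIBLAST_AA_ORDER,
    FeatureBlock,
    PSSMParseError,
    PSSMatrix,
    concat_features,
    dpc_pssm,
    ksb_pssm,
    parse_ascii_pssm,
    s_fpssm,
    write_ascii_pssm,
)
from druggability.sequence_io import ValidationError

from conftest import random_pssm


def unit_rows(positions: list[int], L: int) -> np.ndarray:
    """Rows that are unit indicators e_i (1-based column index)."""
    m = np.zeros((L, 20), dtype=np.int64)
    for k, i in enumerate(positions):
        m[k, i - 1] = 1
    return m


def dpc_oracle(p: np.ndarray) -> np.ndarray:
    """Literal triple-loop transcription of the dipeptide encoder."""
    L = p.shape[0]
    y = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for k in range(L - 1):
                y[i, j] += p[k, i] * p[k + 1, j]
    return (y / (L - 1)).ravel()


def ksb_oracle(p: np.ndarray, k: int) -> np.ndarray:
    L = p.shape[0]
    y = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for t in range(L - k):
                y[i, j] += p[t, i] * p[t + k, j]
    return y.ravel()


def sfpssm_oracle(residues: str, p: np.ndarray, aa_order: str) -> np.ndarray:
    fp = np.maximum(p, 0)
    y = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for k, r in enumerate(residues):
                if r == aa_order[i]:
                    y[i, j] += fp[k, j]
    return y.ravel()


class TestParser:
    def test_round_trips_synthetic_profile(self, tmp_path):
        m = random_pssm(np.random.default_rng(0), 7)
        path = tmp_path / "p.pssm"
        write_ascii_pssm(m, path)
        back = parse_ascii_pssm(path)
        assert back.residues == m.residues
        assert back.aa_order == m.aa_order
        np.testing.assert_array_equal(back.scores, m.scores)

    def test_truncated_row_is_parse_error_naming_line(self, tmp_path):
        m = random_pssm(np.random.default_rng(1), 4)
        path = tmp_path / "p.pssm"
        write_ascii_pssm(m, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5][:40]  # cut a data row mid-way
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PSSMParseError, match="line 6"):
            parse_ascii_pssm(path)

    def test_non_consecutive_positions_rejected(self, tmp_path):
        m = random_pssm(np.random.default_rng(2), 3)
        path = tmp_path / "p.pssm"
        write_ascii_pssm(m, path)
        text = path.read_text().replace("\n    2 ", "\n    5 ")
        path.write_text(text)
        with pytest.raises(PSSMParseError, match="position"):
            parse_ascii_pssm(path)

    def test_residue_column_is_copied(self, tmp_path):
        m = PSSMatrix(residues="ACD", scores=np.zeros((3, 20), dtype=int))
        path = tmp_path / "p.pssm"
        write_ascii_pssm(m, path)
        assert parse_ascii_pssm(path).residues == "ACD"


class TestDPC:
    def test_zero_profile_gives_zero_vector(self):
        m = PSSMatrix(residues="AAAAA", scores=np.zeros((5, 20), dtype=int))
        assert not dpc_pssm(m).values.any()

    def test_unit_indicator_rows(self):
        # rows e1, e2, e1: adjacent products hit (1,2) and (2,1) once each, /(L-1)=2
        m = PSSMatrix(residues="ACD", scores=unit_rows([1, 2, 1], 3))
        b = dpc_pssm(m)
        assert b.values[b.flat_position(1, 2)] == pytest.approx(0.5)
        assert b.values[b.flat_position(2, 1)] == pytest.approx(0.5)
        assert np.count_nonzero(b.values) == 2

    def test_block_has_400_entries(self):
        m = random_pssm(np.random.default_rng(3), 10)
        assert dpc_pssm(m).values.shape == (400,)

    def test_single_row_profile_is_degenerate(self):
        m = PSSMatrix(residues="A", scores=np.zeros((1, 20), dtype=int))
        with pytest.raises(ValidationError):
            dpc_pssm(m)

    def test_appending_zero_row_rescales_by_length_ratio(self):
        rng = np.random.default_rng(4)
        m = random_pssm(rng, 6)
        extended = PSSMatrix(residues=m.residues + "A",
                             scores=np.vstack([m.scores, np.zeros((1, 20), dtype=int)]))
        L = m.length
        np.testing.assert_allclose(
            dpc_pssm(extended).values, dpc_pssm(m).values * (L - 1) / L)


class TestKSB:
    def test_unit_indicator_rows_k3(self):
        m = PSSMatrix(residues="ACDEF", scores=unit_rows([1, 2, 3, 4, 1], 5))
        b = ksb_pssm(m, k=3)
        assert b.values[b.flat_position(1, 4)] == 1
        assert b.values[b.flat_position(2, 1)] == 1
        assert np.count_nonzero(b.values) == 2

    def test_short_sequence_warns_and_returns_zeros(self):
        m = PSSMatrix(residues="ACD", scores=unit_rows([1, 2, 3], 3))
        with pytest.warns(UserWarning, match="empty sum"):
            b = ksb_pssm(m, k=3)
        assert not b.values.any()

    def test_bilinearity_doubling_scores_quadruples_output(self):
        m = random_pssm(np.random.default_rng(5), 9)
        doubled = PSSMatrix(residues=m.residues, scores=m.scores * 2, aa_order=m.aa_order)
        np.testing.assert_allclose(ksb_pssm(doubled).values, 4 * ksb_pssm(m).values)

    def test_invalid_gap_rejected(self):
        m = random_pssm(np.random.default_rng(6), 5)
        with pytest.raises(ValidationError):
            ksb_pssm(m, k=0)


class TestSFPSSM:
    def test_all_negative_scores_filtered_to_zero(self):
        m = PSSMatrix(residues="ACDE", scores=-np.ones((4, 20), dtype=int))
        assert not s_fpssm(m).values.any()

    def test_two_residue_worked_example(self):
        scores = np.zeros((2, 20), dtype=int)
        scores[0, :2] = [2, -1]
        scores[1, :2] = [-3, 5]
        m = PSSMatrix(residues="AC", scores=scores)  # aa_order starts A, R, N, D, C
        b = s_fpssm(m)
        i_A = PSIBLAST_AA_ORDER.index("A") + 1
        i_C = PSIBLAST_AA_ORDER.index("C") + 1
        assert b.values[b.flat_position(i_A, 1)] == 2
        assert b.values[b.flat_position(i_C, 2)] == 5
        assert np.count_nonzero(b.values) == 2

    def test_values_are_non_negative_and_x_contributes_nothing(self):
        rng = np.random.default_rng(7)
        m = random_pssm(rng, 12)
        with_x = PSSMatrix(residues="X" + m.residues[1:], scores=m.scores,
                           aa_order=m.aa_order)
        b = s_fpssm(with_x)
        assert (b.values >= 0).all()
        # the X row's scores vanish from its former residue's row
        i = m.aa_order.index(m.residues[0])
        removed = np.maximum(m.scores[0], 0)
        np.testing.assert_allclose(s_fpssm(m).values[20 * i : 20 * i + 20]
                                   - b.values[20 * i : 20 * i + 20], removed)

    def test_single_residue_type_concentrates_one_row(self):
        rng = np.random.default_rng(8)
        m = PSSMatrix(residues="GGGG", scores=rng.integers(-5, 6, size=(4, 20)))
        b = s_fpssm(m)
        i = PSIBLAST_AA_ORDER.index("G")
        mass = b.values.reshape(20, 20)
        assert not np.delete(mass, i, axis=0).any()


class TestEncodersMatchOracles:
    @pytest.mark.parametrize("trial", range(20))
    def test_all_three_encoders_equal_triple_loop_oracles(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = random_pssm(rng, int(rng.integers(4, 61)))
        p = m.scores.astype(float)
        np.testing.assert_array_equal(dpc_pssm(m).values, dpc_oracle(p))
        np.testing.assert_array_equal(ksb_pssm(m, k=3).values, ksb_oracle(p, 3))
        np.testing.assert_array_equal(
            s_fpssm(m).values, sfpssm_oracle(m.residues, p, m.aa_order))


class TestConcat:
    def test_sentinel_blocks_keep_order(self):
        blocks = [FeatureBlock(name="KSB-PSSM", values=np.full(400, 2.0)),
                  FeatureBlock(name="S-FPSSM", values=np.full(400, 3.0)),
                  FeatureBlock(name="DPC-PSSM", values=np.full(400, 1.0))]
        v = concat_features(blocks)
        assert v.values.shape == (1200,)
        assert (v.values[:400] == 1).all()
        assert (v.values[400:800] == 2).all()
        assert (v.values[800:] == 3).all()
        assert v.group_tags[0] == "DPC-PSSM" and v.group_tags[-1] == "S-FPSSM"

    def test_zero_blocks_concatenate_to_zero(self):
        blocks = [FeatureBlock(name=n, values=np.zeros(400))
                  for n in ("DPC-PSSM", "KSB-PSSM", "S-FPSSM")]
        assert not concat_features(blocks).values.any()

    def test_duplicate_and_missing_blocks_rejected(self):
        b = FeatureBlock(name="DPC-PSSM", values=np.zeros(400))
        with pytest.raises(ValidationError, match="duplicate"):
            concat_features([b, b])
        with pytest.raises(ValidationError, match="missing"):
            concat_features([b])
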