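"""ΔΔG I/O, burial, and the surrogate scoring function."""

import numpy as np
import pytest

import foldscan as fs
from foldscan.ddg_engine import (
    KD_HYDROPATHY,
    RESIDUE_VOLUME,
    StructureModel,
    StructureResidue,
    read_ddg_table,
    write_ddg_table,
)


def _linear_chain(letters, spacing=3.8):
    return StructureModel(
        residues=[
            StructureResidue("A", i + 1, aa, (i * spacing, 0.0, 0.0))
            for i, aa in enumerate(letters)
        ]
    )


class TestDdgTableIO:
    def test_roundtrip_preserves_cells(self, tmp_path, toy_sequence, toy_ddg):
        path = tmp_path / "ddg.tsv"
        write_ddg_table(toy_ddg, path)
        back = read_ddg_table(path, toy_sequence)
        np.testing.assert_allclose(back.values, toy_ddg.values, rtol=1e-6)
        assert back.wild_type == toy_ddg.wild_type

    def test_wt_mismatch_rejected(self, tmp_path, toy_ddg):
        path = tmp_path / "ddg.tsv"
        write_ddg_table(toy_ddg, path)
        other = fs.ProteinSequence(id="x", residues="AGDG")
        with pytest.raises(ValueError, match="position 2"):
            read_ddg_table(path, other)

    def test_missing_row_rejected(self, tmp_path, toy_sequence, toy_ddg):
        path = tmp_path / "ddg.tsv"
        write_ddg_table(toy_ddg, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="positions do not cover"):
            read_ddg_table(path, toy_sequence)

    def test_duplicate_position_rejected(self, tmp_path, toy_sequence, toy_ddg):
        path = tmp_path / "ddg.tsv"
        write_ddg_table(toy_ddg, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines + [lines[-1]]) + "\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_ddg_table(path, toy_sequence)


class TestPdbReader:
    def test_reads_fragment_with_cb_representative(self, pdb_fragment):
        model = fs.read_pdb_minimal(pdb_fragment)
        assert len(model) == 3
        assert model.sequence() == "AGL"
        # Ala and Leu use Cβ; Gly falls back to Cα
        assert model.residues[0].coord == (2.0, 1.4, 0.0)
        assert model.residues[1].coord == (5.258, 0.0, 0.0)
        assert model.residues[2].coord == (9.6, 1.4, 0.2)

    def test_hetatm_only_is_an_error(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00\n"
        )
        with pytest.raises(ValueError, match="no ATOM records"):
            fs.read_pdb_minimal(path)

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "ins.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1A      0.000   0.000   0.000  1.00  0.00\n"
        )
        with pytest.raises(ValueError, match="insertion code"):
            fs.read_pdb_minimal(path)


class TestBurial:
    def test_single_residue_has_zero_burial(self):
        model = _linear_chain("A")
        assert fs.contact_burial(model, 1, fs.SurrogateParams()) == 0.0

    def test_adjacent_residues_excluded(self):
        # 3 residues in a 3.8 Å line: all pairwise within 10 Å, but ±1 excluded,
        # so only the (1,3) pair at 7.6 Å counts.
        model = _linear_chain("AAA")
        params = fs.SurrogateParams()
        assert fs.contact_burial(model, 1, params) == pytest.approx(1 / 20)
        assert fs.contact_burial(model, 2, params) == 0.0

    def test_saturation_at_n_max(self):
        # 30 residues stacked within one contact sphere
        model = StructureModel(
            residues=[
                StructureResidue("A", i + 1, "A", (0.1 * i, 0.0, 0.0))
                for i in range(30)
            ]
        )
        assert fs.contact_burial(model, 15, fs.SurrogateParams()) == 1.0

    def test_fractional_count(self):
        params = fs.SurrogateParams(n_max=20)
        # residue 1 with exactly 5 qualifying neighbours
        residues = [StructureResidue("A", 1, "A", (0.0, 0.0, 0.0))]
        residues += [
            StructureResidue("A", k, "A", (3.0 + 0.1 * k, 0.0, 0.0))
            for k in range(3, 8)
        ]
        model = StructureModel(residues=residues)
        assert fs.contact_burial(model, 1, params) == pytest.approx(0.25)


class TestSurrogate:
    def test_identity_diagonal_exactly_zero_without_noise(self, small_scan):
        seq, structure, _, _ = small_scan
        ddg = fs.surrogate_ddg(seq, structure, fs.SurrogateParams())
        assert np.all(ddg.identity_values() == 0.0)

    def test_exposed_residue_scores_zero_for_non_proline(self):
        # widely spaced chain: burial 0 everywhere
        seq = fs.ProteinSequence(id="x", residues="LKV")
        model = _linear_chain("LKV", spacing=25.0)
        ddg = fs.surrogate_ddg(seq, model, fs.SurrogateParams())
        non_p = [i for i, aa in enumerate(fs.AMINO_ACIDS) if aa != "P"]
        assert np.all(ddg.values[:, non_p] == 0.0)
        # proline introduction still penalized, burial-independent
        assert ddg.lookup(1, "P") == pytest.approx(1.0)

    def test_hand_computed_buried_substitution(self):
        """L→D at burial 1 with default weights: 0.5·7.3 + 0.5·0.556 ≈ 3.93 kcal/mol."""
        expected = 0.5 * (KD_HYDROPATHY["L"] - KD_HYDROPATHY["D"]) + 0.5 * abs(
            RESIDUE_VOLUME["D"] - RESIDUE_VOLUME["L"]
        ) / 100.0
        assert expected == pytest.approx(3.928, abs=1e-3)
        # realize burial 1 with a dense cluster around residue 1
        residues = [StructureResidue("A", 1, "L", (0.0, 0.0, 0.0))]
        rng = np.random.default_rng(0)
        for k in range(3, 28):
            residues.append(
                StructureResidue("A", k, "A", tuple(rng.uniform(-4, 4, 3)))
            )
        model = StructureModel(residues=residues)
        seq = fs.ProteinSequence(id="x", residues=model.sequence())
        params = fs.SurrogateParams()
        assert fs.contact_burial(model, 1, params) == 1.0
        ddg = fs.surrogate_ddg(seq, model, params)
        assert ddg.lookup(1, "D") == pytest.approx(expected)

    def test_deterministic_given_seed(self, small_scan):
        seq, structure, _, _ = small_scan
        params = fs.SurrogateParams(identity_noise_sd=0.05, seed=11)
        a = fs.surrogate_ddg(seq, structure, params)
        b = fs.surrogate_ddg(seq, structure, params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_monotone_in_burial_for_positive_bracket(self, small_scan):
        """For the same wt→mut substitution, ΔΔG never decreases with burial
        when the hydropathy+volume bracket is positive."""
        seq, structure, burial, _ = small_scan
        ddg = fs.surrogate_ddg(seq, structure, fs.SurrogateParams())
        by_letter = {}
        for i, aa in enumerate(seq.residues):
            by_letter.setdefault(aa, []).append(i)
        checked = 0
        for aa, idxs in by_letter.items():
            if len(idxs) < 2 or aa == "W":
                continue
            i, j = min(idxs, key=lambda k: burial[k]), max(idxs, key=lambda k: burial[k])
            if burial[i] == burial[j]:
                continue
            col = fs.AMINO_ACIDS.index("W")  # most hydrophobic-loss target for most wt
            if ddg.values[j, col] > 0:
                assert ddg.values[i, col] <= ddg.values[j, col]
                checked += 1
        assert checked > 0

    def test_structure_sequence_mismatch_rejected(self, small_scan):
        seq, structure, _, _ = small_scan
        other = fs.ProteinSequence(id="x", residues="A" * seq.length)
        if other.residues != seq.residues:
            with pytest.raises(ValueError, match="mismatch"):
                fs.surrogate_ddg(other, structure, fs.SurrogateParams())
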