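import numpy as np
import pandas as pd
import pytest

from oracles import naive_ctd_scan
from pathclass.datamodel import Pathway, ProteinRecord
from pathclass.physchem import (
    HYDROPHOBICITY,
    SOLVENT_ACCESSIBILITY,
    THREE_CLASS_PROPERTIES,
    CorpusStandardizer,
    aa_composition,
    ctd,
    descriptor_matrix,
    encode_sequence,
    physchem_block,
    protein_descriptors,
)


class TestEncodeSequence:
    def test_hydrophobicity_pseudo_sequence(self):
        assert encode_sequence("GGAARRKK", HYDROPHOBICITY) == "NNNNPPPP"

    def test_empty_sequence_stays_empty(self):
        assert encode_sequence("", HYDROPHOBICITY) == ""

    def test_single_class_sequence_is_constant(self):
        assert encode_sequence("CCLL", HYDROPHOBICITY) == "HHHH"

    def test_every_alphabet_covers_all_residues(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        for alphabet in THREE_CLASS_PROPERTIES + (SOLVENT_ACCESSIBILITY,):
            coded = encode_sequence(seq, alphabet)
            assert len(coded) == 20
            assert set(coded) <= set(alphabet.classes)


class TestCTD:
    def test_worked_example(self):
        """C, T and D of the pseudo-sequence NNNNPPPP."""
        d = ctd("NNNNPPPP", "PNH")
        assert d["C.P"] == pytest.approx(50.0)
        assert d["C.N"] == pytest.approx(50.0)
        assert d["C.H"] == pytest.approx(0.0)
        assert d["T.PN"] == pytest.approx(100.0 / 7)
        assert [d[f"D.P.{q}"] for q in ("first", "q25", "q50", "q75", "last")] == \
            pytest.approx([62.5, 62.5, 75.0, 87.5, 100.0])

    def test_single_residue_transitions_zero(self):
        d = ctd("P", "PNH")
        assert d["T.PN"] == 0.0 and d["T.PH"] == 0.0 and d["T.NH"] == 0.0

    def test_three_class_descriptor_count(self):
        assert len(ctd("PNH", "PNH")) == 21

    def test_accessibility_restriction(self):
        assert len(ctd("HEHE", "HE", d_classes="H")) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_position_scanning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            L = int(rng.integers(1, 40))
            coded = "".join(rng.choice(list("PNH"), size=L))
            mine = ctd(coded, "PNH")
            ref = naive_ctd_scan(coded, "PNH")
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_compositions_sum_to_100(self, rng):
        coded = "".join(rng.choice(list("PNH"), size=33))
        d = ctd(coded, "PNH")
        assert d["C.P"] + d["C.N"] + d["C.H"] == pytest.approx(100.0)


class TestAAComposition:
    def test_homopolymer(self):
        d = aa_composition("AAAA")
        assert d["aac.A"] == 100.0 and sum(d.values()) == pytest.approx(100.0)

    def test_uniform_quarters(self):
        d = aa_composition("ACDE")
        for r in "ACDE":
            assert d[f"aac.{r}"] == 25.0

    def test_always_normalized(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=57))
        assert sum(aa_composition(seq).values()) == pytest.approx(100.0)


class TestStandardize:
    def test_population_zscore(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        z = CorpusStandardizer.fit(m).transform(m)
        assert z["f"].tolist() == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)

    def test_constant_column_maps_to_zero(self):
        m = pd.DataFrame({"f": [5.0, 5.0, 5.0]})
        z = CorpusStandardizer.fit(m).transform(m)
        assert (z["f"] == 0.0).all()

    def test_zscored_columns_have_zero_mean_unit_std(self, rng):
        m = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        z = CorpusStandardizer.fit(m).transform(m)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_persistence_round_trip(self, tmp_path, rng):
        m = pd.DataFrame(rng.random((10, 3)), columns=list("abc"))
        std = CorpusStandardizer.fit(m)
        std.to_tsv(tmp_path / "std.tsv")
        back = CorpusStandardizer.from_tsv(tmp_path / "std.tsv")
        pd.testing.assert_frame_equal(std.transform(m), back.transform(m))


def _corpus(n, rng, prefix="p"):
    res = list("ACDEFGHIKLMNPQRSTVWY")
    return {
        f"{prefix}{i}": ProteinRecord(
            f"{prefix}{i}", "".join(rng.choice(res, size=40)), {"GO:1"}
        )
        for i in range(n)
    }


class TestProteinDescriptors:
    def test_132_descriptors(self, rng):
        rec = next(iter(_corpus(1, rng).values()))
        assert len(protein_descriptors(rec)) == 132

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty sequence"):
            protein_descriptors(ProteinRecord("x", "", {"GO:1"}))

    def test_external_coded_strings_override(self, rng):
        rec = next(iter(_corpus(1, rng).values()))
        default = protein_descriptors(rec)
        override = protein_descriptors(
            rec, ss_codes={rec.id: "H" * len(rec.sequence)}
        )
        assert override["secondary_structure.C.H"] == pytest.approx(100.0)
        assert default["aac.A"] == override["aac.A"]


class TestPhyschemBlock:
    def test_264_features_with_subblock_sizes(self, rng):
        proteins = _corpus(6, rng)
        std = CorpusStandardizer.fit(descriptor_matrix(proteins))
        standardized = std.transform(descriptor_matrix(proteins))
        pw = Pathway("pw", list(proteins)[:3], set())
        block = physchem_block(pw, standardized)
        assert len(block) == 264
        sizes = {"hydrophobicity": 0, "vdw_volume": 0, "polarity": 0,
                 "polarizability": 0, "secondary_structure": 0,
                 "solvent_accessibility": 0, "aac": 0}
        for name in block:
            sizes[name.split(".")[1]] += 1
        assert sizes == {
            "hydrophobicity": 42, "vdw_volume": 42, "polarity": 42,
            "polarizability": 42, "secondary_structure": 42,
            "solvent_accessibility": 14, "aac": 40,
        }

    def test_identical_proteins_mean_equals_max(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        proteins = {
            f"p{i}": ProteinRecord(f"p{i}", seq, {"GO:1"}) for i in range(3)
        }
        proteins.update(_corpus(3, rng, prefix="q"))  # corpus variety
        mat = descriptor_matrix(proteins)
        standardized = CorpusStandardizer.fit(mat).transform(mat)
        pw = Pathway("pw", ["p0", "p1", "p2"], set())
        block = physchem_block(pw, standardized)
        for name, v in block.items():
            if name.startswith("mean."):
                assert v == pytest.approx(block["max." + name[5:]], abs=1e-12)

    def test_missing_descriptor_names_protein(self, rng):
        proteins = _corpus(3, rng)
        mat = descriptor_matrix(proteins)
        standardized = CorpusStandardizer.fit(mat).transform(mat)
        pw = Pathway("pw", ["p0", "ghost"], set())
        with pytest.raises(ValueError, match="ghost"):
            physchem_block(pw, standardized)
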