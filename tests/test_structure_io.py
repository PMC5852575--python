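import io

import numpy as np
import pytest

from rnaocclusion import (
    Ensemble,
    PDBParseError,
    RadiusTable,
    Selection,
    Structure,
    TopologyError,
    assign_radii,
    read_pdb,
    resolve_selection,
    write_pdb,
)
from rnaocclusion.structure_io import BACKBONE

from conftest import make_peptide

MINIMAL = "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00\n"

TWO_MODELS = """MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.200   0.800   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.400   0.000   0.300  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.300   0.800   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.500   0.000   0.300  1.00  0.00           C
ENDMDL
END
"""

ALTLOC = """ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA AALA A   2       0.000   2.000   0.000  0.50  0.00           C
ATOM      4  CA BALA A   2       1.000   2.000   0.000  0.50  0.00           C
END
"""


class TestReadPdb:
    def test_minimal_record_infers_element_from_name(self):
        s = read_pdb(io.StringIO(MINIMAL))
        assert isinstance(s, Structure)
        assert len(s) == 1
        assert s.atoms[0].element == "C"
        assert np.allclose(s.atoms[0].coords, [11.104, 6.134, -6.504])

    def test_two_models_become_ensemble(self):
        e = read_pdb(io.StringIO(TWO_MODELS))
        assert isinstance(e, Ensemble)
        assert e.n_frames == 2 and e.n_atoms == 3

    def test_malformed_atom_line_names_line_number(self):
        bad = MINIMAL.replace("11.104", "xx.xxx")
        with pytest.raises(PDBParseError, match="line 1"):
            read_pdb(io.StringIO(bad))

    def test_inconsistent_model_atom_counts_rejected(self):
        bad = TWO_MODELS.replace(
            "ATOM      3  C   ALA A   1       2.500   0.000   0.300  1.00  0.00           C\n",
            "", 1)
        with pytest.raises(TopologyError):
            read_pdb(io.StringIO(bad))

    def test_altloc_keeps_highest_occupancy_tie_goes_to_a(self):
        s = read_pdb(io.StringIO(ALTLOC))
        assert len(s) == 2
        # residue 1: B wins on occupancy; residue 2: tie broken toward A
        assert s.atoms[0].coords[0] == pytest.approx(1.0)
        assert s.atoms[1].coords[0] == pytest.approx(0.0)

    def test_hetatm_retained_and_flagged(self):
        text = MINIMAL + (
            "HETATM    2 ZN    ZN A 900      10.000  10.000  10.000  1.00  0.00          ZN\n")
        s = read_pdb(io.StringIO(text))
        assert len(s) == 2
        assert s.atoms[1].hetero and s.atoms[1].res_name.strip() == "ZN"


class TestRoundTrip:
    def test_structure_round_trip_preserves_atoms_to_pdb_precision(self, tmp_path, rng):
        s = make_peptide(4)
        s.coords = s.coords + rng.normal(scale=2.0, size=(len(s), 3))
        path = tmp_path / "s.pdb"
        write_pdb(s, path)
        s2 = read_pdb(path)
        assert [a.atom_key for a in s2.atoms] == [a.atom_key for a in s.atoms]
        assert np.abs(s2.coords - s.coords).max() < 1e-3

    def test_ensemble_round_trip(self, tmp_path, rng):
        topo = make_peptide(2)
        frames = topo.coords[None] + rng.normal(scale=0.5, size=(3, len(topo), 3))
        ens = Ensemble(topo, frames)
        path = tmp_path / "e.pdb"
        write_pdb(ens, path)
        e2 = read_pdb(path)
        assert isinstance(e2, Ensemble) and e2.n_frames == 3
        assert np.abs(e2.frames - frames).max() < 1e-3

    def test_single_atom_file_has_one_atom_and_one_end_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        write_pdb(read_pdb(io.StringIO(MINIMAL)), path)
        lines = path.read_text().splitlines()
        assert sum(l.startswith("ATOM") for l in lines) == 1
        assert sum(l.strip() == "END" for l in lines) == 1

    def test_ensemble_written_as_model_blocks(self, tmp_path):
        e = read_pdb(io.StringIO(TWO_MODELS))
        path = tmp_path / "e.pdb"
        write_pdb(e, path)
        text = path.read_text()
        assert "MODEL        1" in text and "MODEL        2" in text

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        from rnaocclusion import CoordinateRangeError
        s = make_peptide(1)
        coords = s.coords
        coords[0, 0] = 12345.0
        s.coords = coords
        with pytest.raises(CoordinateRangeError):
            write_pdb(s, tmp_path / "bad.pdb")


class TestSelection:
    def test_backbone_selection_on_three_residue_peptide(self, peptide):
        assert len(resolve_selection(peptide, BACKBONE)) == 9

    def test_residue_range_from_305_selects_all(self):
        s = make_peptide(5, first_res=305)
        idx = resolve_selection(s, Selection(res_range=(305, None)))
        assert idx == list(range(len(s)))

    def test_absent_chain_yields_empty_list(self, peptide):
        assert resolve_selection(peptide, Selection(chains={"R"})) == []

    def test_resolution_idempotent_and_filter_order_independent(self, peptide):
        sel1 = Selection(chains={"A"}, atom_names={"CA", "N"})
        sel2 = Selection(atom_names={"N", "CA"}, chains={"A"})
        idx1 = resolve_selection(peptide, sel1)
        assert idx1 == resolve_selection(peptide, sel2)
        assert idx1 == sorted(idx1)
        sub = peptide.subset(idx1)
        assert resolve_selection(sub, sel1) == list(range(len(sub)))


class TestRadii:
    def test_carbon_gets_bondi_value(self, peptide):
        s = assign_radii(peptide, RadiusTable.bondi())
        ca = next(a for a in s.atoms if a.name == "CA")
        assert ca.radius == pytest.approx(1.70)

    def test_unknown_element_gets_default_with_warning(self):
        s = make_peptide(1)
        s.atoms[0].element = "X"
        with pytest.warns(UserWarning, match="X"):
            s2 = assign_radii(s)
        assert s2.atoms[0].radius == pytest.approx(1.50)

    def test_all_hydrogen_structure_uniform_radii(self):
        s = make_peptide(2)
        for a in s.atoms:
            a.element = "H"
        s2 = assign_radii(s)
        assert all(a.radius == pytest.approx(1.20) for a in s2.atoms)

    def test_every_atom_has_a_radius_after_assignment(self, peptide):
        s = assign_radii(peptide)
        assert np.all(s.radii > 0)

    def test_csv_round_trip(self, tmp_path):
        table = RadiusTable.bondi()
        path = tmp_path / "radii.csv"
        table.to_csv(path)
        table2 = RadiusTable.from_csv(path)
        assert table2.radii == table.radii

    def test_radii_outside_physical_band_rejected(self):
        with pytest.raises(ValueError):
            RadiusTable({"C": 4.2})
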