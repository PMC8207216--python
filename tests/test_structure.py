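"""Multi-model PDB reading, ring extraction and torsion tables."""

import numpy as np
import pytest

from puckerfit import (ResidueSelector, TorsionSet, endocyclic_torsions,
                       extract_ring, gen_torsion_set, pseudorotation_phase,
                       pucker_series, read_models, read_torsion_table,
                       write_torsion_table)
from puckerfit.exceptions import (DataQualityWarning, MissingAtomError,
                                  ResidueNotFoundError, StructureParseError)
from puckerfit.simulate import (PuckerMixtureSpec, gen_pucker_trajectory,
                                sample_pucker_phases,
                                write_ring_trajectory_pdb)

SEL = ResidueSelector(chain_id="A", residue_number=7)


class TestReadModels:
    def test_three_models_in_order(self, three_model_pdb):
        models = read_models(three_model_pdb)
        assert [m.num for m in models] == [1, 2, 3]

    def test_star_dialect_equals_primed(self, three_model_pdb,
                                        star_dialect_pdb):
        primed = extract_ring(read_models(three_model_pdb)[0], SEL)[0]
        star = extract_ring(read_models(star_dialect_pdb)[0], SEL)[0]
        for name in primed.coords:
            assert np.allclose(primed.coords[name], star.coords[name],
                               atol=1e-3)

    def test_empty_file_is_zero_models_error(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("")
        with pytest.raises(StructureParseError, match="zero models"):
            read_models(empty)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureParseError, match="not found"):
            read_models(tmp_path / "nope.pdb")


class TestExtractRing:
    def test_highest_occupancy_picks_major_and_warns(self, altloc_pdb):
        model = read_models(altloc_pdb)[0]
        with pytest.warns(DataQualityWarning, match="B"):
            rings = extract_ring(model, SEL)
        assert len(rings) == 1
        assert rings[0].altloc_id == "A"
        assert rings[0].occupancy_used == pytest.approx(0.75)

    def test_policy_all_returns_both_altlocs(self, altloc_pdb):
        model = read_models(altloc_pdb)[0]
        sel = ResidueSelector("A", 7, altloc="all")
        rings = extract_ring(model, sel)
        assert [r.altloc_id for r in rings] == ["A", "B"]
        # the two conformers really are different puckers
        p = [pseudorotation_phase(endocyclic_torsions(r)).P for r in rings]
        assert abs(p[0] - p[1]) > 90.0

    def test_specified_altloc(self, altloc_pdb):
        model = read_models(altloc_pdb)[0]
        sel = ResidueSelector("A", 7, altloc="specified", altloc_id="B")
        (ring,) = extract_ring(model, sel)
        assert ring.altloc_id == "B"

    def test_protein_residue_missing_ring_atoms(self, protein_pdb):
        model = read_models(protein_pdb)[0]
        sel = ResidueSelector("A", 1)
        with pytest.raises(MissingAtomError, match="O4'"):
            extract_ring(model, sel)

    def test_absent_residue(self, three_model_pdb):
        model = read_models(three_model_pdb)[0]
        with pytest.raises(ResidueNotFoundError, match="A/99"):
            extract_ring(model, ResidueSelector("A", 99))


class TestPuckerSeries:
    def test_series_matches_single_ring_pipeline(self, three_model_pdb):
        states = pucker_series(three_model_pdb, SEL)
        assert len(states) == 3
        direct = pseudorotation_phase(endocyclic_torsions(
            extract_ring(read_models(three_model_pdb)[0], SEL)[0]))
        assert states[0].P == direct.P

    def test_embedded_phases_recovered(self, three_model_pdb):
        states = pucker_series(three_model_pdb, SEL)
        for got, want in zip(states, (19.0, 160.0, 173.0)):
            assert got.P == pytest.approx(want, abs=2.0)

    def test_trajectory_circular_mean_near_truth(self, tmp_path):
        from puckerfit import circular_summary
        spec = PuckerMixtureSpec(components=((19.0, 50.0, 1.0),),
                                 n=100, seed=11)
        phases = sample_pucker_phases(spec)
        pdb = write_ring_trajectory_pdb(phases, tmp_path / "traj.pdb")
        states = pucker_series(pdb, SEL)
        assert len(states) == 100
        mean, _ = circular_summary(states)
        assert min(abs(mean - 19.0), 360 - abs(mean - 19.0)) < 3.0

    def test_error_annotated_with_model(self, three_model_pdb):
        with pytest.raises(ResidueNotFoundError, match="model 1"):
            pucker_series(three_model_pdb, ResidueSelector("B", 7))


class TestTorsionTable:
    def test_write_read_round_trip(self, tmp_path):
        sets = [gen_torsion_set(p, 38.0) for p in (19.0, 160.0, 173.0)]
        path = write_torsion_table(sets, tmp_path / "t.tsv")
        back = read_torsion_table(path)
        assert len(back) == 3
        for a, b in zip(sets, back):
            # 9 significant digits -> relative error below 5e-9
            assert np.allclose(a.as_array(), b.as_array(), rtol=5e-9,
                               atol=1e-9)

    def test_two_row_table(self, tmp_path):
        path = tmp_path / "two.tsv"
        path.write_text("v0\tv1\tv2\tv3\tv4\n1\t2\t3\t4\t5\n-1\t-2\t-3\t-4\t-5\n")
        sets = read_torsion_table(path)
        assert len(sets) == 2
        assert sets[1].v2 == -3.0

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("v0\tv1\tv3\tv4\n1\t2\t3\t4\n")
        with pytest.raises(StructureParseError, match="v2"):
            read_torsion_table(path)

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "nan.tsv"
        path.write_text("v0\tv1\tv2\tv3\tv4\n1\t2\tx\t4\t5\n")
        with pytest.raises(StructureParseError, match="row 1"):
            read_torsion_table(path)

    def test_generator_table_round_trip(self, mixed_trajectory):
        back = read_torsion_table(mixed_trajectory.torsion_table)
        assert len(back) == 10_000
        arr = np.array([t.as_array() for t in back])
        assert np.allclose(arr, mixed_trajectory.torsions, rtol=1e-8,
                           atol=1e-7)
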