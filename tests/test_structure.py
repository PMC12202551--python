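"""Residue composition, Shrake–Rupley SASA, exposure and salt bridges."""

import numpy as np
import pytest

import lovkit as lk
from lovkit.exceptions import InputError
from lovkit.simulate import gen_lov_sequences, gen_toy_structure
from lovkit.structure import MAX_ASA, VDW_RADII


def carbon(serial, xyz, resnum=None, chain="A"):
    return lk.Atom(
        serial=serial,
        name=f"C{serial}",
        residue_name="ALA",
        chain=chain,
        residue_number=serial if resnum is None else resnum,
        xyz=xyz,
        element="C",
    )


class TestResidueComposition:
    def test_acidic_dipeptide(self):
        comp = lk.residue_composition("DE")
        assert comp["D"] == (1, 0.5)
        assert comp["E"] == (1, 0.5)

    def test_all_twenty_residues(self):
        comp = lk.residue_composition("ARNDCEQGHILKMFPSTWYV")
        assert all(v == (1, 0.05) for v in comp.values())
        assert comp["D"][1] + comp["E"][1] == pytest.approx(0.10)

    def test_fractions_sum_to_one(self):
        comp = lk.residue_composition("MKKDDEEARRA")
        assert sum(f for _, f in comp.values()) == pytest.approx(1.0)

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(InputError):
            lk.residue_composition("")
        with pytest.raises(InputError, match="position 2"):
            lk.residue_composition("AZA")

    def test_generator_halophilic_bias(self):
        recs, _ = gen_lov_sequences(50, "A", seed=3, acidic_target=0.20)
        fracs = []
        for rec in recs:
            comp = lk.residue_composition(rec.seq)
            fracs.append(comp.get("D", (0, 0))[1] + comp.get("E", (0, 0))[1])
        assert np.mean(fracs) == pytest.approx(0.20, abs=0.03)


class TestShrakeRupleySasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        model = lk.StructureModel([carbon(1, (0.0, 0.0, 0.0))])
        res = lk.shrake_rupley_sasa(model)
        analytic = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert res.atom_areas[0] == pytest.approx(analytic, rel=0.02)

    def test_distant_pair_equals_isolated_spheres(self):
        gap = 2 * (VDW_RADII["C"] + 1.4) + 0.01
        model = lk.StructureModel(
            [carbon(1, (0.0, 0.0, 0.0)), carbon(2, (gap, 0.0, 0.0))]
        )
        res = lk.shrake_rupley_sasa(model)
        analytic = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert np.allclose(res.atom_areas, analytic, rtol=1e-9)

    def test_overlapping_pair_matches_monte_carlo_oracle(self):
        sep = 2.0
        model = lk.StructureModel(
            [carbon(1, (0.0, 0.0, 0.0)), carbon(2, (sep, 0.0, 0.0))]
        )
        res = lk.shrake_rupley_sasa(model)
        # Monte-Carlo surface-point oracle, independent of the fixed grid
        rng = np.random.default_rng(12345)
        R = VDW_RADII["C"] + 1.4
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        for i, center in enumerate([(0.0, 0.0, 0.0), (sep, 0.0, 0.0)]):
            other = np.array([(sep, 0.0, 0.0), (0.0, 0.0, 0.0)][i])
            surf = np.asarray(center) + R * pts
            frac = (
                np.linalg.norm(surf - other, axis=1) > R
            ).mean()
            mc_area = 4 * np.pi * R**2 * frac
            assert res.atom_areas[i] == pytest.approx(mc_area, rel=0.02)

    def test_point_count_convergence(self):
        model, _ = gen_toy_structure(n_bridges=1, n_exposed_asp=2, seed=2)
        lo = lk.shrake_rupley_sasa(model, n_points=960)
        hi = lk.shrake_rupley_sasa(model, n_points=1920)
        for key, area in lo.residue_areas.items():
            assert area == pytest.approx(hi.residue_areas[key], rel=0.01)

    def test_matches_independent_implementation(self):
        import biotite.structure as struc

        model, _ = gen_toy_structure(
            n_bridges=2, n_exposed_asp=3, n_exposed_arg=2, seed=1
        )
        mine = lk.shrake_rupley_sasa(model)
        arr = struc.AtomArray(len(model.atoms))
        for i, a in enumerate(model.atoms):
            arr.coord[i] = a.xyz
            arr.chain_id[i] = a.chain
            arr.res_id[i] = a.residue_number
            arr.res_name[i] = a.residue_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ref = struc.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii="Single"
        )
        assert mine.atom_areas.sum() == pytest.approx(ref.sum(), rel=0.01)

    def test_unknown_element_requires_default_radius(self):
        atom = lk.Atom(1, "X1", "UNK", "A", 1, (0.0, 0.0, 0.0), "ZZ")
        model = lk.StructureModel([atom])
        with pytest.raises(InputError, match="ZZ"):
            lk.shrake_rupley_sasa(model)
        res = lk.shrake_rupley_sasa(model, default_radius=1.7)
        assert res.atom_areas[0] == pytest.approx(
            4 * np.pi * 3.1**2, rel=0.02
        )


class TestSurfaceExposure:
    def test_buried_core_excluded_and_islands_included(self):
        model, truth = gen_toy_structure(
            n_exposed_asp=2, n_exposed_arg=1, include_buried_core=True,
            seed=5,
        )
        sasa = lk.shrake_rupley_sasa(model)
        exposed = lk.surface_exposed_residues(sasa)
        assert truth["exposed_residues"] <= exposed
        assert not (truth["buried_residues"] & exposed)
        # planted outward-facing residues are exactly the exposed set,
        # once the shell occluder pseudo-residues are set aside
        assert exposed - truth["occluder_residues"] == truth[
            "exposed_residues"
        ]

    def test_cutoff_above_accessibility_bound_empties_buried_fixture(self):
        model, _ = gen_toy_structure(include_buried_core=True, seed=5)
        sasa = lk.shrake_rupley_sasa(model)
        assert lk.surface_exposed_residues(sasa, cutoff_fraction=1.01) == set()

    def test_exposed_set_monotone_in_cutoff(self):
        model, _ = gen_toy_structure(
            n_bridges=1, n_exposed_asp=2, include_buried_core=True, seed=6
        )
        sasa = lk.shrake_rupley_sasa(model)
        previous = None
        for cutoff in (0.05, 0.10, 0.30, 0.60, 1.01):
            current = lk.surface_exposed_residues(sasa, cutoff)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_missing_reference_residue_named(self):
        model = lk.StructureModel(
            [lk.Atom(1, "C1", "XXX", "A", 1, (0.0, 0.0, 0.0), "C")]
        )
        sasa = lk.shrake_rupley_sasa(model)
        with pytest.raises(InputError, match="XXX"):
            lk.surface_exposed_residues(sasa)


class TestSaltBridges:
    def test_planted_pair_at_cutoff_distance(self):
        model, truth = gen_toy_structure(n_bridges=1, bridge_distance=3.5)
        bridges = lk.detect_salt_bridges(model)
        assert len(bridges) == 1
        assert bridges[0].min_distance == pytest.approx(3.5, abs=1e-9)
        assert bridges[0].acidic[2] == "ASP"
        assert bridges[0].basic[2] == "ARG"

    def test_pair_beyond_cutoff_is_empty(self):
        model, _ = gen_toy_structure(n_bridges=1, bridge_distance=5.0)
        assert lk.detect_salt_bridges(model, cutoff=4.0) == []

    def test_polyalanine_has_no_bridges(self):
        model, _ = gen_toy_structure(n_exposed_ala=6)
        assert lk.detect_salt_bridges(model) == []

    def test_lysine_bridge_and_his_flag(self):
        model, _ = gen_toy_structure(
            n_bridges=1, bridge_distance=3.0, bridge_basic="LYS"
        )
        bridges = lk.detect_salt_bridges(model)
        assert len(bridges) == 1 and bridges[0].basic[2] == "LYS"
        # histidine exclusion flag leaves Lys bridges untouched
        assert len(lk.detect_salt_bridges(model, include_his=False)) == 1

    def test_invariant_under_rigid_motion_and_atom_order(self):
        model, _ = gen_toy_structure(n_bridges=3, bridge_distance=3.6, seed=4)
        ref = lk.detect_salt_bridges(model)
        # rotate 40° about z and translate
        th = np.deg2rad(40)
        rot = np.array(
            [
                [np.cos(th), -np.sin(th), 0],
                [np.sin(th), np.cos(th), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([11.0, -7.0, 3.0])
        moved_atoms = [
            lk.Atom(
                a.serial, a.name, a.residue_name, a.chain, a.residue_number,
                tuple(rot @ np.array(a.xyz) + shift), a.element,
            )
            for a in reversed(model.atoms)
        ]
        moved = lk.StructureModel(moved_atoms, id="moved")
        got = lk.detect_salt_bridges(moved)
        assert [(b.acidic, b.basic) for b in got] == [
            (b.acidic, b.basic) for b in ref
        ]
        for a, b in zip(ref, got):
            assert a.min_distance == pytest.approx(b.min_distance, abs=1e-9)


class TestHaloProfile:
    def test_polyalanine_profile_is_empty(self):
        model, _ = gen_toy_structure(n_exposed_ala=5)
        prof = lk.halo_profile(model)
        assert prof.counts["D"] == prof.counts["E"] == 0
        assert prof.exposed_de == 0
        assert prof.n_salt_bridges == 0

    def test_planted_bridges_and_exposed_acidics(self):
        model, truth = gen_toy_structure(
            n_bridges=6, n_exposed_asp=7, n_exposed_glu=7,
            n_exposed_arg=5, n_exposed_lys=2, seed=9,
        )
        prof = lk.halo_profile(model)
        assert prof.n_salt_bridges == truth["n_bridges"] == 6
        assert prof.exposed_de == truth["exposed_de"] == 20

    def test_arg_lys_surface_ordering_matches_plant(self):
        arg_rich, _ = gen_toy_structure(
            n_exposed_arg=8, n_exposed_lys=2, n_exposed_ala=4, seed=1
        )
        lys_rich, _ = gen_toy_structure(
            n_exposed_arg=2, n_exposed_lys=8, n_exposed_ala=4, seed=1
        )
        pa = lk.halo_profile(arg_rich)
        pl = lk.halo_profile(lys_rich)
        assert pa.exposed_arg_pct > pa.exposed_lys_pct
        assert pl.exposed_lys_pct > pl.exposed_arg_pct


class TestPdbRoundTrip:
    def test_write_then_read_preserves_atoms(self, tmp_path):
        model, _ = gen_toy_structure(n_bridges=1, n_exposed_glu=1, seed=8)
        path = tmp_path / "toy.pdb"
        lk.write_pdb(model, path)
        back = lk.read_pdb(path)
        assert len(back.atoms) == len(model.atoms)
        for a, b in zip(model.atoms, back.atoms):
            assert (a.name, a.residue_name, a.residue_number) == (
                b.name, b.residue_name, b.residue_number
            )
            assert np.allclose(a.xyz, b.xyz, atol=1e-3)
        bridges = lk.detect_salt_bridges(back)
        assert len(bridges) == 1
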