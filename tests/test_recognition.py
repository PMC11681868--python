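"""Phosphorus contacts, hydrogen bonds, bidentate clamp and static maps."""

import numpy as np
import pytest

from phosphorec.recognition import (
    bidentate_series,
    contact_frequency,
    hydrogen_bonds,
    phosphate_oxygen_names,
    phosphorus_contacts,
    static_interaction_map,
)
from phosphorec.structure_io import Atom, Residue, Role, Structure, TrajectoryEnsemble
from phosphorec.synthetic import ContactPartnerSpec, GeneratorConfig, generate
from tests.conftest import make_atom, single_atom_residue


def build_structure(phospho_residue, partners):
    return Structure(residues=[phospho_residue, *partners])


class TestPhosphorusContacts:
    def test_strict_cutoff_boundary(self, phospho_residue):
        p = phospho_residue.atom("P").coords
        near = single_atom_residue("H", "SER", 52, p + [3.9, 0, 0], serial=20)
        far = single_atom_residue("H", "GLY", 55, p + [0, 4.1, 0], serial=21)
        exact = single_atom_residue("H", "THR", 56, p + [0, 0, 4.0], serial=22)
        st = build_structure(phospho_residue, [near, far, exact])
        got = phosphorus_contacts(st.coords(), st, phospho_residue)
        assert got == {("H", "SER", "52")}  # 4.1 out; exactly 4.0 excluded (strict <)

    def test_antigen_and_water_excluded(self, phospho_residue):
        p = phospho_residue.atom("P").coords
        antigen = single_atom_residue("P", "PHE", 7, p + [1, 0, 0], serial=30,
                                      role=Role.ANTIGEN)
        water = single_atom_residue("W", "HOH", 1, p + [0, 1, 0], name="O",
                                    element="O", serial=31, role=Role.OTHER)
        ab = single_atom_residue("H", "ARG", 95, p + [0, 0, 1], serial=32)
        st = build_structure(phospho_residue, [antigen, water, ab])
        got = phosphorus_contacts(st.coords(), st, phospho_residue)
        assert got == {("H", "ARG", "95")}
        with_water = phosphorus_contacts(st.coords(), st, phospho_residue,
                                         include_solvent=True)
        assert ("W", "HOH", "1") in with_water

    def test_zero_or_multiple_p_atoms_raise(self):
        res = Residue("A", 1, "SER", atoms=[make_atom("CB", "C", 1, [0, 0, 0])])
        st = Structure(residues=[res])
        with pytest.raises(ValueError, match="exactly one P"):
            phosphorus_contacts(st.coords(), st, res)

    def test_matches_brute_force_on_random_frames(self, phospho_residue, rng):
        partners = [
            single_atom_residue("H", "XXX", 10 + i, [0, 0, 0], serial=40 + i)
            for i in range(44)
        ]
        st = build_structure(phospho_residue, partners)
        res_of_atom = st.atom_residue_index()
        p_global = next(i for i, r, a in st.iter_atoms() if a.name == "P")
        for _ in range(200):
            frame = st.coords()
            frame[6:] = rng.normal(scale=3.0, size=frame[6:].shape) + frame[p_global]
            got = phosphorus_contacts(frame, st, phospho_residue)
            want = set()
            for i, r, a in st.iter_atoms():
                if r is phospho_residue:
                    continue
                if np.linalg.norm(frame[i] - frame[p_global]) < 4.0:
                    want.add(r.key)
            assert got == want


class TestHydrogenBonds:
    def test_in_and_out_of_cutoff(self, phospho_residue):
        p = phospho_residue.atom("OT").coords
        don_in = single_atom_residue("H", "ARG", 95, p + [2.9, 0, 0], name="NE",
                                     element="N", serial=50)
        don_out = single_atom_residue("H", "LYS", 96, p + [0, 3.6, 0], name="NZ",
                                      element="N", serial=51)
        st = build_structure(phospho_residue, [don_in, don_out])
        flat = list(st.iter_atoms())
        donors = [i for i, r, a in flat if a.element == "N"]
        acceptors = [i for i, r, a in flat if a.name == "OT"]
        records = hydrogen_bonds(st.coords(), st, donors, acceptors)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(2.9)

    def test_empty_sets_give_empty_list(self, phospho_residue):
        st = build_structure(phospho_residue, [])
        assert hydrogen_bonds(st.coords(), st, [], [0]) == []

    def test_matches_brute_force_all_pairs(self, rng):
        atoms = [make_atom(f"N{i}", "N", i + 1, rng.normal(scale=3, size=3))
                 for i in range(10)]
        atoms += [make_atom(f"O{i}", "O", 11 + i, rng.normal(scale=3, size=3))
                  for i in range(10)]
        res = Residue("A", 1, "XXX", atoms=atoms)
        st = Structure(residues=[res])
        donors = list(range(10))
        acceptors = list(range(10, 20))
        for _ in range(100):
            frame = rng.normal(scale=3, size=(20, 3))
            got = {(h.donor_index, h.acceptor_index) for h in
                   hydrogen_bonds(frame, st, donors, acceptors)}
            want = {(d, a) for d in donors for a in acceptors
                    if np.sqrt(((frame[d] - frame[a]) ** 2).sum()) < 3.5}
            assert got == want


def make_clamp_system(phospho_residue, ne_xyz, nh1_xyz, nh2_xyz):
    arg = Residue(
        chain_id="H", resseq=53, resname="ARG", role=Role.ANTIBODY_HEAVY,
        atoms=[
            make_atom("CZ", "C", 60, [8.0, 0, 0]),
            make_atom("NE", "N", 61, ne_xyz),
            make_atom("NH1", "N", 62, nh1_xyz),
            make_atom("NH2", "N", 63, nh2_xyz),
        ],
    )
    st = Structure(residues=[phospho_residue, arg])
    ens = TrajectoryEnsemble(topology=st, replicates=[st.coords()[None]],
                             dt_ps=100.0, equilibration_fraction=0.0)
    return st, arg, ens


class TestBidentate:
    def test_distinct_nitrogens_and_oxygens_is_bidentate(self, phospho_residue):
        ot = phospho_residue.atom("OT").coords
        o1 = phospho_residue.atom("O1P").coords
        _, arg, ens = make_clamp_system(
            phospho_residue, ot + [0, 0, 2.8], o1 + [0, 0, 2.9], [9, 9, 9]
        )
        series = bidentate_series(ens, arg, phospho_residue)
        assert series.replicates[0][0]

    def test_same_oxygen_twice_is_not_bidentate(self, phospho_residue):
        # both N point radially away from P so each is near OT only: the two
        # H-bonds share one oxygen, which the distinctness rule must reject
        ot = phospho_residue.atom("OT").coords
        p = phospho_residue.atom("P").coords
        radial = (ot - p) / np.linalg.norm(ot - p)
        _, arg, ens = make_clamp_system(
            phospho_residue, ot + 2.8 * radial, ot + 2.9 * radial, [9, 9, 9]
        )
        series = bidentate_series(ens, arg, phospho_residue)
        assert not series.replicates[0][0]
        assert series.hbond_fraction_pooled == 1.0  # H-bonds exist, clamp does not

    def test_missing_guanidinium_atoms_are_named(self, phospho_residue):
        arg = Residue("H", 53, "ARG", atoms=[make_atom("NE", "N", 61, [9, 9, 9])])
        st = Structure(residues=[phospho_residue, arg])
        ens = TrajectoryEnsemble(topology=st, replicates=[st.coords()[None]],
                                 dt_ps=100.0, equilibration_fraction=0.0)
        with pytest.raises(ValueError, match="NH1.*NH2|NH2.*NH1"):
            bidentate_series(ens, arg, phospho_residue)

    def test_terminal_oxygens_exclude_bridging_og(self, phospho_residue):
        names = phosphate_oxygen_names(phospho_residue)
        assert sorted(names) == ["O1P", "O2P", "OT"]

    def test_clamp_implies_hbond_invariant_on_generator(self):
        cfg = GeneratorConfig(seed=5, n_replicates=2, n_frames=400,
                              bidentate_occupancy=0.5, single_hbond_occupancy=0.3,
                              contact_partners=(), n_ca=0)
        ens, _ = generate(cfg)
        sep = ens.topology.find_residue("A", 8)
        arg = ens.topology.find_residue("H", 53)
        series = bidentate_series(ens, arg, sep)
        assert series.fraction_pooled <= series.hbond_fraction_pooled


class TestContactFrequency:
    def _two_state_ensemble(self, phospho_residue, in_frames, n_frames,
                            equilibration_fraction=0.2, n_replicates=1):
        partner = single_atom_residue("H", "SER", 52, [0, 0, 0], serial=70)
        st = build_structure(phospho_residue, [partner])
        base = st.coords()
        p = phospho_residue.atom("P").coords
        reps = []
        for _ in range(n_replicates):
            frames = np.tile(base, (n_frames, 1, 1))
            for t in range(n_frames):
                d = 3.5 if t in in_frames else 6.0
                frames[t, -1] = p + [0, 0, d]
            reps.append(frames)
        return st, TrajectoryEnsemble(
            topology=st, replicates=reps, dt_ps=100.0,
            equilibration_fraction=equilibration_fraction,
        )

    def test_three_of_four_retained_frames_is_75pct(self, phospho_residue):
        # 5 frames, 20% discard -> retain frames 1..4; contact in 3 of them
        st, ens = self._two_state_ensemble(phospho_residue, {1, 2, 4}, 5)
        table = contact_frequency(ens, phospho_residue).table
        row = table[table.resname == "SER"].iloc[0]
        assert row.mean_pct == pytest.approx(75.0)

    def test_never_in_contact_is_zero_and_suppressed(self, phospho_residue):
        st, ens = self._two_state_ensemble(phospho_residue, set(), 5)
        cft = contact_frequency(ens, phospho_residue, min_report=10.0)
        assert cft.table[cft.table.resname == "SER"].iloc[0].mean_pct == 0.0
        assert len(cft.reported()) == 0  # suppressed on output, computed internally

    def test_generator_occupancy_recovered_within_3_points(self):
        cfg = GeneratorConfig(
            seed=8, n_replicates=3, n_frames=2500,
            contact_partners=(ContactPartnerSpec("H", "SER", 52, 0.85),),
            n_ca=0,
        )
        ens, truth = generate(cfg)
        sep = ens.topology.find_residue("A", 8)
        table = contact_frequency(ens, sep).table
        row = table[(table.resname == "SER") & (table.resseq == "52")].iloc[0]
        assert row.mean_pct == pytest.approx(85.0, abs=3.0)
        # and exactly equal to the realised ground-truth occupancy
        realised = 100.0 * truth.retained_contact_occupancy(("H", "SER", "52"))
        assert row.pooled_pct == pytest.approx(realised, abs=1e-9)

    def test_monotone_in_cutoff_and_limits(self, phospho_residue):
        st, ens = self._two_state_ensemble(phospho_residue, {1, 3}, 5)
        lo = contact_frequency(ens, phospho_residue, cutoff=1e-6).table
        mid = contact_frequency(ens, phospho_residue, cutoff=4.0).table
        hi = contact_frequency(ens, phospho_residue, cutoff=1e6).table
        assert (lo.mean_pct == 0.0).all()
        assert (hi.mean_pct == 100.0).all()
        assert (mid.mean_pct <= hi.mean_pct).all() and (mid.mean_pct >= lo.mean_pct).all()

    def test_replicate_mean_is_permutation_invariant(self, phospho_residue):
        st, ens = self._two_state_ensemble(phospho_residue, {1, 2}, 5, n_replicates=3)
        ens.replicates[1][:, -1] = ens.replicates[1][0, -1]  # make reps differ
        t1 = contact_frequency(ens, phospho_residue).table
        ens.replicates = ens.replicates[::-1]
        t2 = contact_frequency(ens, phospho_residue).table
        np.testing.assert_allclose(t1.mean_pct.values, t2.mean_pct.values)

    def test_all_frames_discarded_raises(self, phospho_residue):
        st, ens = self._two_state_ensemble(phospho_residue, set(), 1,
                                           equilibration_fraction=0.99)
        ens.equilibration_fraction = 0.999999
        with pytest.raises(ValueError, match="discard"):
            # 1 frame with fraction ~1 -> floor(1*0.999999)=0 keeps 1; force it
            ens2 = TrajectoryEnsemble(topology=st, replicates=[ens.replicates[0][:0]],
                                      dt_ps=100.0)
            contact_frequency(ens2, phospho_residue)


class TestStaticInteractionMap:
    def _complex(self, phospho_residue, with_water=False):
        ot = phospho_residue.atom("OT").coords
        arg = Residue(
            "H", 95, "ARG", role=Role.ANTIBODY_HEAVY,
            atoms=[make_atom("NH1", "N", 80, ot + [0, 0, 2.8]),
                   make_atom("CZ", "C", 81, ot + [0, 0, 4.5])],
        )
        ser = Residue(
            "H", 53, "SER", role=Role.ANTIBODY_HEAVY,
            atoms=[make_atom("OG", "O", 82, [0.0, -6.0, 0.0])],
        )
        residues = [phospho_residue, arg, ser]
        if with_water:
            o1 = phospho_residue.atom("O1P").coords
            mid = (o1 + ser.atom("OG").coords) / 2
            # water O within 3.5 A of both the phosphate O and the Ser OG
            residues.append(Residue("W", 1, "HOH",
                                    atoms=[make_atom("O", "O", 90, mid)]))
        return Structure(residues=residues)

    def test_direct_hbond_reported(self, phospho_residue):
        st = self._complex(phospho_residue)
        report = static_interaction_map(st, antigen_chain="A")
        arg_entry = report["residues"]["H/ARG/95"]
        assert any(a == "NH1" for a, *_ in arg_entry["hbond"])
        assert arg_entry["contact"]  # NH1 also a loose contact

    def test_water_mediated_bridge_detected(self, phospho_residue):
        st = self._complex(phospho_residue, with_water=True)
        report = static_interaction_map(st, antigen_chain="A")
        ser_entry = report["residues"]["H/SER/53"]
        assert ser_entry["water_mediated"] == [("W/HOH/1", "OG")]

    def test_no_antigen_chain_raises(self, phospho_residue):
        st = self._complex(phospho_residue)
        with pytest.raises(ValueError, match="antigen"):
            static_interaction_map(st, antigen_chain="Z")

    def test_matches_brute_force_recomputation(self, phospho_residue, rng):
        # random polar atoms around the phosphate; compare vs direct scan
        partners = []
        for i in range(20):
            elem = "N" if i % 2 else "O"
            partners.append(single_atom_residue(
                "H", "XXX", 100 + i,
                phospho_residue.atom("P").coords + rng.normal(scale=3, size=3),
                name=f"{elem}X", element=elem, serial=100 + i,
            ))
        st = Structure(residues=[phospho_residue, *partners])
        report = static_interaction_map(st, antigen_chain="A")
        o_names = ["OT", "O1P", "O2P"]
        group = o_names + ["P"]
        for res in partners:
            atom = res.atoms[0]
            want_hb = sorted(
                on for on in o_names
                if np.linalg.norm(atom.coords - phospho_residue.atom(on).coords) < 3.5
            )
            want_contact = sorted(
                gn for gn in group
                if np.linalg.norm(atom.coords - phospho_residue.atom(gn).coords) < 4.0
            )
            entry = report["residues"].get("/".join(res.key), {"hbond": [], "contact": []})
            assert sorted(h[1] for h in entry["hbond"]) == want_hb
            assert sorted(c[1] for c in entry["contact"]) == want_contact
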