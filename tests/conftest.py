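"""Shared fixtures: tiny hand-built structures and small generator ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from phosphorec.structure_io import Atom, Residue, Role, Structure, TrajectoryEnsemble


def make_atom(name, element, serial, xyz):
    return Atom(name=name, element=element, serial=serial, coords=np.asarray(xyz, float))


@pytest.fixture
def phospho_residue():
    """Minimal phosphoserine: CB-OG-P plus three terminal oxygens (~1.5 Å from P)."""
    p = np.array([1.6, 0.0, 0.0])
    arm = np.array([0.96, 1.15, 0.0])

    def rot_x(deg):
        g = np.radians(deg)
        return np.array([[1, 0, 0], [0, np.cos(g), -np.sin(g)], [0, np.sin(g), np.cos(g)]])

    return Residue(
        chain_id="A",
        resseq=8,
        resname="SEP",
        role=Role.ANTIGEN,
        atoms=[
            make_atom("CB", "C", 1, [-0.8, 1.3, 0.0]),
            make_atom("OG", "O", 2, [0.0, 0.0, 0.0]),
            make_atom("P", "P", 3, p),
            make_atom("OT", "O", 4, p + arm),
            make_atom("O1P", "O", 5, p + rot_x(120) @ arm),
            make_atom("O2P", "O", 6, p + rot_x(-120) @ arm),
        ],
    )


def single_atom_residue(chain, resname, resseq, xyz, name="CB", element="C", serial=10,
                        role=Role.ANTIBODY_HEAVY):
    return Residue(
        chain_id=chain, resseq=resseq, resname=resname, role=role,
        atoms=[make_atom(name, element, serial, xyz)],
    )


def static_ensemble(structure: Structure, frames: np.ndarray, dt_ps=100.0,
                    equilibration_fraction=0.0, **kw) -> TrajectoryEnsemble:
    return TrajectoryEnsemble(
        topology=structure,
        replicates=[np.asarray(frames, float)],
        dt_ps=dt_ps,
        equilibration_fraction=equilibration_fraction,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
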