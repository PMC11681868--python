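"""Synthetic trajectory generator with exact ground truth.

Builds a minimal antibody/phosphopeptide mimic — one phosphoserine (CB, OG,
P, O1P, O2P, OT), one arginine guanidinium (CZ, NE, NH1, NH2), a configurable
set of single-atom contact-partner pseudo-residues and a jittered Cα backbone
— and animates it so that every analysis operation has a known answer:

* the CB–OG–P–OT torsion equals a rotamer-state center plus wrapped-normal
  noise, with states hopping as a continuous-time Markov chain discretised at
  the frame interval (the whole PO3 group rotates rigidly);
* each partner residue sits at its in-distance from the phosphorus atom in
  frames where its Bernoulli contact flag is true, at its out-distance
  otherwise;
* the arginine nitrogens are placed to satisfy (bidentate clamp), weakly
  satisfy (single H-bond) or violate the clamp definition per frame;
* Cα atoms carry independent Gaussian jitter of known σ.

This is kinematic mimicry of the statistical structure of the real
simulations — no force field, solvent or energetics.  Defaults are scaled
down from the study conditions (triplicate runs, 100 ps snapshots, leading
20% discarded) to desk scale: 3 replicates × 2500 frames (250 ns-equivalent,
2000 retained) instead of triplicate 1 μs runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import wrap_angle
from .structure_io import (
    Atom,
    ProtonationState,
    Residue,
    Role,
    Structure,
    TrajectoryEnsemble,
    write_pdb,
)

__all__ = [
    "ContactPartnerSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "presets",
    "write_ensemble",
]

# fixed internal geometry (Å): OG at origin, P on +x, CB in the xy-plane
_CB = np.array([-0.8, 1.3, 0.0])
_OG = np.zeros(3)
_P = np.array([1.6, 0.0, 0.0])
#: terminal-oxygen arm at torsion 0 (length 1.50 Å); rotating it about the
#: OG→P axis by θ sets the CB-OG-P-OT torsion to exactly θ
_O_ARM = np.array([0.96, 1.15, 0.0])
_HBOND_LEN = 2.8
_FAR_SHELL = 7.0


def _rot_x(theta_deg: float) -> np.ndarray:
    g = np.radians(theta_deg)
    c, s = np.cos(g), np.sin(g)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


@dataclass(frozen=True)
class ContactPartnerSpec:
    """One pseudo-residue with a prescribed phosphorus-contact occupancy."""

    chain: str
    resname: str
    resseq: int
    occupancy: float
    in_distance: float = 3.5
    out_distance: float = 6.0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.chain, self.resname, str(self.resseq))


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic ensemble.

    Rotamer jumps follow a continuous-time Markov chain with total exit rate
    ``jump_rate_per_ns`` scaled per state by ``state_weights`` (dwell time of
    state *i* is proportional to its weight); angular noise is wrapped
    normal with ``angular_noise_deg``.  ``bidentate_occupancy`` and
    ``single_hbond_occupancy`` are per-frame Bernoulli probabilities of the
    full clamp and of a lone N–O hydrogen bond (mutually exclusive).
    """

    seed: int = 20240
    n_replicates: int = 3
    n_frames: int = 2500
    dt_ps: float = 100.0
    protonation_state: ProtonationState = ProtonationState.PO3_2MINUS
    equilibration_fraction: float = 0.2
    # rotamer model
    state_centers: tuple[float, ...] = (-60.0, 60.0, 180.0)
    jump_rate_per_ns: float = 0.02
    state_weights: tuple[float, ...] | None = None
    angular_noise_deg: float = 10.0
    initial_state: int | str = "cycle"  # per-replicate r % k, or a fixed int
    # interaction models
    contact_partners: tuple[ContactPartnerSpec, ...] = ()
    bidentate_occupancy: float = 0.9
    single_hbond_occupancy: float = 0.05
    contact_cutoff: float = 4.0
    # backbone
    n_ca: int = 20
    ca_jitter_A: float = 0.05

    def validate(self) -> None:
        if self.n_replicates < 1 or self.n_frames < 1:
            raise ValueError("need at least one replicate and one frame")
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if not self.state_centers:
            raise ValueError("need at least one rotamer state center")
        if self.state_weights is not None and len(self.state_weights) != len(
            self.state_centers
        ):
            raise ValueError("state_weights length must match state_centers")
        if self.jump_rate_per_ns < 0 or self.angular_noise_deg < 0:
            raise ValueError("rates and noise must be non-negative")
        for p in self.contact_partners:
            if not (0.0 <= p.occupancy <= 1.0):
                raise ValueError(f"partner {p.key}: occupancy {p.occupancy} outside [0,1]")
            if not (p.in_distance < self.contact_cutoff < p.out_distance):
                raise ValueError(
                    f"partner {p.key}: need in_distance < cutoff < out_distance, got "
                    f"{p.in_distance} / {self.contact_cutoff} / {p.out_distance}"
                )
        for name in ("bidentate_occupancy", "single_hbond_occupancy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0,1]")
        if self.bidentate_occupancy + self.single_hbond_occupancy > 1.0 + 1e-12:
            raise ValueError(
                "impossible clamp schedule: bidentate_occupancy + "
                "single_hbond_occupancy exceeds 1"
            )
        if self.n_ca < 0 or self.ca_jitter_A < 0:
            raise ValueError("backbone parameters must be non-negative")


@dataclass
class GroundTruth:
    """Exact per-frame labels the analyses must recover."""

    rotamer_labels: list[np.ndarray]
    contact_flags: dict[tuple[str, str, str], list[np.ndarray]]
    clamp_flags: list[np.ndarray]
    single_hbond_flags: list[np.ndarray]
    config: GeneratorConfig

    def _retained(self, arrays: list[np.ndarray]) -> list[np.ndarray]:
        frac = self.config.equilibration_fraction
        return [a[int(np.floor(len(a) * frac)) :] for a in arrays]

    def retained_rotamer_labels(self) -> list[np.ndarray]:
        return self._retained(self.rotamer_labels)

    def retained_contact_occupancy(self, key) -> float:
        """Realised contact fraction of one partner over retained frames."""
        return float(np.mean(np.concatenate(self._retained(self.contact_flags[key]))))

    def retained_clamp_fraction(self) -> float:
        return float(np.mean(np.concatenate(self._retained(self.clamp_flags))))


def _build_topology(config: GeneratorConfig) -> tuple[Structure, dict]:
    """Static topology at torsion 0, everything un-clamped; index map returned."""
    residues = []
    serial = [0]

    def atom(name, element, coords):
        serial[0] += 1
        return Atom(name=name, element=element, serial=serial[0], coords=np.array(coords))

    o_pos = {name: _P + _rot_x(ang) @ _O_ARM for name, ang in (("OT", 0.0), ("O1P", 120.0), ("O2P", -120.0))}
    sep = Residue(
        chain_id="A",
        resseq=8,
        resname="SEP",
        role=Role.ANTIGEN,
        atoms=[
            atom("CB", "C", _CB),
            atom("OG", "O", _OG),
            atom("P", "P", _P),
            atom("O1P", "O", o_pos["O1P"]),
            atom("O2P", "O", o_pos["O2P"]),
            atom("OT", "O", o_pos["OT"]),
        ],
    )
    residues.append(sep)

    far = _P + _FAR_SHELL * np.array([0.0, -1.0, 0.0])
    arg = Residue(
        chain_id="H",
        resseq=53,
        resname="ARG",
        role=Role.ANTIBODY_HEAVY,
        atoms=[
            atom("CZ", "C", far + np.array([0.0, -1.2, 0.0])),
            atom("NE", "N", far),
            atom("NH1", "N", far + np.array([1.1, 0.0, 0.0])),
            atom("NH2", "N", far + np.array([-1.1, 0.0, 0.0])),
        ],
    )
    residues.append(arg)

    n_partners = len(config.contact_partners)
    partner_dirs = {}
    for j, spec in enumerate(config.contact_partners):
        phi = 2.0 * np.pi * j / max(n_partners, 1)
        # cone around -x, polar angle 55 deg: away from the oxygens and the Arg
        u = np.array(
            [-np.cos(np.radians(55.0)),
             np.sin(np.radians(55.0)) * np.cos(phi),
             np.sin(np.radians(55.0)) * np.sin(phi)]
        )
        partner_dirs[spec.key] = u
        residues.append(
            Residue(
                chain_id=spec.chain,
                resseq=spec.resseq,
                resname=spec.resname,
                role=Role.ANTIBODY_HEAVY,
                atoms=[atom("CB", "C", _P + spec.out_distance * u)],
            )
        )

    ca_ref = []
    for i in range(config.n_ca):
        pos = np.array([20.0 + 1.5 * i, 3.0 * np.cos(0.6 * i), 3.0 * np.sin(0.6 * i)])
        ca_ref.append(pos)
        residues.append(
            Residue(
                chain_id="H",
                resseq=200 + i,
                resname="GLY",
                role=Role.ANTIBODY_HEAVY,
                atoms=[atom("CA", "C", pos)],
            )
        )

    topo = Structure(residues=residues, title="synthetic phospho-epitope mimic", source_format="memory")
    index = {}
    for i, res, a in topo.iter_atoms():
        index[(res.chain_id, res.resseq, a.name)] = i
    layout = {
        "index": index,
        "partner_dirs": partner_dirs,
        "ca_ref": np.array(ca_ref) if ca_ref else np.zeros((0, 3)),
        "sep": sep,
        "arg": arg,
    }
    return topo, layout


def _simulate_labels(config: GeneratorConfig, rng: np.random.Generator, rep: int) -> np.ndarray:
    k = len(config.state_centers)
    w = np.asarray(config.state_weights if config.state_weights else np.ones(k), dtype=float)
    w = w / w.sum()
    dt_ns = config.dt_ps / 1000.0
    exit_rates = config.jump_rate_per_ns * (np.mean(w) / w)  # dwell_i ∝ w_i
    p_exit = 1.0 - np.exp(-exit_rates * dt_ns)
    labels = np.empty(config.n_frames, dtype=int)
    if config.initial_state == "cycle":
        cur = rep % k
    else:
        cur = int(config.initial_state) % k
    labels[0] = cur
    if k == 1 or config.jump_rate_per_ns == 0:
        labels[:] = cur
        return labels
    u = rng.random(config.n_frames)
    for t in range(1, config.n_frames):
        if u[t] < p_exit[cur]:
            others = [s for s in range(k) if s != cur]
            pw = w[others] / w[others].sum()
            cur = int(rng.choice(others, p=pw))
        labels[t] = cur
    return labels


def generate(config: GeneratorConfig) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Generate a replicate ensemble and its exact ground truth.

    Deterministic for a fixed seed; replicate streams are derived from
    (seed, replicate index) so adding replicates never reshuffles earlier
    ones.
    """
    config.validate()
    topo, layout = _build_topology(config)
    index = layout["index"]
    sep: Residue = layout["sep"]
    arg: Residue = layout["arg"]
    n_atoms = topo.n_atoms
    base = topo.coords()

    i_ot = index[("A", 8, "OT")]
    i_o1 = index[("A", 8, "O1P")]
    i_o2 = index[("A", 8, "O2P")]
    i_ne = index[("H", 53, "NE")]
    i_nh1 = index[("H", 53, "NH1")]
    i_nh2 = index[("H", 53, "NH2")]
    i_cz = index[("H", 53, "CZ")]
    partner_atom = {
        spec.key: index[(spec.chain, spec.resseq, "CB")] for spec in config.contact_partners
    }
    ca_idx = np.array(
        [index[("H", 200 + i, "CA")] for i in range(config.n_ca)], dtype=int
    )

    far_ne = base[i_ne]
    far_nh1 = base[i_nh1]
    far_nh2 = base[i_nh2]

    replicates = []
    truth = GroundTruth(
        rotamer_labels=[],
        contact_flags={spec.key: [] for spec in config.contact_partners},
        clamp_flags=[],
        single_hbond_flags=[],
        config=config,
    )
    centers = np.asarray(config.state_centers, dtype=float)
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        labels = _simulate_labels(config, rng, rep)
        noise = rng.normal(0.0, config.angular_noise_deg, size=config.n_frames)
        angles = np.asarray(wrap_angle(centers[labels] + noise))

        u = rng.random(config.n_frames)
        clamp = u < config.bidentate_occupancy
        single = (~clamp) & (u < config.bidentate_occupancy + config.single_hbond_occupancy)

        contact = {
            spec.key: rng.random(config.n_frames) < spec.occupancy
            for spec in config.contact_partners
        }
        ca_noise = rng.normal(0.0, config.ca_jitter_A, size=(config.n_frames, config.n_ca, 3))

        frames = np.tile(base, (config.n_frames, 1, 1))
        for t in range(config.n_frames):
            rot = _rot_x(angles[t])
            ot = _P + rot @ _O_ARM
            o1 = _P + _rot_x(angles[t] + 120.0) @ _O_ARM
            o2 = _P + _rot_x(angles[t] - 120.0) @ _O_ARM
            frames[t, i_ot] = ot
            frames[t, i_o1] = o1
            frames[t, i_o2] = o2
            if clamp[t]:
                frames[t, i_ne] = ot + _HBOND_LEN * (ot - _P) / np.linalg.norm(ot - _P)
                frames[t, i_nh1] = o1 + _HBOND_LEN * (o1 - _P) / np.linalg.norm(o1 - _P)
                frames[t, i_nh2] = far_nh2
            elif single[t]:
                frames[t, i_ne] = ot + _HBOND_LEN * (ot - _P) / np.linalg.norm(ot - _P)
                frames[t, i_nh1] = far_nh1
                frames[t, i_nh2] = far_nh2
            else:
                frames[t, i_ne] = far_ne
                frames[t, i_nh1] = far_nh1
                frames[t, i_nh2] = far_nh2
            frames[t, i_cz] = frames[t, [i_ne, i_nh1, i_nh2]].mean(axis=0) + np.array(
                [0.0, -1.2, 0.0]
            )
        for spec in config.contact_partners:
            ai = partner_atom[spec.key]
            d_in = np.where(contact[spec.key], spec.in_distance, spec.out_distance)
            udir = layout["partner_dirs"][spec.key]
            frames[:, ai] = _P[None, :] + d_in[:, None] * udir[None, :]
        if config.n_ca:
            frames[:, ca_idx] = layout["ca_ref"][None] + ca_noise

        replicates.append(frames)
        truth.rotamer_labels.append(labels)
        truth.clamp_flags.append(clamp)
        truth.single_hbond_flags.append(single)
        for spec in config.contact_partners:
            truth.contact_flags[spec.key].append(contact[spec.key])

    ensemble = TrajectoryEnsemble(
        topology=topo,
        replicates=replicates,
        dt_ps=config.dt_ps,
        protonation_state=config.protonation_state,
        equilibration_fraction=config.equilibration_fraction,
    )
    return ensemble, truth


def dihedral_quad_indices(ensemble: TrajectoryEnsemble) -> tuple[int, int, int, int]:
    """Global indices of the CB, OG, P, OT torsion quadruple of the mimic."""
    index = {}
    for i, res, a in ensemble.topology.iter_atoms():
        if res.resname == "SEP":
            index[a.name] = i
    return (index["CB"], index["OG"], index["P"], index["OT"])


def presets() -> dict[str, GeneratorConfig]:
    """Named configurations reproducing the study's qualitative contrasts.

    * ``C7-like``: a rigid clamp — single rotamer well, essentially permanent
      bidentate interaction, a handful of near-100% contact partners.
    * ``A4-like-po3``: unprotonated phosphate in the promiscuous binder —
      three unequal rotamer wells with slow (tens-to-hundreds of ns) 120°
      jumps, intermittent clamp, many partners at varied occupancies.
    * ``A4-like-po3h``: singly protonated phosphate — single dominant well,
      variable multi-residue contacts.
    * ``nonantibody-like``: a weak generic phospho-binder — three equivalent
      wells with fast rotation and a rarely formed clamp.
    """
    return {
        "C7-like": GeneratorConfig(
            protonation_state=ProtonationState.PO3_2MINUS,
            state_centers=(-60.0,),
            jump_rate_per_ns=0.0,
            angular_noise_deg=8.0,
            bidentate_occupancy=0.985,
            single_hbond_occupancy=0.01,
            contact_partners=(
                ContactPartnerSpec("H", "SER", 52, 0.999),
                ContactPartnerSpec("H", "SER", 54, 0.999),
                ContactPartnerSpec("H", "TYR", 97, 0.998),
                ContactPartnerSpec("H", "ILE", 56, 0.01),
            ),
        ),
        "A4-like-po3": GeneratorConfig(
            protonation_state=ProtonationState.PO3_2MINUS,
            state_centers=(-60.0, 60.0, 180.0),
            jump_rate_per_ns=1.0 / 50.0,
            state_weights=(0.6, 0.25, 0.15),
            angular_noise_deg=10.0,
            bidentate_occupancy=0.78,
            single_hbond_occupancy=0.15,
            contact_partners=(
                ContactPartnerSpec("H", "SER", 33, 0.61),
                ContactPartnerSpec("H", "HIS", 50, 0.34),
                ContactPartnerSpec("H", "GLY", 52, 0.96),
                ContactPartnerSpec("H", "SER", 54, 0.53),
                ContactPartnerSpec("H", "GLY", 55, 0.28),
                ContactPartnerSpec("H", "THR", 56, 0.05),
            ),
        ),
        "A4-like-po3h": GeneratorConfig(
            protonation_state=ProtonationState.PO3H_MINUS,
            state_centers=(-60.0,),
            jump_rate_per_ns=0.0,
            angular_noise_deg=12.0,
            bidentate_occupancy=0.45,
            single_hbond_occupancy=0.35,
            contact_partners=(
                ContactPartnerSpec("H", "SER", 33, 0.61),
                ContactPartnerSpec("H", "HIS", 50, 0.35),
                ContactPartnerSpec("H", "GLY", 52, 0.83),
                ContactPartnerSpec("H", "SER", 54, 0.49),
                ContactPartnerSpec("H", "THR", 56, 0.15),
            ),
        ),
        "nonantibody-like": GeneratorConfig(
            protonation_state=ProtonationState.PO3_2MINUS,
            state_centers=(-60.0, 60.0, 180.0),
            jump_rate_per_ns=1.0 / 5.0,
            angular_noise_deg=12.0,
            bidentate_occupancy=0.2,
            single_hbond_occupancy=0.3,
            contact_partners=(ContactPartnerSpec("H", "ARG", 10, 0.9),),
        ),
    }


def write_ensemble(
    ensemble: TrajectoryEnsemble,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write topology.pdb, one multi-model PDB per replicate, and the
    ground-truth JSON sidecar.  Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"topology": out_dir / "topology.pdb"}
    write_pdb(ensemble.topology, paths["topology"])
    for r, frames in enumerate(ensemble.replicates):
        p = out_dir / f"replicate_{r}.pdb"
        write_pdb(ensemble.topology, p, frames=frames)
        paths[f"replicate_{r}"] = p
    sidecar = {
        "config": {
            k: (v.value if isinstance(v, ProtonationState) else v)
            for k, v in asdict(truth.config).items()
            if k != "contact_partners"
        },
        "contact_partners": [asdict(s) for s in truth.config.contact_partners],
        "rotamer_labels": [lab.tolist() for lab in truth.rotamer_labels],
        "clamp_flags": [c.astype(int).tolist() for c in truth.clamp_flags],
        "single_hbond_flags": [c.astype(int).tolist() for c in truth.single_hbond_flags],
        "contact_flags": {
            "/".join(k): [c.astype(int).tolist() for c in v]
            for k, v in truth.contact_flags.items()
        },
    }
    paths["ground_truth"] = out_dir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(sidecar, fh)
    return paths
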