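"""Contact, hydrogen-bond and bidentate-clamp statistics.

Implements the interaction criteria used to characterise how anti-phosphosite
antibodies engage a phosphoserine antigen:

* a residue *contacts* the phosphate when any of its atoms (hydrogens
  included, when present) lies strictly within 4.0 Å of the phosphorus atom;
* a *hydrogen bond* is a donor/acceptor heavy-atom pair strictly within
  3.5 Å (distance-only criterion; an optional donor-angle filter is
  available but off by default);
* a *bidentate clamp* exists in a frame when two H-bonds connect two
  distinct guanidinium nitrogens of an Arg (NE/NH1/NH2) to two distinct
  terminal phosphate oxygens — the interaction that pins the phosphate and
  suppresses its rotation.

Frequencies over trajectories are computed on frames retained after the
equilibration discard, per replicate, then averaged across replicates
(pooled-frame variants are also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import distance
from .structure_io import (
    Residue,
    Role,
    Structure,
    TrajectoryEnsemble,
    PHOSPHOSERINE_RESNAMES,
)

__all__ = [
    "ContactFrequencyTable",
    "HBondRecord",
    "BidentateSeries",
    "CONTACT_CUTOFF",
    "HBOND_CUTOFF",
    "phosphorus_contacts",
    "contact_frequency",
    "hydrogen_bonds",
    "bidentate_series",
    "static_interaction_map",
    "phosphate_oxygen_names",
    "find_phosphorus",
]

#: Default loose-contact cutoff (Å): residue counts as interacting when any
#: atom is strictly closer than this to the phosphorus atom.
CONTACT_CUTOFF = 4.0

#: Default hydrogen-bond donor–acceptor heavy-atom cutoff (Å).
HBOND_CUTOFF = 3.5

#: Guanidinium nitrogen names of arginine.
GUANIDINIUM_N = ("NE", "NH1", "NH2")

#: Polar heavy-atom elements eligible as H-bond donors/acceptors.
_POLAR_ELEMENTS = {"N", "O"}


def find_phosphorus(structure: Structure, phospho_res: Residue) -> int:
    """Global atom index of the unique P atom of the phosphoserine residue."""
    candidates = [
        i
        for i, res, atom in structure.iter_atoms()
        if res is phospho_res and (atom.element == "P" or atom.name == "P")
    ]
    if len(candidates) != 1:
        names = [a.name for a in phospho_res.atoms]
        raise ValueError(
            f"phospho residue {phospho_res.key} must contain exactly one P atom; "
            f"found {len(candidates)} among atoms {names}"
        )
    return candidates[0]


def phosphate_oxygen_names(phospho_res: Residue) -> list[str]:
    """Terminal phosphate oxygen names: O atoms bonded to P, excluding the
    bridging OG ester oxygen (topology coordinates define bonding)."""
    p_atom = None
    for a in phospho_res.atoms:
        if a.element == "P" or a.name == "P":
            p_atom = a
            break
    if p_atom is None:
        raise ValueError(f"no P atom in {phospho_res.key}")
    names = []
    for a in phospho_res.atoms:
        if a.name == "OG" or not (a.element == "O" or a.name.startswith("O")):
            continue
        if distance(a.coords, p_atom.coords) < 1.9:
            names.append(a.name)
    if not names:
        # fall back to conventional names when bond distances are unavailable
        names = [a.name for a in phospho_res.atoms if a.name in ("O1P", "O2P", "O3P", "OT")]
    return names


def _candidate_residues(
    structure: Structure,
    phospho_res: Residue,
    include_solvent: bool,
) -> list[int]:
    """Residue indices eligible as contact partners: everything except the
    antigen (incl. the phospho residue itself) and, by default, solvent."""
    out = []
    for ri, res in enumerate(structure.residues):
        if res is phospho_res or res.role is Role.ANTIGEN:
            continue
        if res.is_water and not include_solvent:
            continue
        out.append(ri)
    return out


def phosphorus_contacts(
    frame: np.ndarray,
    topology: Structure,
    phospho_res: Residue,
    cutoff: float = CONTACT_CUTOFF,
    include_solvent: bool = False,
) -> set[tuple[str, str, str]]:
    """Residues with any atom strictly within ``cutoff`` of the P atom.

    ``frame`` is an (n_atoms, 3) coordinate array congruent with ``topology``.
    Returns residue keys ``(chain, resname, resseq)``.  Hydrogens count when
    present.  The antigen (and solvent, by default) is excluded.
    """
    frame = np.asarray(frame, dtype=float)
    p_idx = find_phosphorus(topology, phospho_res)
    res_of_atom = topology.atom_residue_index()
    eligible = set(_candidate_residues(topology, phospho_res, include_solvent))
    d = np.linalg.norm(frame - frame[p_idx], axis=1)
    hit_residues = {int(r) for r in np.unique(res_of_atom[d < cutoff]) if int(r) in eligible}
    return {topology.residues[ri].key for ri in hit_residues}


@dataclass
class ContactFrequencyTable:
    """Per-residue phosphorus-contact percentages, per replicate and averaged.

    ``table`` columns: chain, resname, resseq, one ``rep{i}_pct`` column per
    replicate, ``mean_pct`` (arithmetic mean of replicate percentages) and
    ``pooled_pct`` (all retained frames pooled — for comparison only).
    """

    table: pd.DataFrame
    protonation_state: str = ""
    cutoff_used: float = CONTACT_CUTOFF
    min_report: float = 0.0

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("rep") and c.endswith("_pct")]

    def reported(self) -> pd.DataFrame:
        """Rows at or above the reporting threshold (all rows are computed)."""
        return self.table[self.table["mean_pct"] >= self.min_report].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.reported().to_csv(path, sep="\t", index=False, float_format="%.1f")


def contact_frequency(
    ensemble: TrajectoryEnsemble,
    phospho_res: Residue,
    cutoff: float = CONTACT_CUTOFF,
    min_report: float = 0.0,
    include_solvent: bool = False,
) -> ContactFrequencyTable:
    """Percentage of retained frames each residue contacts the phosphorus.

    The leading ``equilibration_fraction`` of every replicate is discarded
    first; percentages are computed per replicate and averaged across
    replicates.  Rows with mean below ``min_report`` are computed but
    suppressed from :meth:`ContactFrequencyTable.reported`.
    """
    topo = ensemble.topology
    p_idx = find_phosphorus(topo, phospho_res)
    res_of_atom = topo.atom_residue_index()
    eligible = _candidate_residues(topo, phospho_res, include_solvent)
    atom_groups = {
        ri: np.flatnonzero(res_of_atom == ri) for ri in eligible
    }

    per_rep_pct: dict[int, dict[int, float]] = {}
    pooled_hits = {ri: 0 for ri in eligible}
    pooled_n = 0
    for r in range(ensemble.n_replicates):
        frames = ensemble.retained(r)
        nf = len(frames)
        pooled_n += nf
        counts = {ri: 0 for ri in eligible}
        for frame in frames:
            d = np.linalg.norm(frame - frame[p_idx], axis=1)
            hit = d < cutoff
            for ri, idx in atom_groups.items():
                if hit[idx].any():
                    counts[ri] += 1
        per_rep_pct[r] = {ri: 100.0 * c / nf for ri, c in counts.items()}
        for ri, c in counts.items():
            pooled_hits[ri] += c

    rows = []
    for ri in eligible:
        res = topo.residues[ri]
        row = {
            "chain": res.chain_id,
            "resname": res.resname,
            "resseq": f"{res.resseq}{res.icode}",
        }
        reps = [per_rep_pct[r][ri] for r in range(ensemble.n_replicates)]
        for r, v in enumerate(reps):
            row[f"rep{r}_pct"] = v
        row["mean_pct"] = float(np.mean(reps))
        row["pooled_pct"] = 100.0 * pooled_hits[ri] / pooled_n
        rows.append(row)
    table = pd.DataFrame(rows)
    return ContactFrequencyTable(
        table=table,
        protonation_state=ensemble.protonation_state.value,
        cutoff_used=cutoff,
        min_report=min_report,
    )


@dataclass(frozen=True)
class HBondRecord:
    """One donor–acceptor pair within the H-bond cutoff in one frame."""

    donor_index: int
    acceptor_index: int
    distance: float
    frame_index: int = 0


def hydrogen_bonds(
    frame: np.ndarray,
    topology: Structure,
    donors: list[int],
    acceptors: list[int],
    cutoff: float = HBOND_CUTOFF,
    frame_index: int = 0,
) -> list[HBondRecord]:
    """All donor–acceptor pairs strictly within ``cutoff`` Å.

    ``donors``/``acceptors`` are global atom indices of polar heavy atoms
    (N, O); the criterion is distance-only.  Empty input sets yield an empty
    list.  Self-pairs (same atom index) are skipped.
    """
    frame = np.asarray(frame, dtype=float)
    if not donors or not acceptors:
        return []
    dpos = frame[np.asarray(donors)]
    apos = frame[np.asarray(acceptors)]
    dmat = np.linalg.norm(dpos[:, None, :] - apos[None, :, :], axis=2)
    out = []
    for i, di in enumerate(donors):
        for j, aj in enumerate(acceptors):
            if di == aj:
                continue
            if dmat[i, j] < cutoff:
                out.append(HBondRecord(di, aj, float(dmat[i, j]), frame_index))
    return out


@dataclass
class BidentateSeries:
    """Boolean per-frame bidentate-clamp series per replicate."""

    replicates: list[np.ndarray] = field(default_factory=list)
    dt_ps: float = 100.0
    arg_key: tuple = ()
    phospho_key: tuple = ()
    cutoff: float = HBOND_CUTOFF
    #: per replicate, per frame: list of (N_name, O_name) H-bond pairs found
    pairs: list[list[list[tuple[str, str]]]] = field(default_factory=list)

    @property
    def fraction_per_replicate(self) -> list[float]:
        return [float(np.mean(r)) for r in self.replicates]

    @property
    def fraction_pooled(self) -> float:
        return float(np.mean(np.concatenate(self.replicates)))

    @property
    def hbond_fraction_pooled(self) -> float:
        """Fraction of frames with at least one Arg–phosphate H-bond."""
        flags = np.concatenate(
            [np.array([len(p) > 0 for p in rep_pairs]) for rep_pairs in self.pairs]
        )
        return float(np.mean(flags))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r, series in enumerate(self.replicates):
            for fi, v in enumerate(series):
                rows.append(
                    {
                        "replicate": r,
                        "time_ns": fi * self.dt_ps / 1000.0,
                        "bidentate": int(v),
                    }
                )
        return pd.DataFrame(rows)


def _bidentate_frame(
    frame: np.ndarray,
    n_indices: dict[str, int],
    o_indices: dict[str, int],
    cutoff: float,
) -> tuple[bool, list[tuple[str, str]]]:
    pairs = []
    for nn, ni in n_indices.items():
        for on, oi in o_indices.items():
            if distance(frame[ni], frame[oi]) < cutoff:
                pairs.append((nn, on))
    bident = any(
        a[0] != b[0] and a[1] != b[1] for i, a in enumerate(pairs) for b in pairs[i + 1 :]
    )
    return bident, pairs


def bidentate_series(
    ensemble: TrajectoryEnsemble,
    arg_res: Residue,
    phospho_res: Residue,
    cutoff: float = HBOND_CUTOFF,
) -> BidentateSeries:
    """Per-frame bidentate clamp detection on retained frames.

    A frame is bidentate iff two H-bonds pair two *distinct* guanidinium
    nitrogens (NE/NH1/NH2) with two *distinct* terminal phosphate oxygens.
    """
    if arg_res.resname not in ("ARG",):
        raise ValueError(f"{arg_res.key} is not an arginine")
    missing = [n for n in GUANIDINIUM_N if not arg_res.has_atom(n)]
    if missing:
        raise ValueError(f"arginine {arg_res.key} lacks guanidinium atoms: {missing}")
    o_names = phosphate_oxygen_names(phospho_res)
    if len(o_names) < 2:
        raise ValueError(
            f"phospho residue {phospho_res.key} needs >=2 terminal phosphate oxygens; "
            f"found {o_names}"
        )
    topo = ensemble.topology
    atom_index = {}
    for i, res, atom in topo.iter_atoms():
        if res is arg_res and atom.name in GUANIDINIUM_N:
            atom_index[("N", atom.name)] = i
        if res is phospho_res and atom.name in o_names:
            atom_index[("O", atom.name)] = i
    n_idx = {k[1]: v for k, v in atom_index.items() if k[0] == "N"}
    o_idx = {k[1]: v for k, v in atom_index.items() if k[0] == "O"}

    out = BidentateSeries(
        replicates=[],
        dt_ps=ensemble.dt_ps,
        arg_key=arg_res.key,
        phospho_key=phospho_res.key,
        cutoff=cutoff,
    )
    for r in range(ensemble.n_replicates):
        frames = ensemble.retained(r)
        flags = np.zeros(len(frames), dtype=bool)
        rep_pairs = []
        for fi, frame in enumerate(frames):
            bident, pairs = _bidentate_frame(frame, n_idx, o_idx, cutoff)
            flags[fi] = bident
            rep_pairs.append(pairs)
        out.replicates.append(flags)
        out.pairs.append(rep_pairs)
    return out


def static_interaction_map(
    structure: Structure,
    antigen_chain: str,
    hbond_cutoff: float = HBOND_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
    phospho_resnames: frozenset[str] = PHOSPHOSERINE_RESNAMES,
) -> dict:
    """Interaction map of the phosphate group in a static (crystal) structure.

    For each non-antigen, non-water residue reports:

    * ``hbond``: polar heavy atoms (N/O) strictly within ``hbond_cutoff`` of a
      terminal phosphate oxygen;
    * ``contact``: any atom strictly within ``contact_cutoff`` of any
      phosphate-group atom (P + terminal oxygens);
    * ``water_mediated``: waters whose O sits within ``hbond_cutoff`` of both
      a phosphate oxygen and a polar atom of the residue.
    """
    antigen = [r for r in structure.residues if r.chain_id == antigen_chain]
    if not antigen:
        raise ValueError(f"no antigen chain {antigen_chain!r} in structure")
    phospho = [r for r in antigen if r.resname in phospho_resnames]
    if not phospho:
        raise ValueError(
            f"no phosphoserine ({sorted(phospho_resnames)}) on chain {antigen_chain!r}"
        )
    phospho_res = phospho[0]
    o_names = phosphate_oxygen_names(phospho_res)
    group_atoms = {n: phospho_res.atom(n) for n in o_names}
    for a in phospho_res.atoms:
        if a.element == "P" or a.name == "P":
            group_atoms[a.name] = a
    o_atoms = {n: phospho_res.atom(n) for n in o_names}

    waters = [r for r in structure.residues if r.is_water]
    report: dict = {
        "phospho_residue": "/".join(phospho_res.key),
        "hbond_cutoff": hbond_cutoff,
        "contact_cutoff": contact_cutoff,
        "residues": {},
    }
    for res in structure.residues:
        if res.chain_id == antigen_chain or res.is_water:
            continue
        hb = []
        contacts = []
        for atom in res.atoms:
            for gname, gatom in group_atoms.items():
                d = distance(atom.coords, gatom.coords)
                if d < contact_cutoff:
                    contacts.append((atom.name, gname, round(d, 2)))
                if (
                    atom.element in _POLAR_ELEMENTS
                    and gname in o_atoms
                    and d < hbond_cutoff
                ):
                    hb.append((atom.name, gname, round(d, 2)))
        bridged = []
        for w in waters:
            try:
                wo = next(a for a in w.atoms if a.element == "O" or a.name.startswith("O"))
            except StopIteration:
                continue
            near_phos = any(
                distance(wo.coords, oa.coords) <= hbond_cutoff for oa in o_atoms.values()
            )
            if not near_phos:
                continue
            for atom in res.atoms:
                if atom.element in _POLAR_ELEMENTS and distance(atom.coords, wo.coords) <= hbond_cutoff:
                    bridged.append(("/".join(w.key), atom.name))
                    break
        if hb or contacts or bridged:
            report["residues"]["/".join(res.key)] = {
                "hbond": hb,
                "contact": contacts,
                "water_mediated": bridged,
            }
    return report
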