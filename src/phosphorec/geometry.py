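"""Geometric kernels: distances, torsion angles, superposition, RMSD series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "RmsdSeries",
    "distance",
    "dihedral",
    "wrap_angle",
    "circular_difference",
    "superpose",
    "ca_rmsd_series",
]


class DegenerateGeometryError(ValueError):
    """Coincident/collinear points where an angle or fit is undefined."""


def distance(a, b) -> float:
    """Euclidean distance between two points in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def wrap_angle(deg) -> np.ndarray | float:
    """Wrap angle(s) in degrees into the half-open interval (-180, 180]."""
    wrapped = -np.remainder(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def circular_difference(a, b) -> np.ndarray | float:
    """Signed circular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral(p1, p2, p3, p4, _tol: float = 1e-10) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    cis (eclipsed) is 0°; looking along p2→p3, a clockwise rotation of the
    far bond is positive.  Range is (-180, 180]; the tie at ±180° reports
    +180°.  Raises :class:`DegenerateGeometryError` when consecutive points
    coincide or either bonded triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(b1) < _tol or nb2 < _tol or np.linalg.norm(b3) < _tol:
        raise DegenerateGeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _tol or np.linalg.norm(n2) < _tol:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral_array(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Vectorised torsion over stacked point arrays of shape (n, 3)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2hat = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", np.cross(n1, n2), b2hat)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def superpose(
    mobile_coords: np.ndarray, ref_coords: np.ndarray, _tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, no reflection).

    Returns ``(rotation, translation, rmsd)`` with the transform mapping
    mobile onto the reference: ``x' = R @ x + t``.  The rotation determinant
    is always +1.  Requires ≥3 points with non-degenerate spread.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {mobile.shape} vs {ref.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"superposition needs >= 3 points, got {n}")
    cm = mobile.mean(axis=0)
    cr = ref.mean(axis=0)
    h = (mobile - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    if s[1] < _tol * max(s[0], 1.0):
        raise DegenerateGeometryError("rank-deficient (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


@dataclass
class RmsdSeries:
    """Per-replicate RMSD (Å) of a Cα subset against each replicate's first frame."""

    replicates: list[np.ndarray] = field(default_factory=list)
    dt_ps: float = 100.0
    excluded: str = ""
    superposed: bool = True

    def times_ns(self, replicate: int) -> np.ndarray:
        return np.arange(len(self.replicates[replicate])) * self.dt_ps / 1000.0

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r, series in enumerate(self.replicates):
            t = self.times_ns(r)
            for ti, v in zip(t, series):
                rows.append({"replicate": r, "time_ns": ti, "rmsd_A": v})
        return pd.DataFrame(rows)


def ca_rmsd_series(
    ensemble,
    exclude_residues: set[tuple[str, int]] | frozenset = frozenset(),
    fit: bool = True,
) -> RmsdSeries:
    """Cα-RMSD convergence series versus each replicate's first snapshot.

    ``exclude_residues`` is a set of (chain_id, resseq) pairs to drop from the
    Cα set — typically the GS linker and the first/last terminal residues,
    supplied explicitly by the caller.  With ``fit=True`` (default) each frame
    is superposed onto the first frame on the included Cα set before the RMSD
    is measured; raw (unfitted) RMSD is available with ``fit=False``.

    All frames are used (no equilibration discard): the series is the
    diagnostic that justifies the discard.
    """
    topo = ensemble.topology
    idx = [
        i
        for i, res, atom in topo.iter_atoms()
        if atom.name == "CA" and (res.chain_id, res.resseq) not in exclude_residues
    ]
    if not idx:
        raise ValueError("exclusion spec leaves no CA atoms")
    idx = np.asarray(idx)
    out = RmsdSeries(
        replicates=[],
        dt_ps=ensemble.dt_ps,
        excluded=";".join(f"{c}:{r}" for c, r in sorted(exclude_residues)),
        superposed=fit,
    )
    for rep in ensemble.replicates:
        ref = rep[0][idx]
        series = np.empty(len(rep))
        series[0] = 0.0
        for fi in range(1, len(rep)):
            mob = rep[fi][idx]
            if fit:
                _, _, rmsd = superpose(mob, ref)
            else:
                rmsd = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
            series[fi] = rmsd
        out.replicates.append(series)
    return out
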