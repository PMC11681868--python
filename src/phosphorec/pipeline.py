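"""End-to-end report assembly: convergence → contacts → clamp → rotation → thermo."""

from __future__ import annotations

import hashlib
import json
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import (
    assign_states,
    circular_distribution,
    detect_peaks,
    dihedral_series,
    rotation_events,
)
from .geometry import ca_rmsd_series
from .recognition import (
    CONTACT_CUTOFF,
    HBOND_CUTOFF,
    bidentate_series,
    contact_frequency,
)
from .structure_io import ProtonationState, TrajectoryEnsemble, select

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _parse_residue_ref(ref: str) -> tuple[str, int, str]:
    """Parse 'CHAIN:RESSEQ[ICODE]' residue references, e.g. 'H:53' or 'H:95A'."""
    try:
        chain, num = ref.split(":")
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1].upper()
        return chain, int(num), icode
    except Exception as exc:
        raise ValueError(f"bad residue reference {ref!r} (expected CHAIN:RESSEQ)") from exc


@dataclass
class PipelineConfig:
    """Everything one trajectory-analysis run needs; validated before any stage."""

    phospho_res: str = "A:8"
    arg_res: str = "H:53"
    dihedral_atoms: tuple[str, str, str, str] = ("CB", "OG", "P", "OT")
    contact_cutoff: float = CONTACT_CUTOFF
    hbond_cutoff: float = HBOND_CUTOFF
    rmsd_exclude: tuple[str, ...] = ()  # residue refs excluded from the Cα set
    state_centers: tuple[float, ...] | None = None  # None: data-driven from peaks
    core_half_width: float = 40.0
    bin_width: float = 5.0
    min_report_pct: float = 0.0
    seed: int = 0

    def resolve(self, ensemble: TrajectoryEnsemble) -> dict:
        """Fail fast: resolve every selection against the topology."""
        topo = ensemble.topology
        c, n, i = _parse_residue_ref(self.phospho_res)
        phospho = topo.find_residue(c, n, i)
        c, n, i = _parse_residue_ref(self.arg_res)
        arg = topo.find_residue(c, n, i)
        quad = []
        pc, pn, pi = _parse_residue_ref(self.phospho_res)
        for name in self.dihedral_atoms:
            spec = f"chain {pc} and resseq {pn}{pi} and name {name}"
            hits = select(topo, spec)
            if len(hits) != 1:
                raise ValueError(
                    f"dihedral atom {name!r}: selection {spec!r} matched {len(hits)} atoms"
                )
            quad.append(hits[0])
        exclude = {(_parse_residue_ref(r)[0], _parse_residue_ref(r)[1]) for r in self.rmsd_exclude}
        return {"phospho": phospho, "arg": arg, "quad": tuple(quad), "exclude": exclude}

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    ensemble: TrajectoryEnsemble,
    config: PipelineConfig,
    out_dir: str | Path,
    quiet: bool = False,
) -> dict:
    """Run every analysis stage and write the report bundle.

    Emits rmsd.tsv, contacts.tsv, bidentate.tsv, dihedral.tsv, histogram.tsv,
    kinetics.json and summary.json into ``out_dir``.  Identical inputs and
    config produce byte-identical outputs.  On any stage failure the partial
    outputs are removed and :class:`PipelineError` names the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def log(msg: str) -> None:
        if not quiet:
            print(msg, file=sys.stderr)

    def emit_df(df, name: str, floatfmt: str = "%.4f") -> None:
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False, float_format=floatfmt)
        written.append(p)

    stage = "resolve-selections"
    try:
        sel = config.resolve(ensemble)

        stage = "rmsd-convergence"
        log("stage: rmsd-convergence")
        rmsd = ca_rmsd_series(ensemble, exclude_residues=sel["exclude"])
        emit_df(rmsd.to_dataframe(), "rmsd.tsv")

        stage = "contact-frequency"
        log("stage: contact-frequency")
        contacts = contact_frequency(
            ensemble,
            sel["phospho"],
            cutoff=config.contact_cutoff,
            min_report=config.min_report_pct,
        )
        p = out_dir / "contacts.tsv"
        contacts.to_tsv(p)
        written.append(p)

        stage = "bidentate"
        log("stage: bidentate")
        clamp = bidentate_series(
            ensemble, sel["arg"], sel["phospho"], cutoff=config.hbond_cutoff
        )
        emit_df(clamp.to_dataframe(), "bidentate.tsv")

        stage = "dihedral"
        log("stage: dihedral")
        series = dihedral_series(ensemble, sel["quad"])
        emit_df(series.to_dataframe(), "dihedral.tsv")
        hist = circular_distribution(series, bin_width=config.bin_width)
        emit_df(hist.to_dataframe(), "histogram.tsv", floatfmt="%.6f")
        peaks = detect_peaks(hist)

        stage = "rotation-kinetics"
        log("stage: rotation-kinetics")
        fold = ensemble.protonation_state.symmetry_fold
        kinetics = None
        if peaks:
            if config.state_centers is not None:
                centers = config.state_centers
            else:
                centers = tuple(p.center for p in peaks)
            try:
                assignment = assign_states(series, centers, config.core_half_width)
                kinetics = rotation_events(assignment, symmetry_fold=fold)
            except ValueError as exc:
                log(f"rotation-kinetics skipped: {exc}")
        p = out_dir / "kinetics.json"
        with open(p, "w") as fh:
            json.dump(kinetics.to_dict() if kinetics else {"n_events": None}, fh, indent=1)
        written.append(p)

        stage = "summary"
        summary = {
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()},
            "config_digest": config.digest(),
            "protonation_state": ensemble.protonation_state.value,
            "n_replicates": ensemble.n_replicates,
            "n_frames": [len(r) for r in ensemble.replicates],
            "dt_ps": ensemble.dt_ps,
            "equilibration_fraction": ensemble.equilibration_fraction,
            "cutoffs": {"contact_A": config.contact_cutoff, "hbond_A": config.hbond_cutoff},
            "rmsd_mean_A": float(np.mean([s.mean() for s in rmsd.replicates])),
            "n_contact_residues_ge10pct": int((contacts.table["mean_pct"] >= 10).sum()),
            "bidentate_fraction_pooled": clamp.fraction_pooled,
            "bidentate_fraction_per_replicate": clamp.fraction_per_replicate,
            "n_dihedral_peaks": len(peaks),
            "peaks": [
                {"center_deg": p.center, "mass": p.mass} for p in peaks
            ],
            "n_rotation_events": kinetics.n_events if kinetics else 0,
            "mean_dwell_ns": (kinetics.mean_dwell_ns if kinetics else None),
            "flags": {
                "single_peak": len(peaks) == 1,
                "clamp_ge_0.95": clamp.fraction_pooled >= 0.95,
            },
        }
        p = out_dir / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=1, allow_nan=True)
        written.append(p)
        return summary
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
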