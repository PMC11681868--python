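"""ITC-derived binding thermodynamics.

Starts from fitted dissociation constants and binding enthalpies (isotherm
fitting itself is upstream) and derives the standard quantities:

    ΔG = RT ln K_D          (K_D in molar; negative for sub-molar K_D)
    TΔS = ΔH − ΔG
    ΔΔG = RT ln(K_D ratio)  (mutant fold changes, phospho/non-phospho
                             selectivity)

with R = 1.9872e-3 kcal/(mol·K) so all energies are in kcal/mol, and a typed
"no measurable binding" sentinel instead of NaN arithmetic.  A packaged TSV
fixture ships the wildtype/mutant ITC table of the two anti-phosphosite
clones (A4, C7) used throughout the tests and reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

__all__ = [
    "R_KCAL",
    "DEFAULT_T_K",
    "NO_BINDING",
    "NoBinding",
    "ThermoRecord",
    "BindingComparison",
    "dG_from_Kd",
    "Kd_from_dG",
    "entropy_term",
    "fold_change",
    "selectivity",
    "load_itc_table",
    "packaged_itc_table_path",
    "derive_table",
]

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872e-3

#: Default analysis temperature (K).  The ITC temperature was not reported;
#: 298.15 K is assumed (simulations used 298 K) and echoed in every report.
DEFAULT_T_K = 298.15


class NoBinding:
    """Sentinel for titrations with no measurable binding."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NO_BINDING"


NO_BINDING = NoBinding()


def dG_from_Kd(K_D: float, T: float = DEFAULT_T_K) -> float:
    """Binding free energy ΔG = RT ln K_D in kcal/mol (K_D in molar)."""
    if not (K_D > 0):
        raise ValueError(f"K_D must be positive (molar); got {K_D}")
    if not (T > 0):
        raise ValueError(f"temperature must be positive; got {T}")
    return R_KCAL * T * math.log(K_D)


def Kd_from_dG(dG: float, T: float = DEFAULT_T_K) -> float:
    """Inverse of :func:`dG_from_Kd`."""
    if not (T > 0):
        raise ValueError(f"temperature must be positive; got {T}")
    return math.exp(dG / (R_KCAL * T))


def entropy_term(dH: float, dG: float) -> float:
    """Entropic contribution TΔS = ΔH − ΔG (kcal/mol)."""
    if not (math.isfinite(dH) and math.isfinite(dG)):
        raise ValueError("dH and dG must be finite")
    return dH - dG


def fold_change(K_D_mut: float, K_D_wt: float) -> float:
    """Affinity-loss ratio K_D(mut)/K_D(wt); report layer rounds to integer."""
    if not (K_D_mut > 0 and K_D_wt > 0):
        raise ValueError("dissociation constants must be positive")
    return K_D_mut / K_D_wt


@dataclass(frozen=True)
class BindingComparison:
    """Ratio of two dissociation constants and the corresponding ΔΔG."""

    numerator_label: str
    denominator_label: str
    ratio: float | NoBinding
    ddG_kcal: float | NoBinding
    T: float = DEFAULT_T_K

    @property
    def no_binding(self) -> bool:
        return isinstance(self.ratio, NoBinding)

    def summary(self) -> str:
        if self.no_binding:
            return (
                f"{self.numerator_label} vs {self.denominator_label}: "
                "no measurable binding in numerator"
            )
        return (
            f"{self.numerator_label} vs {self.denominator_label}: "
            f"ratio {self.ratio:.1f} (ΔΔG {self.ddG_kcal:+.2f} kcal/mol at {self.T:.2f} K)"
        )


def selectivity(
    K_D_nonphospho: float,
    K_D_phospho: float,
    T: float = DEFAULT_T_K,
    numerator_label: str = "non-phospho",
    denominator_label: str = "phospho",
) -> BindingComparison:
    """Phospho/non-phospho selectivity as a K_D ratio and ΔΔG.

    ``K_D_nonphospho`` may be ``math.inf`` (or :data:`NO_BINDING`) when the
    non-phosphorylated antigen shows no measurable binding; the comparison
    then carries the no-binding sentinel instead of numbers.
    """
    if isinstance(K_D_nonphospho, NoBinding) or (
        isinstance(K_D_nonphospho, float) and math.isinf(K_D_nonphospho)
    ):
        return BindingComparison(numerator_label, denominator_label, NO_BINDING, NO_BINDING, T)
    if not (K_D_nonphospho > 0 and K_D_phospho > 0):
        raise ValueError("dissociation constants must be positive")
    ratio = K_D_nonphospho / K_D_phospho
    return BindingComparison(
        numerator_label, denominator_label, ratio, R_KCAL * T * math.log(ratio), T
    )


@dataclass
class ThermoRecord:
    """One clone/antigen titration with derived ΔG and TΔS.

    K_D is stored in molar; uncertainties are triplicate SDs carried through
    first-order (σ_ΔG = RT·σ_K/K).  ``no_binding`` records have no numeric
    fields.  ``dG_printed``/``TdS_printed`` (and their ±) hold externally
    reported values for cross-checking; they never feed the derivation.
    """

    clone: str
    antigen: str = "phospho"
    K_D: float | None = None
    K_D_sd: float | None = None
    dH: float | None = None
    dH_sd: float | None = None
    T: float = DEFAULT_T_K
    n_replicates: int = 3
    no_binding: bool = False
    dG: float | None = None
    dG_sd: float | None = None
    TdS: float | None = None
    TdS_sd: float | None = None
    dG_printed: float | None = None
    dG_printed_sd: float | None = None
    TdS_printed: float | None = None
    TdS_printed_sd: float | None = None

    def derive(self) -> "ThermoRecord":
        """Return a copy with ΔG, TΔS and first-order uncertainties filled in."""
        if self.no_binding:
            return replace(self)
        if self.K_D is None:
            raise ValueError(f"{self.clone}/{self.antigen}: K_D missing")
        dG = dG_from_Kd(self.K_D, self.T)
        dG_sd = (
            R_KCAL * self.T * self.K_D_sd / self.K_D if self.K_D_sd is not None else None
        )
        TdS = entropy_term(self.dH, dG) if self.dH is not None else None
        TdS_sd = None
        if self.dH_sd is not None and dG_sd is not None:
            TdS_sd = math.hypot(self.dH_sd, dG_sd)
        rec = replace(self, dG=dG, dG_sd=dG_sd, TdS=TdS, TdS_sd=TdS_sd)
        if rec.TdS is not None:
            assert abs(rec.dG - (rec.dH - rec.TdS)) < 1e-9
        return rec


def packaged_itc_table_path():
    """Path-like handle to the packaged wildtype/mutant ITC fixture."""
    return resources.files("phosphorec.data") / "itc_profiles.tsv"


def load_itc_table(path=None) -> list[ThermoRecord]:
    """Load an ITC TSV (clone, antigen, Kd_nM, Kd_sd_nM, dH, dH_sd, T_K, ...).

    ``Kd_nM`` equal to ``no_binding`` marks an undetectable titration.
    Optional ``dG_printed``/``TdS_printed`` (± ``_sd``) columns carry
    externally reported values for comparison.  Defaults to the packaged
    fixture.  Returns derived records.
    """
    if path is None:
        path = packaged_itc_table_path()
    df = pd.read_csv(str(path), sep="\t", comment="#", dtype={"clone": str, "antigen": str})
    records = []
    for _, row in df.iterrows():
        no_bind = str(row["Kd_nM"]).strip().lower() in ("no_binding", "nobinding", "inf", "nan")

        def _get(col):
            if col not in df.columns or pd.isna(row.get(col)):
                return None
            return float(row[col])

        kd_sd = _get("Kd_sd_nM")
        rec = ThermoRecord(
            clone=str(row["clone"]),
            antigen=str(row.get("antigen", "phospho")),
            K_D=None if no_bind else float(row["Kd_nM"]) * 1e-9,
            K_D_sd=None if no_bind or kd_sd is None else kd_sd * 1e-9,
            dH=None if no_bind else _get("dH"),
            dH_sd=None if no_bind else _get("dH_sd"),
            T=_get("T_K") or DEFAULT_T_K,
            no_binding=no_bind,
            dG_printed=_get("dG_printed"),
            dG_printed_sd=_get("dG_printed_sd"),
            TdS_printed=_get("TdS_printed"),
            TdS_printed_sd=_get("TdS_printed_sd"),
        )
        records.append(rec.derive())
    return records


def derive_table(records: list[ThermoRecord]) -> pd.DataFrame:
    """Tabulate derived thermodynamics, mirroring the ITC report layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "clone": r.clone,
                "antigen": r.antigen,
                "Kd_nM": None if r.no_binding else r.K_D * 1e9,
                "dG_kcal": None if r.no_binding else round(r.dG, 2),
                "dH_kcal": None if r.no_binding else r.dH,
                "TdS_kcal": None if r.no_binding or r.TdS is None else round(r.TdS, 2),
                "dG_sd": None if r.no_binding or r.dG_sd is None else round(r.dG_sd, 2),
                "TdS_sd": None if r.no_binding or r.TdS_sd is None else round(r.TdS_sd, 2),
                "T_K": r.T,
                "no_binding": r.no_binding,
            }
        )
    return pd.DataFrame(rows)
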