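"""Core kinetic model of the EGFR→SOS→Ras→ERK→MYC→{miR-9, let-7}→E-Cadherin→MMP
signaling cascade.

The model tracks eight dynamic concentrations (all in nM, time in minutes):

========  =======================================
x1  sos   active SOS
x2  ras   active Ras
x3  erk   active ERK
x4  myc   MYC protein
x5  mir9  miR-9
x6  let7  let-7
x7  ecad  E-Cadherin
x8  mmp   MMP mRNA
========  =======================================

The three upstream species cycle between active and inactive forms; only the
active pools are state variables and the inactive pools are recovered from the
conserved totals at every evaluation.  Activation/deactivation of SOS, Ras and
ERK follow Michaelis–Menten kinetics: the constant EGF-EGFR complex catalyzes
SOS activation while active ERK catalyzes SOS deactivation (the negative
feedback); active SOS catalyzes Ras activation, repressed by let-7 through a
multiplicative inhibition factor; active Ras catalyzes ERK activation.  MYC is
produced in proportion to active ERK.  MYC drives miR-9 through a fourth-order
Hill function and represses let-7 through an inhibition factor.  E-Cadherin is
produced in proportion to let-7 and inhibited by miR-9; MMP mRNA is produced at
a constant rate and removed at a rate proportional to E-Cadherin.  All species
decay by linear mass action.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_LABELS",
    "SpeciesState",
    "ParameterSet",
    "michaelis_menten_flux",
    "hill_activation",
    "inhibition_factor",
    "rhs",
    "rhs_array",
]

#: Canonical species order (x1..x8).
SPECIES = ("sos", "ras", "erk", "myc", "mir9", "let7", "ecad", "mmp")

SPECIES_LABELS = {
    "sos": "active SOS",
    "ras": "active Ras",
    "erk": "active ERK",
    "myc": "MYC protein",
    "mir9": "miR-9",
    "let7": "let-7",
    "ecad": "E-Cadherin",
    "mmp": "MMP mRNA",
}


class ModelDomainError(ValueError):
    """Raised when an input violates a kinetic-function or state invariant."""


def michaelis_menten_flux(catalyst: float, substrate, rate: float, km: float):
    """Saturating conversion flux ``rate * catalyst * substrate / (km + substrate)``.

    Used for each active↔inactive conversion of SOS, Ras and ERK; ``catalyst``
    is the concentration of the catalyzing species (EGF-EGFR complex, active
    ERK, active SOS or active Ras), ``substrate`` the pool being converted.
    Returns a flux in nM/min.
    """
    if km <= 0:
        raise ModelDomainError(f"Michaelis constant must be positive, got {km}")
    if catalyst < 0 or rate < 0 or np.any(np.asarray(substrate) < 0):
        raise ModelDomainError("negative concentration or rate in Michaelis-Menten flux")
    return rate * catalyst * substrate / (km + substrate)


def hill_activation(x, k: float, n: int = 4):
    """Sigmoidal activation ``x**n / (k**n + x**n)`` in [0, 1].

    Fourth order by default, as used for the MYC→miR-9 transcriptional drive
    (MYC is a transcription factor and activation involves several enzymatic
    steps, hence the cooperative form).
    """
    if k <= 0:
        raise ModelDomainError(f"Hill saturation constant must be positive, got {k}")
    if n < 1:
        raise ModelDomainError(f"Hill order must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ModelDomainError("negative concentration in Hill function")
    xn = (x / k) ** n
    out = xn / (1.0 + xn)
    return float(out) if out.ndim == 0 else out


def inhibition_factor(x, k: float):
    """Multiplicative repression ``1 / (1 + x/k)`` in (0, 1].

    Used for let-7 repression of Ras activation, MYC repression of let-7
    production, and miR-9 repression of E-Cadherin production.
    """
    if k <= 0:
        raise ModelDomainError(f"control constant must be positive, got {k}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ModelDomainError("negative concentration in inhibition factor")
    out = 1.0 / (1.0 + x / k)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpeciesState:
    """The eight dynamic concentrations, in nM."""

    sos: float
    ras: float
    erk: float
    myc: float
    mir9: float
    let7: float
    ecad: float
    mmp: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "SpeciesState":
        x = np.asarray(x, dtype=float)
        if x.shape != (8,):
            raise ModelDomainError(f"state vector must have shape (8,), got {x.shape}")
        return cls(**{s: float(v) for s, v in zip(SPECIES, x)})

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())

    def validate(self, params: "ParameterSet | None" = None, tol: float = 0.0) -> None:
        for s in SPECIES:
            v = getattr(self, s)
            if not np.isfinite(v) or v < -tol:
                raise ModelDomainError(f"species '{s}' must be finite and >= 0, got {v}")
        if params is not None:
            for s, total in (("sos", params.sos_total), ("ras", params.ras_total),
                             ("erk", params.erk_total)):
                if getattr(self, s) > total * (1.0 + 1e-12) + tol:
                    raise ModelDomainError(
                        f"active {s} ({getattr(self, s)}) exceeds conserved total ({total})")


# parameter-name -> human description, mirroring the descriptive-name column of
# the summary parameter table; used for validation messages and audit output.
PARAMETER_DESCRIPTIONS = {
    "egfr_complex": "concentration of EGF-EGFR complex (constant)",
    "sos_total": "total concentration of SOS",
    "ras_total": "total concentration of Ras",
    "erk_total": "total concentration of ERK",
    "km_sos_act": "saturation of inactive SOS on active SOS",
    "km_sos_deact": "saturation of active SOS on inactive SOS",
    "km_ras_act": "saturation of inactive Ras on active Ras",
    "km_ras_deact": "saturation of active Ras on inactive Ras",
    "km_erk_act": "saturation of inactive ERK on active ERK",
    "km_erk_deact": "saturation of active ERK on inactive ERK",
    "k_let7_on_ras": "control of let-7 on Ras",
    "k_myc_on_mir9": "saturation of MYC on miR-9",
    "k_myc_on_let7": "control of MYC on let-7",
    "k_mir9_on_ecad": "control of miR-9 on E-Cadherin",
    "k_ecad_on_mmp": "control of E-Cadherin on MMP mRNA",
    "prod_sos": "catalytic production rate of active SOS",
    "prod_ras": "catalytic production rate of active Ras",
    "prod_erk": "catalytic production rate of active ERK",
    "prod_myc": "catalytic production rate of MYC",
    "prod_mir9": "catalytic production rate of miR-9",
    "prod_let7": "catalytic production rate of let-7",
    "prod_ecad": "catalytic production rate of E-Cadherin",
    "prod_mmp": "catalytic production rate of MMP",
    "deg_sos": "degradation (ERK-catalyzed deactivation) rate of active SOS",
    "deg_ras": "degradation rate of active Ras",
    "deg_erk": "degradation rate of active ERK",
    "deg_myc": "degradation rate of MYC protein",
    "deg_mir9": "degradation rate of miR-9",
    "deg_let7": "degradation rate of let-7",
    "deg_ecad": "degradation rate of E-Cadherin",
    "deg_mmp": "degradation rate of MMP mRNA",
}


@dataclass(frozen=True)
class ParameterSet:
    """All kinetic constants, conserved totals and the healthy steady state.

    ``deg_sos`` is the ERK→SOS negative-feedback constant: SOS deactivation is
    catalyzed by active ERK with catalytic constant ``deg_sos`` (units
    1/(nM·min)), so weakening the feedback means lowering ``deg_sos``.  Ras and
    ERK deactivation are catalyzed by constant phosphatase pools (Ras-Gap,
    PP2A) folded into ``deg_ras`` / ``deg_erk`` (units 1/min).
    """

    egfr_complex: float
    sos_total: float
    ras_total: float
    erk_total: float
    steady_state: SpeciesState
    km_sos_act: float
    km_sos_deact: float
    km_ras_act: float
    km_ras_deact: float
    km_erk_act: float
    km_erk_deact: float
    k_let7_on_ras: float
    k_myc_on_mir9: float
    k_myc_on_let7: float
    k_mir9_on_ecad: float
    k_ecad_on_mmp: float
    prod_sos: float
    prod_ras: float
    prod_erk: float
    prod_myc: float
    prod_mir9: float
    prod_let7: float
    prod_ecad: float
    prod_mmp: float
    deg_sos: float
    deg_ras: float
    deg_erk: float
    deg_myc: float
    deg_mir9: float
    deg_let7: float
    deg_ecad: float
    deg_mmp: float
    hill_order_mir9: int = 4
    units: dict = field(default_factory=lambda: {"concentration": "nM", "time": "min"})

    #: scenario-facing alias for the ERK→SOS negative-feedback constant
    FEEDBACK_ALIAS = "erk_sos_feedback"

    def validate(self) -> None:
        for f in fields(self):
            if f.name in ("steady_state", "units", "hill_order_mir9"):
                continue
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                desc = PARAMETER_DESCRIPTIONS.get(f.name, f.name)
                raise ModelDomainError(f"parameter '{f.name}' ({desc}) must be positive, got {v}")
        if not (isinstance(self.hill_order_mir9, (int, np.integer)) and self.hill_order_mir9 >= 1):
            raise ModelDomainError(f"hill_order_mir9 must be a positive integer, got {self.hill_order_mir9}")
        self.steady_state.validate()
        for s, total in (("sos", self.sos_total), ("ras", self.ras_total), ("erk", self.erk_total)):
            if getattr(self.steady_state, s) >= total:
                raise ModelDomainError(
                    f"steady-state active {s} must lie strictly below the total {total}")

    # --- name-based access used by scenarios and sensitivity analysis ----
    def get(self, name: str) -> float:
        if name == self.FEEDBACK_ALIAS:
            name = "deg_sos"
        if name.startswith("steady_state_"):
            return getattr(self.steady_state, name[len("steady_state_"):])
        return getattr(self, name)

    def with_values(self, **overrides: float) -> "ParameterSet":
        """Return a copy with named parameters replaced.

        Accepts plain field names, the ``erk_sos_feedback`` alias, and
        ``steady_state_<species>`` for the stored healthy concentrations.
        """
        ss_over = {}
        flat = {}
        for name, value in overrides.items():
            if name == self.FEEDBACK_ALIAS:
                flat["deg_sos"] = value
            elif name.startswith("steady_state_"):
                ss_over[name[len("steady_state_"):]] = value
            else:
                if name not in {f.name for f in fields(self)}:
                    raise KeyError(f"unknown parameter '{name}'")
                flat[name] = value
        if ss_over:
            flat["steady_state"] = replace(self.steady_state, **ss_over)
        return replace(self, **flat)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            if f.name == "steady_state":
                d["steady_state"] = {s: getattr(self.steady_state, s) for s in SPECIES}
            elif f.name == "units":
                d["units"] = dict(self.units)
            else:
                d[f.name] = getattr(self, f.name)
        return d

    @classmethod
    def from_dict(cls, d: dict, strict: bool = False) -> "ParameterSet":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            if strict:
                raise ModelDomainError(f"unknown parameter keys: {sorted(unknown)}")
            for k in unknown:
                d.pop(k)
        missing = {f.name for f in fields(cls)
                   if f.name not in d and f.name not in ("hill_order_mir9", "units")}
        if missing:
            descs = {m: PARAMETER_DESCRIPTIONS.get(m, m) for m in sorted(missing)}
            raise ModelDomainError(f"missing parameter entries: {descs}")
        d["steady_state"] = SpeciesState(**d["steady_state"])
        if "hill_order_mir9" in d:
            d["hill_order_mir9"] = int(d["hill_order_mir9"])
        p = cls(**d)
        p.validate()
        return p


def rhs_array(x: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Vectorized right-hand side.

    ``x`` has the 8 species along the *last* axis; any number of leading axes
    (time points, ensemble members) is allowed.  Returns dx/dt with the same
    shape.  Inactive SOS/Ras/ERK pools are recovered from the conserved totals.
    """
    x = np.asarray(x, dtype=float)
    x1, x2, x3, x4, x5, x6, x7, x8 = (x[..., i] for i in range(8))

    inact_sos = p.sos_total - x1
    inact_ras = p.ras_total - x2
    inact_erk = p.erk_total - x3

    dx1 = (p.prod_sos * p.egfr_complex * inact_sos / (p.km_sos_act + inact_sos)
           - p.deg_sos * x3 * x1 / (p.km_sos_deact + x1))
    dx2 = (p.prod_ras * x1 * inact_ras / (p.km_ras_act + inact_ras)
           / (1.0 + x6 / p.k_let7_on_ras)
           - p.deg_ras * x2 / (p.km_ras_deact + x2))
    dx3 = (p.prod_erk * x2 * inact_erk / (p.km_erk_act + inact_erk)
           - p.deg_erk * x3 / (p.km_erk_deact + x3))
    dx4 = p.prod_myc * x3 - p.deg_myc * x4
    hn = (x4 / p.k_myc_on_mir9) ** p.hill_order_mir9
    dx5 = p.prod_mir9 * hn / (1.0 + hn) - p.deg_mir9 * x5
    dx6 = p.prod_let7 / (1.0 + x4 / p.k_myc_on_let7) - p.deg_let7 * x6
    dx7 = p.prod_ecad * x6 / (1.0 + x5 / p.k_mir9_on_ecad) - p.deg_ecad * x7
    dx8 = p.prod_mmp - p.deg_mmp * x8 * x7 / p.k_ecad_on_mmp

    return np.stack([dx1, dx2, dx3, dx4, dx5, dx6, dx7, dx8], axis=-1)


def rhs(state: SpeciesState | np.ndarray, params: ParameterSet,
        validate: bool = True) -> np.ndarray:
    """Instantaneous derivatives (nM/min) of the eight species."""
    if isinstance(state, SpeciesState):
        if validate:
            state.validate(params)
        x = state.as_array()
    else:
        x = np.asarray(state, dtype=float)
        if validate:
            SpeciesState.from_array(x).validate(params)
    return rhs_array(x, params)
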