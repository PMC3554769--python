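"""Biophysical calibration: derive every kinetic parameter from primitive
measurements (cell geometry, molecule copy numbers, half-lives, binding rates)
and steady-state closure.

The chain, in order:

1. **Geometry.** The reference cell is approximated as a sphere with the total
   HeLa volume (Fujioka et al. 2006); the cell-surface pool of EGF-EGFR
   complexes is converted to a concentration through a thin membrane shell
   (area × shell thickness).  The shell thickness cancels against the matching
   factor in the SOS activation constant, so it only fixes the unit of the
   (constant) complex concentration.
2. **EGF/EGFR binding equilibrium.** Complex count from the steady-state
   balance kon·EGF·(R_T − C) = koff·C, i.e. C = R_T·EGF/(EGF + koff/kon).
3. **Copy number → concentration.** Cytoplasmic species use the cytoplasm
   volume, nuclear MYC the nucleus volume (Rudolph et al. 1999 count), let-7
   the HeLa copy number of Lim et al. (2003), and the MMP mRNA steady state
   comes from a per-tissue-mass copy number divided through the lung tissue
   density (Safranek et al. 2009; Hopkins 2007).
4. **Half-life → rate.** First-order degradation rates ln 2 / t_half for MYC,
   miR-9, let-7, E-Cadherin and MMP mRNA.
5. **Cascade kinetics.** Per-molecule catalytic constants and molecule-unit
   Michaelis constants of the Brown et al. (2004) EGFR cascade are rescaled to
   concentration units; the constant phosphatase pools (Ras-Gap, PP2A) are
   folded into the Ras/ERK deactivation rates, active P90Rsk is proxied by
   active ERK for the SOS feedback, and active MEK by active Ras for ERK
   activation (count-ratio rescaling).
6. **Steady-state closure.** The upstream (SOS/Ras/ERK) fixed point is solved
   numerically with let-7 held at its healthy level; the downstream production
   rates (MYC, miR-9, let-7, E-Cadherin, MMP) are then solved exactly from the
   steady-state identities, which makes the healthy state a fixed point of the
   full system by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import ModelDomainError, ParameterSet, SpeciesState, hill_activation

__all__ = [
    "AVOGADRO",
    "CalibrationPrimitives",
    "CalibrationError",
    "halflife_to_rate",
    "molecules_to_concentration",
    "sphere_geometry",
    "equilibrium_complex",
    "solve_upstream_steady_state",
    "derive_parameter_set",
]

AVOGADRO = 6.022e23  # 1/mol


class CalibrationError(ValueError):
    """A calibration sub-derivation failed; the message names the step."""


def halflife_to_rate(t_half: float) -> float:
    """First-order degradation rate ln(2)/t_half (1/min for t_half in min)."""
    if t_half <= 0:
        raise ModelDomainError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def molecules_to_concentration(count: float, volume: float) -> float:
    """Concentration in mol/L of ``count`` molecules in ``volume`` liters."""
    if volume <= 0:
        raise ModelDomainError(f"volume must be positive, got {volume}")
    if count < 0:
        raise ModelDomainError(f"molecule count must be >= 0, got {count}")
    return count / (AVOGADRO * volume)


def molecules_to_nM(count: float, volume: float) -> float:
    return molecules_to_concentration(count, volume) * 1e9


def sphere_geometry(volume: float) -> tuple[float, float]:
    """Radius and surface area of a sphere of the given volume."""
    if volume <= 0:
        raise ModelDomainError(f"volume must be positive, got {volume}")
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    area = 4.0 * math.pi * radius ** 2
    return radius, area


def equilibrium_complex(egf_count: float, egfr_total: float,
                        kon: float, koff: float) -> float:
    """Steady-state EGF-EGFR complex count from the binding balance.

    Binding and unbinding balance at steady state,
    kon·EGF·(R_T − C) = koff·C, giving C = R_T·EGF/(EGF + koff/kon).
    EGF is assumed in excess (free ≈ total).
    """
    if kon <= 0:
        raise ModelDomainError(f"kon must be positive, got {kon}")
    if egf_count < 0 or egfr_total < 0 or koff < 0:
        raise ModelDomainError("counts and rates must be >= 0")
    return egfr_total * egf_count / (egf_count + koff / kon)


@dataclass(frozen=True)
class CalibrationPrimitives:
    """Biophysical inputs from which the full parameter set is derived.

    Volumes in liters, counts in molecules/cell, half-lives in minutes,
    per-molecule rates in 1/(molecule·min), Michaelis constants in molecules.
    ``kinetics_molecular`` keys: kf_/km_act_/kd_/km_deact_ for sos, ras, erk.
    """

    hela_total_volume: float = 2.6e-12        # L (Fujioka et al. 2006)
    cytoplasm_volume: float = 1.9e-12         # L
    nucleus_volume: float = 7.0e-13           # L
    membrane_shell_thickness: float = 1.0e-8  # m (10 nm shell for surface species)
    avogadro: float = AVOGADRO

    egf_count: float = 1.0e4
    egfr_total_count: float = 8.0e4
    kon: float = 1.0e-4                       # 1/(molecule·min)
    koff: float = 1.0                         # 1/min  (Kd = koff/kon = 1e4 molecules)

    molecule_counts: dict = field(default_factory=lambda: {
        "sos": 1.0e5, "ras": 1.0e5, "erk": 6.0e5, "mek": 6.0e5,
        "p90rsk": 1.0e5, "ras_gap": 1.2e4, "pp2a": 1.0e5,
        "myc_nucleus": 6.0e4, "let7": 1.0e4, "mir9": 1.0,
    })
    half_lives: dict = field(default_factory=lambda: {
        # minutes; MYC (Lüscher & Eisenman), miR-9 brain tissue (Sethi & Lukiw),
        # let-7 after TAM (Iliopoulos et al.), E-Cadherin (Fujita et al.),
        # MMP-9 mRNA (Akool et al.)
        "myc": 30.0, "mir9": 60.0, "let7": 240.0, "ecad": 300.0, "mmp": 720.0,
    })
    kinetics_molecular: dict = field(default_factory=lambda: {
        # Brown et al. (2004)-style cascade constants, molecule units
        "kf_sos": 2.5e-4, "km_act_sos": 1.0e5,
        "kd_sos": 4.0e-4, "km_deact_sos": 2.5e4,
        "kf_ras": 2.2e-3, "km_act_ras": 1.0e5,
        "kd_ras": 5.0e-3, "km_deact_ras": 2.5e4,
        "kf_erk": 1.8e-3, "km_act_erk": 6.0e5,
        "kd_erk": 2.0e-3, "km_deact_erk": 1.5e5,
    })

    ecad_steady_nM: float = 100.0             # total E-Cadherin (Chaplain 2011)
    mmp_copies_per_gram_tissue: float = 6.0e8  # MMP-9 mRNA per g lung tissue
    lung_tissue_density: float = 1.05e3       # g/L (≈1.05 g/cm^3)
    mir9_overexpression_factor: float = 30.0  # tumor/normal miR-9 fold (tissue data)

    control_factors: dict = field(default_factory=lambda: {
        # estimated control/saturation constants, as multiples of the
        # corresponding healthy steady-state concentration
        # weak repression: the let-7 arm modulates Ras without dragging the
        # fast cascade onto the slow microRNA timescale
        "k_let7_on_ras_over_let7": 20.0,
        "k_myc_on_mir9_over_myc": 10.0,
        "k_myc_on_let7_over_myc": 1.0,
        "k_mir9_on_ecad_over_mir9": 10.0,
        "k_ecad_on_mmp_over_ecad": 1.0,
    })

    def validate(self) -> None:
        scalars = {
            "hela_total_volume": self.hela_total_volume,
            "cytoplasm_volume": self.cytoplasm_volume,
            "nucleus_volume": self.nucleus_volume,
            "membrane_shell_thickness": self.membrane_shell_thickness,
            "egf_count": self.egf_count, "egfr_total_count": self.egfr_total_count,
            "kon": self.kon, "koff": self.koff,
            "ecad_steady_nM": self.ecad_steady_nM,
            "mmp_copies_per_gram_tissue": self.mmp_copies_per_gram_tissue,
            "lung_tissue_density": self.lung_tissue_density,
            "mir9_overexpression_factor": self.mir9_overexpression_factor,
        }
        for name, v in scalars.items():
            if not (np.isfinite(v) and v > 0):
                raise CalibrationError(f"primitive '{name}' must be positive, got {v}")
        for d in (self.molecule_counts, self.half_lives, self.kinetics_molecular,
                  self.control_factors):
            for k, v in d.items():
                if not (np.isfinite(v) and v > 0):
                    raise CalibrationError(f"primitive '{k}' must be positive, got {v}")
        if self.cytoplasm_volume >= self.hela_total_volume:
            raise CalibrationError("cytoplasm volume must be below the total cell volume")
        if self.nucleus_volume >= self.hela_total_volume:
            raise CalibrationError("nucleus volume must be below the total cell volume")

    def to_dict(self) -> dict:
        return {
            "hela_total_volume": self.hela_total_volume,
            "cytoplasm_volume": self.cytoplasm_volume,
            "nucleus_volume": self.nucleus_volume,
            "membrane_shell_thickness": self.membrane_shell_thickness,
            "avogadro": self.avogadro,
            "egf_count": self.egf_count,
            "egfr_total_count": self.egfr_total_count,
            "kon": self.kon,
            "koff": self.koff,
            "molecule_counts": dict(self.molecule_counts),
            "half_lives": dict(self.half_lives),
            "kinetics_molecular": dict(self.kinetics_molecular),
            "ecad_steady_nM": self.ecad_steady_nM,
            "mmp_copies_per_gram_tissue": self.mmp_copies_per_gram_tissue,
            "lung_tissue_density": self.lung_tissue_density,
            "mir9_overexpression_factor": self.mir9_overexpression_factor,
            "control_factors": dict(self.control_factors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationPrimitives":
        d = {k: v for k, v in d.items() if not k.startswith("_")}
        p = cls(**d)
        p.validate()
        return p


def _upstream_rhs(x: np.ndarray, p: ParameterSet, let7_level: float) -> np.ndarray:
    """SOS/Ras/ERK sub-system derivatives with let-7 held fixed."""
    x1, x2, x3 = x
    i_s, i_r, i_e = p.sos_total - x1, p.ras_total - x2, p.erk_total - x3
    return np.array([
        p.prod_sos * p.egfr_complex * i_s / (p.km_sos_act + i_s)
        - p.deg_sos * x3 * x1 / (p.km_sos_deact + x1),
        p.prod_ras * x1 * i_r / (p.km_ras_act + i_r) / (1.0 + let7_level / p.k_let7_on_ras)
        - p.deg_ras * x2 / (p.km_ras_deact + x2),
        p.prod_erk * x2 * i_e / (p.km_erk_act + i_e)
        - p.deg_erk * x3 / (p.km_erk_deact + x3),
    ])


def solve_upstream_steady_state(params: ParameterSet, let7_level: float,
                                horizon: float = 2.0e4, rtol: float = 1e-9,
                                ) -> tuple[float, float, float]:
    """Fixed point of the SOS/Ras/ERK sub-system at a fixed let-7 level.

    Integrates to a long horizon from the inactive state and polishes with a
    root-finder; raises :class:`CalibrationError` carrying the residual if the
    relative residual stays above ``rtol``.
    """
    if let7_level < 0:
        raise ModelDomainError("let-7 level must be >= 0")
    if params.egfr_complex == 0 or params.prod_sos == 0:
        return (0.0, 0.0, 0.0)
    sol = solve_ivp(lambda t, x: _upstream_rhs(x, params, let7_level),
                    (0.0, horizon), np.zeros(3), method="LSODA",
                    rtol=1e-10, atol=1e-14)
    x0 = sol.y[:, -1]
    res = root(lambda x: _upstream_rhs(x, params, let7_level), x0, method="hybr",
               options={"xtol": 1e-13})
    x = np.clip(res.x, 0.0, [params.sos_total, params.ras_total, params.erk_total])
    p = params
    x1, x2, x3 = x
    fluxes = np.array([  # one-sided flux magnitudes, used as the relative scale
        p.prod_sos * p.egfr_complex * (p.sos_total - x1) / (p.km_sos_act + p.sos_total - x1),
        p.deg_ras * x2 / (p.km_ras_deact + x2),
        p.deg_erk * x3 / (p.km_erk_deact + x3),
    ])
    rel = np.abs(_upstream_rhs(x, params, let7_level)) / np.maximum(fluxes, 1e-30)
    if np.max(rel) > rtol:
        raise CalibrationError(
            f"upstream steady-state solve did not converge: relative residual {np.max(rel):.3e}")
    return tuple(float(v) for v in x)


def derive_parameter_set(primitives: CalibrationPrimitives) -> ParameterSet:
    """Derive the full :class:`ParameterSet` from biophysical primitives.

    The returned set makes the configured healthy state a fixed point: exact
    algebraically for the MYC/miR-9/let-7/E-Cadherin/MMP equations, and to
    solver tolerance for the SOS/Ras/ERK cycle.
    """
    prim = primitives
    prim.validate()
    NA = prim.avogadro

    # 1. geometry and unit conversions ---------------------------------
    _, area_m2 = sphere_geometry(prim.hela_total_volume * 1e-3)  # L -> m^3
    shell_volume = area_m2 * prim.membrane_shell_thickness * 1e3  # m^3 -> L
    counts_per_nM_shell = 1e-9 * NA * shell_volume
    counts_per_nM_cyt = 1e-9 * NA * prim.cytoplasm_volume

    complex_count = equilibrium_complex(prim.egf_count, prim.egfr_total_count,
                                        prim.kon, prim.koff)
    egfr_complex = complex_count / counts_per_nM_shell

    mc = prim.molecule_counts
    sos_total = mc["sos"] / counts_per_nM_cyt
    ras_total = mc["ras"] / counts_per_nM_cyt
    erk_total = mc["erk"] / counts_per_nM_cyt

    myc_ss = mc["myc_nucleus"] / (1e-9 * NA * prim.nucleus_volume)
    let7_ss = mc["let7"] / counts_per_nM_cyt
    mir9_ss = mc["mir9"] / counts_per_nM_cyt
    ecad_ss = prim.ecad_steady_nM
    # copies per gram × g/L → copies/L → mol/L → nM
    mmp_ss = prim.mmp_copies_per_gram_tissue * prim.lung_tissue_density / NA * 1e9

    # 2. half-life → degradation rates ---------------------------------
    hl = prim.half_lives
    deg_myc = halflife_to_rate(hl["myc"])
    deg_mir9 = halflife_to_rate(hl["mir9"])
    deg_let7 = halflife_to_rate(hl["let7"])
    deg_ecad = halflife_to_rate(hl["ecad"])
    deg_mmp = halflife_to_rate(hl["mmp"])

    # 3. cascade kinetic constants (molecule → concentration units) ----
    km = prim.kinetics_molecular
    prod_sos = km["kf_sos"] * counts_per_nM_shell           # per nM complex
    km_sos_act = km["km_act_sos"] / counts_per_nM_cyt
    # active P90Rsk (SOS phosphatase) proxied by active ERK at full activation
    deg_sos = km["kd_sos"] * mc["p90rsk"] / erk_total       # 1/(nM·min)
    km_sos_deact = km["km_deact_sos"] / counts_per_nM_cyt

    prod_ras = km["kf_ras"] * counts_per_nM_cyt             # per nM active SOS
    km_ras_act = km["km_act_ras"] / counts_per_nM_cyt
    deg_ras = km["kd_ras"] * mc["ras_gap"]                  # 1/min (Ras-Gap folded)
    km_ras_deact = km["km_deact_ras"] / counts_per_nM_cyt

    # active MEK proxied by active Ras, rescaled by the total-count ratio
    prod_erk = km["kf_erk"] * counts_per_nM_cyt * (mc["mek"] / mc["ras"])
    km_erk_act = km["km_act_erk"] / counts_per_nM_cyt
    deg_erk = km["kd_erk"] * mc["pp2a"]                     # 1/min (PP2A folded)
    km_erk_deact = km["km_deact_erk"] / counts_per_nM_cyt

    # 4. estimated control/saturation constants ------------------------
    cf = prim.control_factors
    k_let7_on_ras = cf["k_let7_on_ras_over_let7"] * let7_ss
    k_myc_on_mir9 = cf["k_myc_on_mir9_over_myc"] * myc_ss
    k_myc_on_let7 = cf["k_myc_on_let7_over_myc"] * myc_ss
    k_mir9_on_ecad = cf["k_mir9_on_ecad_over_mir9"] * mir9_ss
    k_ecad_on_mmp = cf["k_ecad_on_mmp_over_ecad"] * ecad_ss

    # 5. upstream fixed point ------------------------------------------
    partial = ParameterSet(
        egfr_complex=egfr_complex, sos_total=sos_total, ras_total=ras_total,
        erk_total=erk_total,
        steady_state=SpeciesState(sos_total / 2, ras_total / 2, erk_total / 2,
                                  myc_ss, mir9_ss, let7_ss, ecad_ss, mmp_ss),
        km_sos_act=km_sos_act, km_sos_deact=km_sos_deact,
        km_ras_act=km_ras_act, km_ras_deact=km_ras_deact,
        km_erk_act=km_erk_act, km_erk_deact=km_erk_deact,
        k_let7_on_ras=k_let7_on_ras, k_myc_on_mir9=k_myc_on_mir9,
        k_myc_on_let7=k_myc_on_let7, k_mir9_on_ecad=k_mir9_on_ecad,
        k_ecad_on_mmp=k_ecad_on_mmp,
        prod_sos=prod_sos, prod_ras=prod_ras, prod_erk=prod_erk,
        prod_myc=1.0, prod_mir9=1.0, prod_let7=1.0, prod_ecad=1.0, prod_mmp=1.0,
        deg_sos=deg_sos, deg_ras=deg_ras, deg_erk=deg_erk,
        deg_myc=deg_myc, deg_mir9=deg_mir9, deg_let7=deg_let7,
        deg_ecad=deg_ecad, deg_mmp=deg_mmp,
    )
    try:
        sos_ss, ras_ss, erk_ss = solve_upstream_steady_state(partial, let7_ss)
    except CalibrationError as err:
        raise CalibrationError(f"cascade (SOS/Ras/ERK) calibration failed: {err}") from err
    if min(sos_ss, ras_ss, erk_ss) <= 0:
        raise CalibrationError(
            "cascade calibration produced a zero active steady state; "
            "check the EGF/EGFR binding and cascade kinetic primitives")

    # 6. downstream steady-state closure -------------------------------
    prod_myc = deg_myc * myc_ss / erk_ss
    prod_mir9 = deg_mir9 * mir9_ss / hill_activation(myc_ss, k_myc_on_mir9, 4)
    prod_let7 = deg_let7 * let7_ss * (1.0 + myc_ss / k_myc_on_let7)
    prod_ecad = deg_ecad * ecad_ss * (1.0 + mir9_ss / k_mir9_on_ecad) / let7_ss
    prod_mmp = deg_mmp * mmp_ss * ecad_ss / k_ecad_on_mmp

    params = partial.with_values(
        prod_myc=prod_myc, prod_mir9=prod_mir9, prod_let7=prod_let7,
        prod_ecad=prod_ecad, prod_mmp=prod_mmp,
        steady_state_sos=sos_ss, steady_state_ras=ras_ss, steady_state_erk=erk_ss,
    )
    params.validate()
    return params
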