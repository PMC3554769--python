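"""Global sensitivity of the miR-9/let-7 ratio via Latin hypercube sampling
and partial rank correlation coefficients (PRCC).

Each estimated parameter is varied uniformly between ``low_factor`` and
``high_factor`` times its calibrated value (default 0.5×–2×).  For every
sample the model is simulated from the healthy initial state to ``t_eval``,
the miR-9/let-7 ratio is recorded, everything is rank-transformed, and the
PRCC of each parameter is the Pearson correlation of the residuals after
linearly regressing its ranks — and the output ranks — on all other
parameters' ranks.  Significance uses the t statistic
``r·sqrt((n - 2 - (k - 1)) / (1 - r^2))`` with ``n - 2 - (k - 1)`` degrees of
freedom (two-sided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model import ModelDomainError, ParameterSet
from .ode import DEFAULT_ATOL, DEFAULT_RTOL, simulate

__all__ = ["SensitivitySpec", "PRCCResult", "latin_hypercube", "rank_transform",
           "prcc", "prcc_significance", "run_sensitivity", "ESTIMATED_PARAMETERS"]

log = logging.getLogger(__name__)

#: The 14 parameters without a direct literature derivation ("estimated"):
#: the four estimated steady-state concentrations (used as initial values),
#: five control/saturation constants and five production rates.
ESTIMATED_PARAMETERS = (
    "steady_state_sos", "steady_state_ras", "steady_state_erk", "steady_state_mir9",
    "k_let7_on_ras", "k_myc_on_mir9", "k_myc_on_let7", "k_mir9_on_ecad",
    "k_ecad_on_mmp",
    "prod_myc", "prod_mir9", "prod_let7", "prod_ecad", "prod_mmp",
)


@dataclass(frozen=True)
class SensitivitySpec:
    parameters: tuple[str, ...] = ESTIMATED_PARAMETERS
    low_factor: float = 0.5
    high_factor: float = 2.0
    n_samples: int = 200
    t_eval: float = 2880.0
    output: str = "mir9_let7_ratio"
    alpha: float = 0.01
    seed: int = 0
    max_drop_fraction: float = 0.05

    def __post_init__(self):
        if not (0 < self.low_factor < 1 < self.high_factor):
            raise ModelDomainError("factors must satisfy 0 < low < 1 < high")
        if self.n_samples <= len(self.parameters) + 2:
            raise ModelDomainError("n_samples must exceed number of parameters + 2")
        if self.t_eval <= 0:
            raise ModelDomainError("t_eval must be positive")
        if not self.parameters:
            raise ModelDomainError("parameter list must be nonempty")


@dataclass(frozen=True)
class PRCCResult:
    """Table 3-style result: one row per parameter, sorted by |PRCC|."""

    table: pd.DataFrame                # parameter, low, high, prcc, t_stat, p_value, significant
    n_samples: int
    alpha: float
    rank_pairs: dict = field(default_factory=dict)  # parameter -> (param ranks, output ranks)

    def coefficient(self, parameter: str) -> float:
        row = self.table.loc[self.table["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row["prcc"].iloc[0])

    def significant(self, parameter: str) -> bool:
        row = self.table.loc[self.table["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return bool(row["significant"].iloc[0])


def latin_hypercube(n: int, k: int, seed: int | None = None) -> np.ndarray:
    """Stratified n×k sample of the unit hypercube.

    Each column places exactly one point, uniformly positioned, in each of the
    ``n`` equal strata.
    """
    if n < 1 or k < 1:
        raise ModelDomainError("n and k must be >= 1")
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    return sampler.random(n=n)


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n with ties receiving the average rank."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ModelDomainError("cannot rank an empty vector")
    return stats.rankdata(values, method="average")


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y regressed on X (with intercept), via least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("collinear design")
    return y - A @ coef


def prcc(sample_ranks: np.ndarray, output_ranks: np.ndarray) -> np.ndarray:
    """Partial rank correlation coefficient of each column with the output.

    Coefficient j is the Pearson correlation between the residuals of
    (a) column j's ranks and (b) the output ranks, after each is regressed on
    all remaining columns.
    """
    R = np.asarray(sample_ranks, dtype=float)
    y = np.asarray(output_ranks, dtype=float)
    n, k = R.shape
    if y.shape != (n,):
        raise ModelDomainError("output vector length must match the sample matrix")
    if n <= k + 2:
        raise ModelDomainError(f"need n > k + 2 samples (n={n}, k={k})")
    const = [j for j in range(k) if np.ptp(R[:, j]) == 0]
    if const:
        raise ModelDomainError(f"constant parameter columns {const} cannot be partialled")
    out = np.empty(k)
    for j in range(k):
        others = np.delete(R, j, axis=1)
        try:
            rx = _residuals(R[:, j], others)
            ry = _residuals(y, others)
        except np.linalg.LinAlgError as err:
            raise ModelDomainError(
                f"singular regression design when partialling column {j}: {err}") from err
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        out[j] = 0.0 if denom == 0 else float(rx @ ry / denom)
    return out


def prcc_significance(coefficient: float, n: int, k: int) -> tuple[float, float]:
    """t statistic and two-sided p-value for one PRCC.

    Degrees of freedom n − 2 − (k − 1): two lost to the correlation itself and
    k − 1 to the partialled-out parameters.
    """
    df = n - 2 - (k - 1)
    if df <= 0:
        raise ModelDomainError(f"degrees of freedom must be positive (n={n}, k={k})")
    if abs(coefficient) >= 1:
        raise ModelDomainError("|coefficient| must be < 1")
    t = coefficient * np.sqrt(df / (1.0 - coefficient ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def run_sensitivity(spec: SensitivitySpec, params: ParameterSet,
                    rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                    ) -> PRCCResult:
    """LHS + PRCC analysis of the miR-9/let-7 ratio at ``spec.t_eval``.

    Samples the hypercube, scales each column into
    [low_factor·θ, high_factor·θ], simulates every sample from its healthy
    initial state, computes the miR-9/let-7 ratio, and returns PRCCs with
    significance, sorted by |coefficient|.  Failing samples are dropped with a
    warning; more than ``max_drop_fraction`` drops is an error.
    """
    params.validate()
    names = list(spec.parameters)
    k = len(names)
    base = np.array([params.get(nm) for nm in names])
    unit = latin_hypercube(spec.n_samples, k, seed=spec.seed)
    lo, hi = spec.low_factor * base, spec.high_factor * base
    samples = lo + unit * (hi - lo)

    t_grid = np.array([0.0, spec.t_eval / 2, spec.t_eval])
    outputs, kept = [], []
    for i in range(spec.n_samples):
        p_i = params.with_values(**dict(zip(names, samples[i])))
        try:
            traj = simulate(p_i, p_i.steady_state, t_grid, rtol=rtol, atol=atol)
            ratio = traj.species("mir9")[-1] / traj.species("let7")[-1]
        except Exception as err:  # saturating kinetics can fail at corner samples
            log.warning("sensitivity sample %d dropped: %s", i, err)
            continue
        outputs.append(ratio)
        kept.append(i)
    n_kept = len(kept)
    if spec.n_samples - n_kept > spec.max_drop_fraction * spec.n_samples:
        raise RuntimeError(
            f"{spec.n_samples - n_kept} of {spec.n_samples} sensitivity samples failed")

    X = samples[kept]
    y = np.asarray(outputs)
    XR = np.column_stack([rank_transform(X[:, j]) for j in range(k)])
    yr = rank_transform(y)
    coefs = prcc(XR, yr)

    rows = []
    for j, nm in enumerate(names):
        t, p = prcc_significance(coefs[j], n_kept, k)
        rows.append({"parameter": nm, "low": lo[j], "high": hi[j],
                     "prcc": coefs[j], "t_stat": t, "p_value": p,
                     "significant": p < spec.alpha})
    table = (pd.DataFrame(rows)
             .sort_values("prcc", key=np.abs, ascending=False)
             .reset_index(drop=True))
    rank_pairs = {nm: (XR[:, j].copy(), yr.copy()) for j, nm in enumerate(names)}
    return PRCCResult(table=table, n_samples=n_kept, alpha=spec.alpha,
                      rank_pairs=rank_pairs)
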