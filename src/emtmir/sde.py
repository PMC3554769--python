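"""Stochastic robustness engine: additive Gaussian (Brownian-increment) input
on the miR-9 or let-7 equation, integrated with a fixed-step Euler scheme.

The perturbed species follows

    x_{t+dt} = x_t + f(x_t)·dt + σ·√dt·Z,   Z ~ N(0, 1) i.i.d.,

while the other seven species take deterministic Euler steps.  States are
clipped at zero after every step (concentrations are nonnegative; clip events
are counted and reported).  Realization ``i`` of an ensemble draws from a
counter-based stream derived from the master seed, so ensembles are
reproducible and order-independent, and a single path with the same derived
seed is bitwise identical to the corresponding ensemble member.

The random input stands in for unmodeled regulation of the two microRNAs
("background" genes), not for molecular shot noise — hence the additive form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import SPECIES, ModelDomainError, ParameterSet, rhs_array
from .ode import ScenarioSpec, TrajectoryTable

__all__ = ["NoiseSpec", "EnsembleSummary", "euler_maruyama_path",
           "ensemble_stats", "robustness_compare", "EulerStabilityError"]

_CHUNK = 4096  # noise increments are generated per-realization in blocks


class EulerStabilityError(RuntimeError):
    """The deterministic part of an Euler step moved a species by > 50%."""


@dataclass(frozen=True)
class NoiseSpec:
    """Configuration of one stochastic run."""

    target_species: str              # "mir9" or "let7"
    sigma: float                     # noise amplitude, nM/sqrt(min)
    dt: float = 0.05                 # fixed step, min
    horizon: float = 2880.0          # total time, min
    n_realizations: int = 1
    seed: int = 0
    scenario: Optional[ScenarioSpec] = None   # applied before integrating
    strict: bool = False             # escalate stability warnings to errors

    def __post_init__(self):
        if self.target_species not in ("mir9", "let7"):
            raise ModelDomainError("noise target must be 'mir9' or 'let7'")
        if self.sigma < 0:
            raise ModelDomainError("sigma must be >= 0")
        if self.dt <= 0:
            raise ModelDomainError("dt must be positive")
        n_steps = self.horizon / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
            raise ModelDomainError("horizon must be an integer multiple of dt")
        if self.n_realizations < 1:
            raise ModelDomainError("n_realizations must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise ensemble mean/SD plus the noise-free reference trajectory."""

    times: np.ndarray
    mean: np.ndarray          # (n_times, 8)
    sd: np.ndarray            # (n_times, 8)
    reference: np.ndarray     # (n_times, 8), sigma = 0
    n_realizations: int
    clip_fraction: float
    metadata: dict = field(default_factory=dict)

    def species_index(self, name: str) -> int:
        return SPECIES.index(name)


def _realization_rng(master_seed: int, index: int) -> np.random.Generator:
    """Counter-based per-realization stream: Philox keyed off the master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return np.random.Generator(np.random.Philox(ss))


def _apply_scenario(params: ParameterSet, spec: NoiseSpec) -> ParameterSet:
    if spec.scenario is None:
        return params
    if spec.scenario.is_scan():
        raise ModelDomainError("a noise run takes a scalar scenario, not a scan")
    return spec.scenario.apply(params, float(np.atleast_1d(spec.scenario.value)[0]))

def _euler_ensemble(params: ParameterSet, spec: NoiseSpec,
                    save_every: int, realization_offset: int = 0,
                    increments: np.ndarray | None = None):
    """Vectorized fixed-step integration of all realizations at once.

    Returns (times, paths, clip_events, total_steps) where paths has shape
    (n_saved, n_realizations, 8).
    """
    p = _apply_scenario(params, spec)
    p.validate()
    n, n_steps = spec.n_realizations, spec.n_steps
    tgt = SPECIES.index(spec.target_species)
    x = np.tile(p.steady_state.as_array(), (n, 1))
    n_saved = n_steps // save_every + 2  # slot for t=0 and a possibly off-grid final step
    out = np.empty((n_saved, n, 8))
    out[0] = x
    times = np.empty(n_saved)
    times[0] = 0.0
    if increments is not None:
        increments = np.asarray(increments, dtype=float)
        if increments.shape != (n, n_steps):
            raise ModelDomainError(
                f"increments must have shape ({n}, {n_steps}), got {increments.shape}")
    rngs = [_realization_rng(spec.seed, realization_offset + i) for i in range(n)]
    clip_events = 0
    stability_hits = 0
    noise = np.empty((n, _CHUNK))
    sqrt_dt = np.sqrt(spec.dt)
    save_idx = 1
    for start in range(0, n_steps, _CHUNK):
        m = min(_CHUNK, n_steps - start)
        # `noise` holds the additive term σ·√dt·Z for each step
        if increments is not None:
            noise[:, :m] = increments[:, start:start + m]
        elif spec.sigma > 0:
            for i, rng in enumerate(rngs):
                noise[i, :m] = spec.sigma * sqrt_dt * rng.standard_normal(m)
        else:
            noise[:, :m] = 0.0
        for k in range(m):
            step = rhs_array(x, p) * spec.dt
            big = np.abs(step) > 0.5 * (np.abs(x) + 1e-12)
            if big.any():
                stability_hits += int(big.sum())
                if spec.strict:
                    raise EulerStabilityError(
                        f"dt={spec.dt} too large: a deterministic Euler step moved a "
                        f"species by more than 50% at t={(start + k) * spec.dt:.4g} min")
            x = x + step
            if spec.sigma > 0 or increments is not None:
                x[:, tgt] += noise[:, k]
            neg = x < 0
            if neg.any():
                clip_events += int(neg.sum())
                np.clip(x, 0.0, None, out=x)
            global_step = start + k + 1
            if global_step % save_every == 0 or global_step == n_steps:
                out[save_idx] = x
                times[save_idx] = global_step * spec.dt
                save_idx += 1
    return times[:save_idx], out[:save_idx], clip_events, n_steps * n, stability_hits


def euler_maruyama_path(params: ParameterSet, spec: NoiseSpec,
                        save_every: int = 1, realization_index: int = 0,
                        increments: np.ndarray | None = None) -> TrajectoryTable:
    """One sample path (uses realization ``realization_index`` of the seed).

    ``increments`` optionally supplies the Brownian increments σ·√dt·Z for
    every step explicitly (shape ``(n_steps,)``), e.g. to integrate the same
    Brownian path at several step sizes.
    """
    one = replace(spec, n_realizations=1)
    if increments is not None:
        increments = np.asarray(increments, dtype=float).reshape(1, -1)
    times, paths, clips, steps, hits = _euler_ensemble(
        params, one, save_every, realization_offset=realization_index,
        increments=increments)
    return TrajectoryTable(times=times, states=paths[:, 0, :], metadata={
        "sigma": spec.sigma, "dt": spec.dt, "seed": spec.seed,
        "target_species": spec.target_species, "clip_events": clips,
        "clip_fraction": clips / max(steps * 8, 1),
        "stability_hits": hits,
    })


def ensemble_stats(params: ParameterSet, spec: NoiseSpec,
                   save_every: int = 20) -> EnsembleSummary:
    """Pointwise mean and SD over realizations plus the σ=0 reference."""
    if spec.n_realizations < 2:
        raise ModelDomainError("ensemble statistics need n_realizations >= 2")
    times, paths, clips, steps, _ = _euler_ensemble(params, spec, save_every)
    ref_times, ref_paths, *_ = _euler_ensemble(
        params, replace(spec, sigma=0.0, n_realizations=1), save_every)
    return EnsembleSummary(
        times=times,
        mean=paths.mean(axis=1),
        sd=paths.std(axis=1, ddof=1),
        reference=ref_paths[:, 0, :],
        n_realizations=spec.n_realizations,
        clip_fraction=clips / max(steps * 8, 1),
        metadata={"sigma": spec.sigma, "dt": spec.dt, "seed": spec.seed,
                  "target_species": spec.target_species},
    )


def robustness_compare(params: ParameterSet, sigma: float, dt: float = 0.05,
                       horizon: float = 2880.0, n_realizations: int = 200,
                       seed: int = 0, scenario: ScenarioSpec | None = None,
                       save_every: int = 20) -> dict:
    """MMP variability under miR-9 noise vs under let-7 noise.

    Both arms share dt, horizon, ensemble size and master seed.  Returns the
    time-resolved MMP SD of each arm and a verdict naming the arm with the
    smaller terminal MMP SD ("tie" at σ=0).
    """
    arms = {}
    for target in ("mir9", "let7"):
        spec = NoiseSpec(target_species=target, sigma=sigma, dt=dt,
                         horizon=horizon, n_realizations=n_realizations,
                         seed=seed, scenario=scenario)
        arms[target] = ensemble_stats(params, spec, save_every=save_every)
    j = SPECIES.index("mmp")
    sd_mir9 = arms["mir9"].sd[:, j]
    sd_let7 = arms["let7"].sd[:, j]
    if sigma == 0 or sd_mir9[-1] == sd_let7[-1]:
        verdict = "tie"
    else:
        verdict = "let7" if sd_let7[-1] < sd_mir9[-1] else "mir9"
    return {
        "times": arms["mir9"].times,
        "mmp_sd_mir9_arm": sd_mir9,
        "mmp_sd_let7_arm": sd_let7,
        "terminal_sd_mir9_arm": float(sd_mir9[-1]),
        "terminal_sd_let7_arm": float(sd_let7[-1]),
        "verdict": verdict,
        "summaries": arms,
    }
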