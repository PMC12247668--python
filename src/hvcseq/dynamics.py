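"""Five-population stochastic rate dynamics.

The state holds the firing rates of the two excitatory chains (HVC_RA,
HVC_X), the local inhibitory chain, the scalar global inhibitory unit and
the scalar peri-song unit. One explicit Euler step (Euler-Maruyama when the
Poisson-like rate noise is on) integrates::

    tau_E dr_RA = -r_RA + W_X_RA f_E(r_X) - W_I_RA f_I(r_I)
                  - w_g_RA f_g(r_g) + W_ps_RA f_ps(r_ps) + I_ext1 (+pulse +noise)
    tau_E dr_X  = -r_X + W_RA_X f_E(r_RA) - W_I_X f_I(r_I)
                  - w_g_X f_g(r_g) + I_ext2 (+pulse)
    tau_g dr_g  = -r_g + sum W_RA_g f_E(r_RA) + sum W_X_g f_E(r_X)
    tau_I dr_I  = -r_I + W_RA_I f_E(r_RA) + W_X_I f_E(r_X)
    tau_ps dr_ps = -r_ps + I_Uva - w_g_ps f_g(r_g)

Inhibitory-source terms carry an explicit minus sign; stored weights are
magnitudes. Rates are clamped at zero after every step. The noise term is
``sqrt(F * r_RA(j)) * xi(t)`` per unit, independent across units, entering
the Euler-Maruyama update with the usual ``sqrt(dt)`` scaling.

The tonic Uva drive gates the behavioural state: with it on, silence of
the network lowers global inhibition, the peri-song unit charges up, and a
fresh bump is seeded at the chain start — the model's account of song
initiation and of restart after truncation or natural completion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .connectivity import ConnectivitySet
from .params import ActivationSpec, ConfigurationError, NetworkParameters

__all__ = [
    "NetworkState",
    "PulseEvent",
    "InputProtocol",
    "SimulationTrace",
    "IntegrationBlowupError",
    "activation",
    "step",
    "simulate",
]


class IntegrationBlowupError(RuntimeError):
    """A rate became non-finite during integration."""

    def __init__(self, t: float, population: str):
        super().__init__(
            f"non-finite rate in population {population!r} at t = {t:.3f} ms; "
            "reduce dt or weights"
        )
        self.t = t
        self.population = population


def activation(value, spec: ActivationSpec):
    """Static nonlinearity f(value): non-negative, non-decreasing."""
    x = np.maximum(np.asarray(value, dtype=float) - spec.threshold, 0.0)
    if spec.family == "threshold_linear":
        return spec.gain * x
    if spec.family == "threshold_quadratic":
        return spec.gain * x**2
    raise ConfigurationError(f"unknown activation family {spec.family!r}")


@dataclass
class NetworkState:
    """Instantaneous rates of all five populations at time ``t`` (ms)."""

    r_RA: np.ndarray
    r_X: np.ndarray
    r_I: np.ndarray
    r_g: float
    r_ps: float
    t: float = 0.0

    @classmethod
    def zeros(cls, N: int) -> "NetworkState":
        return cls(np.zeros(N), np.zeros(N), np.zeros(N), 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PulseEvent:
    """A spatially homogeneous square pulse onto one excitatory chain."""

    target: str  # "RA" or "X"
    onset: float  # ms
    duration: float  # ms
    amplitude: float

    def __post_init__(self) -> None:
        if self.target not in ("RA", "X"):
            raise ConfigurationError(
                f"pulse target must be 'RA' or 'X', got {self.target!r}"
            )
        if self.duration <= 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration}")


@dataclass
class InputProtocol:
    """Realized external input schedule.

    ``uva_drive`` is a piecewise-constant schedule of (onset ms, value)
    pairs; the value holding at time t is the last one whose onset is
    <= t (before the first onset the drive is 0). ``pulse_events`` are the
    simulated optogenetic perturbations. ``noise_targets`` selects which
    excitatory chains receive the Poisson-like rate noise.
    """

    uva_drive: Sequence[tuple[float, float]] = ((0.0, 1.0),)
    pulse_events: Sequence[PulseEvent] = ()
    I_ext_1: float = 0.0
    I_ext_2: float = 0.0
    noise_enabled: bool = False
    noise_targets: tuple[str, ...] = ("RA",)

    def __post_init__(self) -> None:
        self.uva_drive = tuple((float(t), float(v)) for t, v in self.uva_drive)
        if any(
            self.uva_drive[k][0] > self.uva_drive[k + 1][0]
            for k in range(len(self.uva_drive) - 1)
        ):
            raise ValueError("uva_drive onsets must be non-decreasing")
        for tgt in self.noise_targets:
            if tgt not in ("RA", "X"):
                raise ConfigurationError(f"noise target must be 'RA' or 'X': {tgt!r}")

    def uva_at(self, t: float) -> float:
        value = 0.0
        for onset, v in self.uva_drive:
            if onset <= t:
                value = v
            else:
                break
        return value

    def pulse_at(self, t: float) -> tuple[float, float]:
        """(amplitude onto RA, amplitude onto X) holding at time t."""
        a_ra = a_x = 0.0
        for ev in self.pulse_events:
            if ev.onset <= t < ev.onset + ev.duration:
                if ev.target == "RA":
                    a_ra += ev.amplitude
                else:
                    a_x += ev.amplitude
        return a_ra, a_x


@dataclass
class SimulationTrace:
    """Time-indexed record of a run (uniform grid, spacing dt)."""

    times: np.ndarray  # (T,)
    r_RA: np.ndarray  # (T, N)
    r_X: np.ndarray  # (T, N)
    r_I: np.ndarray  # (T, N)
    r_g: np.ndarray  # (T,)
    r_ps: np.ndarray  # (T,)
    pulse_applied: np.ndarray  # (T, 2) realized pulse amplitude (RA, X)
    uva_applied: np.ndarray  # (T,)
    params_digest: str = ""
    seed: int = 0

    @property
    def N(self) -> int:
        return self.r_RA.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def total_excitatory(self) -> np.ndarray:
        """Summed excitatory activity per step (bump amplitude readout)."""
        return self.r_RA.sum(axis=1) + self.r_X.sum(axis=1)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("times", "r_RA", "r_X", "r_I", "r_g", "r_ps",
                         "pulse_applied", "uva_applied"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["params_digest"] = self.params_digest
            f.attrs["seed"] = self.seed

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationTrace":
        with h5py.File(path, "r") as f:
            return cls(
                **{
                    name: f[name][...]
                    for name in (
                        "times", "r_RA", "r_X", "r_I", "r_g", "r_ps",
                        "pulse_applied", "uva_applied",
                    )
                },
                params_digest=str(f.attrs["params_digest"]),
                seed=int(f.attrs["seed"]),
            )


# ----------------------------------------------------------------------
def _step_arrays(
    r_RA: np.ndarray,
    r_X: np.ndarray,
    r_I: np.ndarray,
    r_g: float,
    r_ps: float,
    t: float,
    conn: ConnectivitySet,
    params: NetworkParameters,
    protocol: InputProtocol,
    rng: np.random.Generator | None,
):
    """One explicit (Euler / Euler-Maruyama) step; returns the new arrays."""
    spec = params.activation_specs
    fE_RA = activation(r_RA, spec["E"])
    fE_X = activation(r_X, spec["E"])
    fI = activation(r_I, spec["I"])
    fg = float(activation(r_g, spec["g"]))
    fps = float(activation(r_ps, spec["ps"]))

    pulse_RA, pulse_X = protocol.pulse_at(t)
    uva = protocol.uva_at(t)

    drift_RA = (
        -r_RA
        + conn.W_X_RA @ fE_X
        - conn.W_I_RA @ fI
        - conn.w_g_RA * fg
        + conn.W_ps_RA * fps
        + params.I_ext_1
        + protocol.I_ext_1
        + pulse_RA
    )
    drift_X = (
        -r_X
        + conn.W_RA_X @ fE_RA
        - conn.W_I_X @ fI
        - conn.w_g_X * fg
        + params.I_ext_2
        + protocol.I_ext_2
        + pulse_X
    )
    drift_I = -r_I + conn.W_RA_I @ fE_RA + conn.W_X_I @ fE_X
    drift_g = -r_g + float(conn.W_RA_g @ fE_RA) + float(conn.W_X_g @ fE_X)
    drift_ps = -r_ps + uva - conn.w_g_ps * fg

    dt = params.dt
    new_RA = r_RA + (dt / params.tau_E) * drift_RA
    new_X = r_X + (dt / params.tau_E) * drift_X
    new_I = r_I + (dt / params.tau_I) * drift_I
    new_g = r_g + (dt / params.tau_g) * drift_g
    new_ps = r_ps + (dt / params.tau_ps) * drift_ps

    if protocol.noise_enabled and params.noise_fano > 0.0:
        if rng is None:
            raise ValueError("noise enabled but no rng supplied")
        sq = math.sqrt(dt) / params.tau_E
        if "RA" in protocol.noise_targets:
            amp = np.sqrt(params.noise_fano * np.maximum(r_RA, 0.0))
            new_RA = new_RA + sq * amp * rng.standard_normal(r_RA.shape)
        if "X" in protocol.noise_targets:
            amp = np.sqrt(params.noise_fano * np.maximum(r_X, 0.0))
            new_X = new_X + sq * amp * rng.standard_normal(r_X.shape)

    # rates are non-negative by construction
    np.maximum(new_RA, 0.0, out=new_RA)
    np.maximum(new_X, 0.0, out=new_X)
    np.maximum(new_I, 0.0, out=new_I)
    new_g = max(new_g, 0.0)
    new_ps = max(new_ps, 0.0)
    return new_RA, new_X, new_I, new_g, new_ps, (pulse_RA, pulse_X), uva


def step(
    state: NetworkState,
    conn: ConnectivitySet,
    params: NetworkParameters,
    protocol: InputProtocol,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the network by one integration step of length ``dt``."""
    if state.r_RA.shape[0] != conn.N:
        raise ValueError(
            f"state dimension {state.r_RA.shape[0]} does not match connectivity N={conn.N}"
        )
    r_RA, r_X, r_I, r_g, r_ps, _, _ = _step_arrays(
        state.r_RA, state.r_X, state.r_I, state.r_g, state.r_ps, state.t,
        conn, params, protocol, rng,
    )
    new = NetworkState(r_RA, r_X, r_I, r_g, r_ps, state.t + params.dt)
    _check_finite(new)
    return new


def _check_finite(state: NetworkState) -> None:
    for name in ("r_RA", "r_X", "r_I"):
        if not np.all(np.isfinite(getattr(state, name))):
            raise IntegrationBlowupError(state.t, name)
    if not math.isfinite(state.r_g):
        raise IntegrationBlowupError(state.t, "r_g")
    if not math.isfinite(state.r_ps):
        raise IntegrationBlowupError(state.t, "r_ps")


def simulate(
    params: NetworkParameters,
    conn: ConnectivitySet,
    protocol: InputProtocol,
    duration: float,
    seed: int = 0,
    initial_state: NetworkState | None = None,
) -> SimulationTrace:
    """Integrate the network for ``duration`` ms from rest.

    The default initial condition is all-zero rates: with the Uva drive on,
    initiation emerges on its own through the peri-song unit. Deterministic
    given (params, protocol, seed).
    """
    if duration < params.dt:
        raise ValueError(f"duration {duration} ms shorter than one step dt={params.dt}")
    n_steps = int(math.ceil(duration / params.dt))
    N = conn.N
    state = initial_state or NetworkState.zeros(N)
    rng = np.random.default_rng(seed)

    times = np.empty(n_steps)
    out_RA = np.empty((n_steps, N))
    out_X = np.empty((n_steps, N))
    out_I = np.empty((n_steps, N))
    out_g = np.empty(n_steps)
    out_ps = np.empty(n_steps)
    pulses = np.empty((n_steps, 2))
    uvas = np.empty(n_steps)

    r_RA, r_X, r_I = state.r_RA.copy(), state.r_X.copy(), state.r_I.copy()
    r_g, r_ps, t = float(state.r_g), float(state.r_ps), float(state.t)
    check_every = max(1, int(round(5.0 / params.dt)))  # finiteness audit cadence
    for k in range(n_steps):
        r_RA, r_X, r_I, r_g, r_ps, pulse, uva = _step_arrays(
            r_RA, r_X, r_I, r_g, r_ps, t, conn, params, protocol, rng
        )
        t += params.dt
        times[k] = t
        out_RA[k] = r_RA
        out_X[k] = r_X
        out_I[k] = r_I
        out_g[k] = r_g
        out_ps[k] = r_ps
        pulses[k] = pulse
        uvas[k] = uva
        if k % check_every == 0 and not (
            math.isfinite(r_g) and math.isfinite(r_RA.sum())
        ):
            raise IntegrationBlowupError(t, f"step {k}")

    trace = SimulationTrace(
        times, out_RA, out_X, out_I, out_g, out_ps, pulses, uvas,
        params_digest=params.digest(), seed=seed,
    )
    if not (np.all(np.isfinite(out_g)) and np.all(np.isfinite(out_RA[-1]))):
        raise IntegrationBlowupError(times[-1], "trace")
    return trace


def export_trace_csv(trace: SimulationTrace, path: str | Path, stride: int = 10) -> None:
    """Down-sampled per-step CSV export of population summaries."""
    import pandas as pd

    sl = slice(None, None, max(1, stride))
    df = pd.DataFrame(
        {
            "time_ms": trace.times[sl],
            "total_RA": trace.r_RA[sl].sum(axis=1),
            "total_X": trace.r_X[sl].sum(axis=1),
            "total_I": trace.r_I[sl].sum(axis=1),
            "r_g": trace.r_g[sl],
            "r_ps": trace.r_ps[sl],
            "pulse_RA": trace.pulse_applied[sl, 0],
            "pulse_X": trace.pulse_applied[sl, 1],
            "uva": trace.uva_applied[sl],
        }
    )
    df.to_csv(path, index=False)
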