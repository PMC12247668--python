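"""Synaptic weight construction.

All structured weights are translation-invariant Gaussian kernels of the
chain distance ``(i - j)`` measured in radians via the ``2*pi/N`` scaling::

    W_{A,B}(i, j) = w_{A,B} * exp(-(2*pi/N)**2 * (i - j)**2 / (2 * sigma**2))

The chain is linear, not a ring: there is no wraparound in ``(i - j)``.
Two position-dependent boundary factors break the symmetry of the chain:
local inhibition onto the excitatory chains is enhanced near the start
(which gives the activity bump its direction of travel), and the mutual
excitation between the two excitatory chains fades just past the last
position (which extinguishes the bump instead of letting it bounce).
A one-shot stochastic degradation transform models tetanus-toxin blockade
of HVC_X output synapses.

Weight magnitudes are stored non-negative; the dynamics module applies the
inhibitory sign to local-inhibitory and global-inhibitory source terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

from .params import (
    KERNEL_PAIRS,
    ConfigurationError,
    NetworkParameters,
    ParameterError,
)

__all__ = [
    "ConnectivitySet",
    "build_kernel_matrix",
    "build_perisong_column",
    "build_connectivity",
    "apply_boundary_compensation",
    "degrade_hvcx_output",
]


@dataclass
class ConnectivitySet:
    """Dense weight structures between the five populations.

    The N x N matrices are indexed ``[postsynaptic, presynaptic]`` so that
    matrix-vector products implement the summed synaptic drive.
    """

    W_X_RA: np.ndarray
    W_RA_X: np.ndarray
    W_I_RA: np.ndarray
    W_I_X: np.ndarray
    W_RA_I: np.ndarray
    W_X_I: np.ndarray
    W_ps_RA: np.ndarray  # (N,) column: peri-song -> chain start
    w_g_RA: float
    w_g_X: float
    w_g_ps: float
    W_RA_g: np.ndarray  # (N,) summation row
    W_X_g: np.ndarray  # (N,) summation row
    compensated: bool = False
    degraded: bool = False
    degradation_seed: int | None = None

    @property
    def N(self) -> int:
        return self.W_X_RA.shape[0]

    def kernel_matrices(self) -> Iterator[tuple[str, np.ndarray]]:
        yield "W_X_RA", self.W_X_RA
        yield "W_RA_X", self.W_RA_X
        yield "W_I_RA", self.W_I_RA
        yield "W_I_X", self.W_I_X
        yield "W_RA_I", self.W_RA_I
        yield "W_X_I", self.W_X_I

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write all matrices plus provenance flags to an HDF5 container."""
        with h5py.File(path, "w") as f:
            for name, mat in self.kernel_matrices():
                f.create_dataset(name, data=mat)
            f.create_dataset("W_ps_RA", data=self.W_ps_RA)
            f.create_dataset("W_RA_g", data=self.W_RA_g)
            f.create_dataset("W_X_g", data=self.W_X_g)
            f.attrs["w_g_RA"] = self.w_g_RA
            f.attrs["w_g_X"] = self.w_g_X
            f.attrs["w_g_ps"] = self.w_g_ps
            f.attrs["compensated"] = self.compensated
            f.attrs["degraded"] = self.degraded
            f.attrs["degradation_seed"] = (
                -1 if self.degradation_seed is None else self.degradation_seed
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ConnectivitySet":
        with h5py.File(path, "r") as f:
            seed = int(f.attrs["degradation_seed"])
            return cls(
                W_X_RA=f["W_X_RA"][...],
                W_RA_X=f["W_RA_X"][...],
                W_I_RA=f["W_I_RA"][...],
                W_I_X=f["W_I_X"][...],
                W_RA_I=f["W_RA_I"][...],
                W_X_I=f["W_X_I"][...],
                W_ps_RA=f["W_ps_RA"][...],
                W_RA_g=f["W_RA_g"][...],
                W_X_g=f["W_X_g"][...],
                w_g_RA=float(f.attrs["w_g_RA"]),
                w_g_X=float(f.attrs["w_g_X"]),
                w_g_ps=float(f.attrs["w_g_ps"]),
                compensated=bool(f.attrs["compensated"]),
                degraded=bool(f.attrs["degraded"]),
                degradation_seed=None if seed < 0 else seed,
            )


# ----------------------------------------------------------------------
def _distance_kernel(N: int, sigma: float) -> np.ndarray:
    idx = np.arange(N, dtype=float)
    d = idx[:, None] - idx[None, :]
    return np.exp(-((2.0 * np.pi / N) ** 2) * d**2 / (2.0 * sigma**2))


def build_kernel_matrix(params: NetworkParameters, pair: tuple[str, str]) -> np.ndarray:
    """Dense N x N Gaussian distance kernel for one structured pair.

    Entry (i, j) = w_{A,B} * exp(-(2*pi/N)^2 (i-j)^2 / (2 sigma^2)); the
    peak weight sits on the diagonal.
    """
    if tuple(pair) not in KERNEL_PAIRS:
        raise ConfigurationError(
            f"pair {pair!r} has no chain-indexed kernel; structured pairs are "
            f"{KERNEL_PAIRS}"
        )
    w = params.peak_weight(*pair)
    return w * _distance_kernel(params.N, params.sigma)


def build_perisong_column(params: NetworkParameters) -> np.ndarray:
    """Peri-song targeting column, Gaussian centred on chain position 0.

    Entry k = w_{ps,RA} * exp(-(2*pi/N)^2 k^2 / (2 sigma^2)), so the
    peri-song unit drives the start of the HVC_RA chain and its influence
    decays monotonically along the chain.
    """
    k = np.arange(params.N, dtype=float)
    w = params.peak_weight("ps", "RA")
    return w * np.exp(-((2.0 * np.pi / params.N) ** 2) * k**2 / (2.0 * params.sigma**2))


def build_connectivity(params: NetworkParameters) -> ConnectivitySet:
    """Assemble the raw (uncompensated, undegraded) connectivity."""
    N = params.N
    return ConnectivitySet(
        W_X_RA=build_kernel_matrix(params, ("X", "RA")),
        W_RA_X=build_kernel_matrix(params, ("RA", "X")),
        W_I_RA=build_kernel_matrix(params, ("I", "RA")),
        W_I_X=build_kernel_matrix(params, ("I", "X")),
        W_RA_I=build_kernel_matrix(params, ("RA", "I")),
        W_X_I=build_kernel_matrix(params, ("X", "I")),
        W_ps_RA=build_perisong_column(params),
        w_g_RA=params.peak_weight("g", "RA"),
        w_g_X=params.peak_weight("g", "X"),
        w_g_ps=params.peak_weight("g", "ps"),
        W_RA_g=np.full(N, params.peak_weight("RA", "g")),
        W_X_g=np.full(N, params.peak_weight("X", "g")),
    )


# ----------------------------------------------------------------------
def boundary_factors(
    params: NetworkParameters, index_axis: str = "post"
) -> tuple[np.ndarray, np.ndarray]:
    """Position-dependent boundary factors (start-enhancement, end-fade).

    Returns (g0, g1) of length N: g0(i) = 1 + c0*exp(-(2pi/N)^2 i^2/(4 sigma^2))
    multiplies local-inhibitory input near the chain start; g1(i) =
    1 - c1*exp(-(2pi/N)^2 (i-N-phi)^2/(4 sigma^2)) fades the mutual
    excitation approaching a point phi positions beyond the last index.
    """
    if index_axis not in ("post", "pre"):
        raise ConfigurationError("index_axis must be 'post' or 'pre'")
    N = params.N
    i = np.arange(N, dtype=float)
    scale = (2.0 * np.pi / N) ** 2 / (4.0 * params.sigma**2)
    g0 = 1.0 + params.c0 * np.exp(-scale * i**2)
    g1 = 1.0 - params.c1 * np.exp(-scale * (i - N - params.phi) ** 2)
    return g0, g1


def apply_boundary_compensation(
    conn: ConnectivitySet, params: NetworkParameters, index_axis: str = "post"
) -> ConnectivitySet:
    """Apply the start-enhancement and end-fade factors to the kernels.

    The compensation index runs over the postsynaptic (row) position by
    default: inhibition is enhanced where early-chain excitatory neurons
    *receive* it, and excitation fades where late-chain neurons receive it.
    ``index_axis='pre'`` instead scales by the presynaptic (column) index.
    Not idempotent: a second application raises.
    """
    if conn.compensated:
        raise ValueError(
            "connectivity already boundary-compensated; compensation is not idempotent"
        )
    g0, g1 = boundary_factors(params, index_axis)
    if index_axis == "post":
        sh0, sh1 = g0[:, None], g1[:, None]  # scale rows
    else:
        sh0, sh1 = g0[None, :], g1[None, :]  # scale columns
    return replace(
        conn,
        W_I_RA=conn.W_I_RA * sh0,
        W_I_X=conn.W_I_X * sh0,
        W_X_RA=conn.W_X_RA * sh1,
        W_RA_X=conn.W_RA_X * sh1,
        compensated=True,
    )


def degrade_hvcx_output(
    conn: ConnectivitySet, p: float, sigma_W: float, seed: int
) -> ConnectivitySet:
    """Stochastically degrade the HVC_X -> HVC_RA projection.

    Each entry W is replaced by ``[(1-p) W + (1-p) W sigma_W xi]+`` with
    independent standard-normal ``xi`` — a mean reduction by the degraded
    proportion ``p`` plus multiplicative weight scatter, rectified at zero
    so weights stay excitatory. Deterministic given ``seed``; only the
    X -> RA matrix is touched.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"degradation proportion p must lie in [0, 1], got {p}")
    if sigma_W < 0:
        raise ParameterError(f"sigma_W must be >= 0, got {sigma_W}")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(conn.W_X_RA.shape)
    W = conn.W_X_RA
    degraded = np.maximum((1.0 - p) * W + (1.0 - p) * W * sigma_W * xi, 0.0)
    return replace(conn, W_X_RA=degraded, degraded=True, degradation_seed=seed)
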