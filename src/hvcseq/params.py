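"""Model parameters and configuration I/O.

The network is a five-population rate model of the songbird premotor
nucleus HVC: two excitatory projection-neuron chains (HVC_RA and HVC_X,
``N`` units each), a chain of local inhibitory units, one fast global
inhibitory unit, and one peri-song unit that seeds the start of the chain.
:class:`NetworkParameters` collects every symbol of the circuit equations
plus integration settings, validates them, and round-trips through
YAML/JSON config files with a versioned schema.

Chain distances are measured in radians through the ``2*pi/N`` scaling, so
a kernel width ``sigma`` corresponds to ``sigma*N/(2*pi)`` chain positions
regardless of ``N``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

CONFIG_SCHEMA_VERSION = 1

#: Ordered (source, target) pairs with structured (chain-indexed) kernels.
KERNEL_PAIRS = (
    ("X", "RA"),
    ("RA", "X"),
    ("I", "RA"),
    ("I", "X"),
    ("RA", "I"),
    ("X", "I"),
)

#: Scalar weights: global-inhibitory output and input, peri-song gating.
SCALAR_PAIRS = (
    ("g", "RA"),
    ("g", "X"),
    ("g", "ps"),
    ("RA", "g"),
    ("X", "g"),
)

#: Peri-song targeting column onto the start of the HVC_RA chain.
COLUMN_PAIRS = (("ps", "RA"),)

ALL_PAIRS = KERNEL_PAIRS + SCALAR_PAIRS + COLUMN_PAIRS

#: Populations whose output is sign-inverted by the dynamics (weights are
#: stored as non-negative magnitudes).
INHIBITORY_SOURCES = frozenset({"I", "g"})


class ParameterError(ValueError):
    """A parameter value violates its documented constraint."""


class ConfigurationError(ValueError):
    """A configuration file or lookup key is malformed or unknown."""


@dataclass(frozen=True)
class ActivationSpec:
    """Static nonlinearity of one population.

    family:
        ``"threshold_linear"`` -> ``gain * max(x - threshold, 0)``;
        ``"threshold_quadratic"`` -> ``gain * max(x - threshold, 0)**2``.
        The global inhibitory unit uses the quadratic family so that its
        response to synchronous excitation is much steeper than the
        excitatory response, which is what lets a homogeneous pulse flip
        the network into net suppression.
    """

    family: str = "threshold_linear"
    gain: float = 1.0
    threshold: float = 0.0

    def validate(self) -> None:
        if self.family not in ("threshold_linear", "threshold_quadratic"):
            raise ConfigurationError(
                f"unknown activation family {self.family!r}; expected "
                "'threshold_linear' or 'threshold_quadratic'"
            )
        if self.gain <= 0:
            raise ParameterError(f"activation gain must be > 0, got {self.gain}")


def _default_peak_weights() -> dict[str, float]:
    # Magnitudes only; inhibitory sign is applied in the dynamics.
    # Chosen so that the mutual RA<->X loop self-sustains a single bump,
    # the lagging local-inhibitory bump pushes it forward at ~0.15
    # positions/ms (one traversal in ~650 ms), and the global unit keeps
    # the peri-song unit silent during the traversal.
    return {
        "X->RA": 1.2,
        "RA->X": 1.2,
        "I->RA": 0.6,
        "I->X": 0.6,
        "RA->I": 0.15,
        "X->I": 0.15,
        "ps->RA": 0.3,
        "g->RA": 1.2,
        "g->X": 1.2,
        "g->ps": 120.0,
        "RA->g": 0.15,
        "X->g": 0.15,
    }


def _default_activations() -> dict[str, ActivationSpec]:
    return {
        "E": ActivationSpec("threshold_linear", gain=1.0, threshold=0.02),
        "I": ActivationSpec("threshold_linear", gain=1.0, threshold=0.0),
        "g": ActivationSpec("threshold_quadratic", gain=1.0, threshold=0.0),
        "ps": ActivationSpec("threshold_linear", gain=1.0, threshold=0.5),
    }


@dataclass
class NetworkParameters:
    """Every parameter of the circuit model plus integration settings.

    Defaults are package defaults calibrated so that one unperturbed
    traversal of the chain lasts roughly 600-700 ms of simulated time (a
    zebra finch motif duration scale); they are not fitted to recordings.
    """

    N: int = 100
    sigma: float = 0.1
    peak_weights: dict[str, float] = field(default_factory=_default_peak_weights)
    c0: float = 2.0
    c1: float = 1.0
    tau_E: float = 2.0
    tau_I: float = 24.0
    tau_ps: float = 300.0
    tau_g: float = 0.1
    activation_specs: dict[str, ActivationSpec] = field(
        default_factory=_default_activations
    )
    I_Uva: float = 1.0
    I_ext_1: float = 0.0
    I_ext_2: float = 0.0
    noise_fano: float = 0.005
    degradation_p: float = 0.0
    degradation_sigma_W: float = 0.05
    dt: float = 0.1
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        if isinstance(self.activation_specs, Mapping):
            self.activation_specs = {
                k: (v if isinstance(v, ActivationSpec) else ActivationSpec(**v))
                for k, v in self.activation_specs.items()
            }
        self.validate()

    def validate(self) -> None:
        if self.N < 3:
            raise ParameterError(f"N must be >= 3, got {self.N}")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        for name in ("tau_E", "tau_I", "tau_ps", "tau_g"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.degradation_p <= 1.0:
            raise ParameterError(
                f"degradation_p must lie in [0, 1], got {self.degradation_p}"
            )
        if self.degradation_sigma_W < 0:
            raise ParameterError("degradation_sigma_W must be >= 0")
        if self.noise_fano < 0:
            raise ParameterError("noise_fano must be >= 0")
        expected = {f"{a}->{b}" for a, b in ALL_PAIRS}
        got = set(self.peak_weights)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ConfigurationError(
                f"peak_weights keys mismatch: missing {missing}, unknown {extra}"
            )
        for key, w in self.peak_weights.items():
            if w < 0:
                raise ParameterError(
                    f"peak weight {key} must be a non-negative magnitude, got {w}"
                )
        for pop in ("E", "I", "g", "ps"):
            if pop not in self.activation_specs:
                raise ConfigurationError(f"missing activation spec for {pop!r}")
            self.activation_specs[pop].validate()

    # ------------------------------------------------------------------
    @property
    def phi(self) -> float:
        """Boundary offset phi = 0.5 * sigma * N / (2*pi), chain positions."""
        import math

        return 0.5 * self.sigma * self.N / (2.0 * math.pi)

    @property
    def kernel_width_positions(self) -> float:
        """Gaussian kernel width expressed in chain positions."""
        import math

        return self.sigma * self.N / (2.0 * math.pi)

    def peak_weight(self, source: str, target: str) -> float:
        key = f"{source}->{target}"
        try:
            return self.peak_weights[key]
        except KeyError:
            raise ConfigurationError(f"unknown population pair {key!r}") from None

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["activation_specs"] = {
            k: dataclasses.asdict(v) for k, v in self.activation_specs.items()
        }
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NetworkParameters":
        d = dict(d)
        version = d.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema version {version}; "
                f"this package reads version {CONFIG_SCHEMA_VERSION}"
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        if not isinstance(payload, Mapping):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(payload)

    def digest(self) -> str:
        """Stable hash of the parameter set (provenance for traces)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **changes: Any) -> "NetworkParameters":
        d = self.to_dict()
        d.pop("schema_version")
        d.update(changes)
        return NetworkParameters.from_dict(d)
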