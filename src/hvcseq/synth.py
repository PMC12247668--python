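"""Synthetic behavioural data and canned model configurations.

Everything the analysis pipeline consumes can be generated here with known
ground truth: cohorts of stimulation trials (truncation outcomes, latencies,
post-truncation categories), bout-length series, retrograde cell-count
tables for the lesion-extrapolation estimator, and a set of named model
configurations exercising the main experimental protocols. Generators are
deterministic under a fixed seed and emit a manifest of every true
parameter so recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import apply_boundary_compensation, build_connectivity
from .dynamics import InputProtocol, PulseEvent, simulate
from .params import ConfigurationError, NetworkParameters

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_cellcounts",
    "canned_configs",
    "calibrate_pulse_amplitude",
    "DEFAULT_CONTROL_RATIOS",
    "TRIAL_COLUMNS",
    "BOUT_COLUMNS",
    "CELLCOUNT_COLUMNS",
]

#: CSV schemas shared with the behaviour-statistics module.
TRIAL_COLUMNS = (
    "bird_id",
    "motif_duration_ms",
    "stim_onset_ms",
    "truncated",
    "truncation_latency_ms",
    "category",
    "restart_latency_ms",
    "context",
)
BOUT_COLUMNS = ("bird_id", "motifs_in_bout", "stimulated_across_transition", "terminated_at_stim")
CELLCOUNT_COLUMNS = ("hemisphere_id", "nucleus", "cell_count")

CATEGORIES = ("motif_reset", "intro_notes_only", "call", "pause_continuation", "none")

#: Control-hemisphere count ratios (target nucleus relative to its reference)
#: used as generator defaults; references are Uva for the HVC afferents and
#: HVC for lMAN (an RA afferent).
DEFAULT_CONTROL_RATIOS: Mapping[str, float] = {
    "mMAN": 1.46,
    "NIf": 6.40,
    "Av": 0.09,
    "lMAN": 1.23,
}


@dataclass
class CohortSpec:
    """Ground-truth parameters of a synthetic stimulation cohort.

    Latency families are lognormal by default — behavioural latencies are
    positive and right-skewed — parameterized by the *median* (ms) and the
    log-scale sd. Bout lengths are shifted-geometric (memoryless motif
    chaining) with the given mean M >= 1.
    """

    n_birds: int = 6
    trials_per_bird: int = 100
    bouts_per_bird: int = 40
    motif_duration_mean: float = 700.0
    motif_duration_sd: float = 60.0
    p_truncation: float = 0.85
    truncation_latency_median: float = 66.0
    truncation_latency_logsd: float = 0.35
    category_probs: Sequence[float] = (0.7, 0.1, 0.05, 0.1, 0.05)
    restart_latency_median: float = 135.0
    restart_latency_logsd: float = 0.45
    mean_motifs_per_bout: float = 3.2
    p_bout_termination: float = 0.3
    latency_family: str = "lognormal"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_birds < 1:
            problems.append("n_birds must be >= 1")
        if self.trials_per_bird < 1:
            problems.append("trials_per_bird must be >= 1")
        if not 0.0 <= self.p_truncation <= 1.0:
            problems.append("p_truncation must lie in [0, 1]")
        if not 0.0 <= self.p_bout_termination <= 1.0:
            problems.append("p_bout_termination must lie in [0, 1]")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.size != len(CATEGORIES) or (probs < 0).any():
            problems.append(f"category_probs must be {len(CATEGORIES)} non-negative values")
        elif abs(probs.sum() - 1.0) > 1e-9:
            problems.append("category_probs must sum to 1")
        if self.mean_motifs_per_bout < 1.0:
            problems.append("mean_motifs_per_bout must be >= 1")
        if self.latency_family not in ("lognormal", "exponential"):
            problems.append("latency_family must be 'lognormal' or 'exponential'")
        if self.motif_duration_mean <= 100.0:
            problems.append("motif_duration_mean must exceed 100 ms")
        if problems:
            raise ValueError("invalid CohortSpec: " + "; ".join(problems))


def _draw_latency(rng: np.random.Generator, spec: CohortSpec, median: float, logsd: float, n: int):
    if spec.latency_family == "lognormal":
        return rng.lognormal(mean=np.log(median), sigma=logsd, size=n)
    return rng.exponential(scale=median / np.log(2.0), size=n)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw (trials, bouts, manifest) for a synthetic stimulation cohort.

    Stimulation onsets are uniform over each bird's motif; truncation is
    Bernoulli; post-truncation categories are multinomial over the five
    outcome levels; bout lengths are shifted-geometric. The manifest
    records every true parameter (and the seed), so estimator-recovery
    tests can compare against ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trial_rows = []
    bout_rows = []
    for b in range(spec.n_birds):
        bird = f"bird{b:02d}"
        motif = max(150.0, rng.normal(spec.motif_duration_mean, spec.motif_duration_sd))
        onsets = rng.uniform(0.0, motif, size=spec.trials_per_bird)
        truncated = rng.random(spec.trials_per_bird) < spec.p_truncation
        lat = _draw_latency(
            rng, spec, spec.truncation_latency_median, spec.truncation_latency_logsd,
            spec.trials_per_bird,
        )
        cats = rng.choice(len(CATEGORIES), size=spec.trials_per_bird, p=spec.category_probs)
        restart = _draw_latency(
            rng, spec, spec.restart_latency_median, spec.restart_latency_logsd,
            spec.trials_per_bird,
        )
        for i in range(spec.trials_per_bird):
            onset = float(onsets[i])
            context = "last_100ms" if onset > motif - 100.0 else "within_motif"
            is_trunc = bool(truncated[i])
            cat = CATEGORIES[cats[i]] if is_trunc else "none"
            trial_rows.append(
                dict(
                    bird_id=bird,
                    motif_duration_ms=motif,
                    stim_onset_ms=onset,
                    truncated=is_trunc,
                    truncation_latency_ms=float(lat[i]) if is_trunc else np.nan,
                    category=cat,
                    restart_latency_ms=(
                        float(restart[i]) if is_trunc and cat == "motif_reset" else np.nan
                    ),
                    context=context,
                )
            )
        # shifted geometric: 1 + Geom(q), mean = 1 + (1-q)/q = M
        q = 1.0 / spec.mean_motifs_per_bout if spec.mean_motifs_per_bout > 1 else 1.0
        n_bouts = rng.geometric(q, size=spec.bouts_per_bird) if q < 1.0 else np.ones(
            spec.bouts_per_bird, dtype=int
        )
        stimulated = rng.random(spec.bouts_per_bird) < 0.5
        terminated = stimulated & (rng.random(spec.bouts_per_bird) < spec.p_bout_termination)
        for i in range(spec.bouts_per_bird):
            bout_rows.append(
                dict(
                    bird_id=bird,
                    motifs_in_bout=int(n_bouts[i]),
                    stimulated_across_transition=bool(stimulated[i]),
                    terminated_at_stim=bool(terminated[i]),
                )
            )
    trials = pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS))
    bouts = pd.DataFrame(bout_rows, columns=list(BOUT_COLUMNS))
    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in spec.__dict__.items()
        },
        "categories": list(CATEGORIES),
        "n_trials": len(trials),
        "n_bouts": len(bouts),
    }
    return trials, bouts, manifest


def generate_cellcounts(
    ratios: Mapping[str, float] | None = None,
    hemispheres: int = 12,
    noise_cv: float = 0.3,
    seed: int = 0,
    reference: str = "Uva",
    base_mean: float = 400.0,
    base_dispersion: float = 8.0,
) -> pd.DataFrame:
    """Synthetic retrograde cell-count table for lesion extrapolation.

    Reference counts come from a negative binomial (over-dispersed, as
    real per-hemisphere counts are); each target count is ratio x reference
    x lognormal noise with coefficient of variation ``noise_cv``, then
    integerized. ``noise_cv=0`` recovers the ratios exactly.
    """
    if ratios is None:
        ratios = DEFAULT_CONTROL_RATIOS
    if any(r <= 0 for r in ratios.values()):
        raise ValueError("ratios must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    # NB with mean m and size k: p = k/(k+m)
    p_nb = base_dispersion / (base_dispersion + base_mean)
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for h in range(hemispheres):
        ref_count = int(rng.negative_binomial(base_dispersion, p_nb)) + 1
        rows.append(dict(hemisphere_id=f"hemi{h:02d}", nucleus=reference, cell_count=ref_count))
        for nucleus, ratio in ratios.items():
            noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma) if noise_cv > 0 else 1.0
            count = int(round(ratio * ref_count * noise))
            rows.append(dict(hemisphere_id=f"hemi{h:02d}", nucleus=nucleus, cell_count=count))
    return pd.DataFrame(rows, columns=list(CELLCOUNT_COLUMNS))


# ----------------------------------------------------------------------
_PULSE_CACHE: dict[str, float] = {}


def calibrate_pulse_amplitude(
    params: NetworkParameters, factor: float = 10.0, duration: float = 1400.0
) -> float:
    """Pulse amplitude = ``factor`` x the peak recurrent excitatory drive.

    "Intense" is defined relative to what the network itself generates: an
    unperturbed run is simulated and the maximum single-unit recurrent
    drive (HVC_X onto HVC_RA) is scaled up. Cached per parameter digest.
    """
    key = f"{params.digest()}:{factor}:{duration}"
    if key not in _PULSE_CACHE:
        conn = apply_boundary_compensation(build_connectivity(params), params)
        trace = simulate(params, conn, InputProtocol(), duration, seed=0)
        from .dynamics import activation

        spec_E = params.activation_specs["E"]
        stride = max(1, int(round(5.0 / params.dt)))
        drive = max(
            float((conn.W_X_RA @ activation(trace.r_X[k], spec_E)).max())
            for k in range(0, trace.r_X.shape[0], stride)
        )
        _PULSE_CACHE[key] = factor * drive
    return _PULSE_CACHE[key]


def canned_configs() -> dict[str, dict]:
    """Named model/protocol fixtures for the main experimental protocols.

    Keys: ``default_song`` (unperturbed traversal plus restart),
    ``pulse_mid`` (simulated optogenetic pulse while the bump is
    mid-chain), ``uva_off`` (tonic thalamic drive gated off mid-traversal)
    and ``degraded_p20`` (20% degraded HVC_X output with rate noise on).
    Each value holds ``params``, ``protocol`` and a suggested ``duration``.
    """
    base = NetworkParameters()
    amp = calibrate_pulse_amplitude(base)
    configs = {
        "default_song": dict(
            params=base,
            protocol=InputProtocol(uva_drive=((0.0, base.I_Uva),)),
            duration=1400.0,
        ),
        "pulse_mid": dict(
            params=base,
            protocol=InputProtocol(
                uva_drive=((0.0, base.I_Uva),),
                pulse_events=(PulseEvent("RA", 680.0, 10.0, amp),),
            ),
            duration=1700.0,
        ),
        "uva_off": dict(
            params=base,
            protocol=InputProtocol(uva_drive=((0.0, base.I_Uva), (700.0, 0.0))),
            duration=2500.0,
        ),
        "degraded_p20": dict(
            params=base.replace(degradation_p=0.2),
            protocol=InputProtocol(uva_drive=((0.0, base.I_Uva),), noise_enabled=True),
            duration=1500.0,
        ),
    }
    return configs


def get_config(name: str) -> dict:
    configs = canned_configs()
    try:
        return configs[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(configs)}"
        ) from None


def write_cohort(
    trials: pd.DataFrame, bouts: pd.DataFrame, manifest: dict, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials.to_csv(outdir / "trials.csv", index=False)
    bouts.to_csv(outdir / "bouts.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
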