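"""End-to-end experiment drivers.

Each function runs one of the package's headline experiments from scratch
— building connectivity, simulating, and reducing the trace to the
quantities of interest — so analyses, tests and reproduction scripts all
execute the identical computation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ranksums, spearmanr

from . import behavior as bh
from .connectivity import apply_boundary_compensation, build_connectivity
from .dynamics import InputProtocol, simulate
from .params import NetworkParameters
from .readout import (
    boundary_region_width,
    degradation_sweep,
    detect_events,
    track_bump,
    traversal_table,
)
from .synth import CohortSpec, DEFAULT_CONTROL_RATIOS, generate_cellcounts, generate_cohort, get_config

__all__ = [
    "run_fixture",
    "song_experiment",
    "pulse_experiment",
    "restart_latency_experiment",
    "uva_gating_experiment",
    "degradation_experiment",
    "behavior_recovery_experiment",
]


def run_fixture(name: str, seed: int = 0, noise: bool | None = None, duration: float | None = None):
    """Simulate a canned fixture; returns (params, protocol, trace)."""
    cfg = get_config(name)
    params, protocol = cfg["params"], cfg["protocol"]
    if noise is not None:
        protocol = InputProtocol(
            uva_drive=protocol.uva_drive,
            pulse_events=protocol.pulse_events,
            noise_enabled=noise,
        )
    conn = apply_boundary_compensation(build_connectivity(params), params)
    if params.degradation_p > 0:
        from .connectivity import degrade_hvcx_output

        conn = degrade_hvcx_output(
            conn, params.degradation_p, params.degradation_sigma_W, seed
        )
    trace = simulate(params, conn, protocol, duration or cfg["duration"], seed=seed)
    return params, protocol, trace


def song_experiment(seed: int = 0) -> dict:
    """Unperturbed traversal: initiation at the start, monotone advance,
    >= 95% coverage, self-termination at the boundary."""
    params, protocol, trace = run_fixture("default_song", seed=seed)
    track = track_bump(trace)
    events = detect_events(track, protocol, params)
    trav = traversal_table(events, track, params)
    pos = track.position[track.active]
    steps = np.diff(pos)
    within = steps[steps > -50]  # exclude the jump back at a restart
    first = trav.iloc[0] if not trav.empty else None
    return dict(
        events=events,
        traversals=trav,
        initiation_position=float(events.position.iloc[0]) if len(events) else np.nan,
        margin=boundary_region_width(params),
        max_backstep=float(-within.min()) if within.size else 0.0,
        first_length=float(first.length) if first is not None else 0.0,
        motif_duration_ms=(
            float(first.t_end - first.t_start) if first is not None else np.nan
        ),
        n_natural_ends=int((events.kind == "natural_end").sum()),
        n_truncations=int((events.kind == "truncation").sum()),
        final_amplitude=float(track.amplitude[-1]),
    )


def pulse_experiment(seed: int = 0) -> dict:
    """Mid-motif homogeneous pulse: one pulse-attributed truncation, one
    restart at the chain start, and the inhibition-stabilization order
    (global unit rises before excitatory activity collapses)."""
    params, protocol, trace = run_fixture("pulse_mid", seed=seed)
    track = track_bump(trace)
    events = detect_events(track, protocol, params)
    pulse = protocol.pulse_events[0]
    k_on = int(round(pulse.onset / params.dt))
    tot = trace.total_excitatory()
    pre = k_on - int(round(1.0 / params.dt))
    pre_g, pre_tot = float(trace.r_g[pre]), float(tot[pre])
    t_g_rise = float(trace.times[k_on + np.argmax(trace.r_g[k_on:] > pre_g)])
    t_collapse = float(trace.times[k_on + np.argmax(tot[k_on:] < 0.1 * pre_tot)])
    trunc = events[(events.kind == "truncation") & (events.cause == "pulse")]
    restarts = events[events.kind == "restart"]
    after = restarts[restarts.time_ms > trunc.time_ms.iloc[0]] if len(trunc) else restarts
    return dict(
        events=events,
        n_pulse_truncations=len(trunc),
        truncation_latency_ms=float(trunc.latency_ms.iloc[0]) if len(trunc) else np.nan,
        n_restarts_after=len(after),
        restart_position=float(after.position.iloc[0]) if len(after) else np.nan,
        margin=boundary_region_width(params),
        t_g_rise=t_g_rise,
        t_collapse=t_collapse,
        pulse_onset=pulse.onset,
    )


def restart_latency_experiment(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Restart latencies after pulse truncation vs after natural ends,
    across noise seeds, with the rank-sum comparison."""
    lat_pulse, lat_nat = [], []
    for k in range(n_seeds):
        seed = base_seed + k
        params, proto1, t1 = run_fixture("pulse_mid", seed=seed, noise=True, duration=1450.0)
        e1 = detect_events(track_bump(t1), proto1, params)
        trunc = e1[(e1.kind == "truncation") & (e1.cause == "pulse")]
        if not trunc.empty:
            r = e1[(e1.kind == "restart") & (e1.time_ms > trunc.time_ms.iloc[0])]
            if not r.empty:
                lat_pulse.append(float(r.latency_ms.iloc[0]))
        params, proto2, t2 = run_fixture("default_song", seed=seed, noise=True, duration=2400.0)
        e2 = detect_events(track_bump(t2), proto2, params)
        ne = e2[e2.kind == "natural_end"]
        if not ne.empty:
            r2 = e2[(e2.kind == "restart") & (e2.time_ms > ne.time_ms.iloc[0])]
            if not r2.empty:
                lat_nat.append(float(r2.latency_ms.iloc[0]))
    p_value = float(ranksums(lat_pulse, lat_nat).pvalue)
    return dict(
        lat_pulse=np.asarray(lat_pulse),
        lat_nat=np.asarray(lat_nat),
        ranksum_p=p_value,
    )


def uva_gating_experiment(seed: int = 0) -> dict:
    """Gate the tonic drive off mid-traversal: completion without restart;
    control with the drive on restarts after every end."""
    params, protocol, trace = run_fixture("uva_off", seed=seed)
    track = track_bump(trace)
    events = detect_events(track, protocol, params)
    gate_t = protocol.uva_drive[1][0]
    after_gate = events[events.time_ms > gate_t]
    params2, proto2, t2 = run_fixture("default_song", seed=seed, duration=2400.0)
    e2 = detect_events(track_bump(t2), proto2, params2)
    ends2 = int((e2.kind == "natural_end").sum())
    restarts2 = int((e2.kind == "restart").sum())
    return dict(
        events=events,
        max_position=float(np.nanmax(track.position)),
        completed=bool((events.kind == "natural_end").any()),
        restarts_after_gate=int((after_gate.kind == "restart").sum()),
        control_ends=ends2,
        control_restarts=restarts2,
        N=params.N,
    )


def degradation_experiment(
    p_grid=(0.0, 0.1, 0.2, 0.3, 0.4), seeds_per_p: int = 20, base_seed: int = 0
) -> dict:
    """Mean sequence length vs degraded proportion, plus its Spearman rho."""
    params = NetworkParameters()
    table = degradation_sweep(
        params, list(p_grid), seeds_per_p, duration=1500.0, base_seed=base_seed
    )
    rho = float(spearmanr(table.p, table.mean_length).statistic)
    return dict(table=table, rho=rho)


def behavior_recovery_experiment(seed: int = 0, n_trials: int = 500) -> dict:
    """Closed-loop recovery of generator ground truth by the behavioural
    estimators (reset probability, bout termination, lesion ratios)."""
    spec = CohortSpec(
        n_birds=1, trials_per_bird=n_trials, p_truncation=1.0,
        bouts_per_bird=200, seed=seed,
    )
    trials, bouts, _ = generate_cohort(spec)
    per_bird, summary = bh.reset_probability_from_trials(trials, bouts)
    p_term = bh.bout_termination_probability(bouts, "stimulated")
    n_term = int(bouts.stimulated_across_transition.sum())

    control = generate_cellcounts(DEFAULT_CONTROL_RATIOS, hemispheres=12,
                                  noise_cv=0.3, seed=seed + 1)
    sham = generate_cellcounts(DEFAULT_CONTROL_RATIOS, hemispheres=12,
                               noise_cv=0.3, seed=seed + 2)
    extent = bh.lesion_extent(control, sham, "Uva", list(DEFAULT_CONTROL_RATIOS))
    piv = control.pivot(index="hemisphere_id", columns="nucleus", values="cell_count")
    recovered_ratios = {
        t: float((piv[t] / piv["Uva"]).mean()) for t in DEFAULT_CONTROL_RATIOS
    }
    return dict(
        spec=spec,
        per_bird=per_bird,
        summary=summary,
        raw=float(per_bird.raw.iloc[0]),
        n_truncations=int(per_bird.n_truncations.iloc[0]),
        M=float(per_bird.M.iloc[0]),
        normalized=float(per_bird.normalized.iloc[0]),
        bout_termination=float(p_term),
        n_term_bouts=n_term,
        recovered_ratios=recovered_ratios,
        lesion_extent=extent,
    )
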