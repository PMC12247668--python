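"""Sequence-level readouts of simulation traces.

Operationalizes the song-level vocabulary on top of raw rate traces: the
traveling excitatory activity bump is tracked by its center of mass, and
active/inactive transitions of total excitatory activity become the event
taxonomy used for behaviour — initiation, truncation, natural end, restart
— with latencies. The degradation sweep reproduces the
sequence-length-vs-degradation experiment: weaker HVC_X output plus
per-unit rate noise makes traversals die at random chain positions, and
mean sequence length falls as the degraded proportion grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import apply_boundary_compensation, build_connectivity, degrade_hvcx_output
from .dynamics import InputProtocol, SimulationTrace, simulate
from .params import NetworkParameters

__all__ = [
    "BumpTrack",
    "track_bump",
    "detect_events",
    "sequence_length",
    "degradation_sweep",
    "boundary_region_width",
    "EVENT_COLUMNS",
]

#: Column schema of the event table.
EVENT_COLUMNS = ("kind", "time_ms", "cause", "position", "latency_ms")


@dataclass
class BumpTrack:
    """Bump position / amplitude readout of one trace.

    ``position`` is the center of mass of summed excitatory rates over
    chain indices, NaN wherever the network is inactive. ``active`` means
    total excitatory activity at or above ``threshold`` times its running
    maximum, so post-truncation suppression reads as inactive without
    needing an absolute rate scale.
    """

    times: np.ndarray
    position: np.ndarray
    amplitude: np.ndarray
    active: np.ndarray
    N: int
    threshold: float

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def boundary_region_width(params: NetworkParameters) -> float:
    """Width (chain positions) of the initial/terminal regions: 4*sigma*N/(2*pi).

    Matches the kernel footprint, so the zones where the boundary factors
    act are classified consistently.
    """
    return 4.0 * params.sigma * params.N / (2.0 * np.pi)


def track_bump(
    trace: SimulationTrace,
    activity_threshold: float = 0.1,
    settle_ms: float = 5.0,
) -> BumpTrack:
    """Center-of-mass bump track of the summed excitatory activity.

    "Active" compares the summed excitatory rate against its running
    *unperturbed* maximum: steps under an external pulse — plus a
    ``settle_ms`` relaxation window after it, while the hyper-activated
    field is still collapsing — are excluded from the maximum (their
    amplitude is not a propagation scale), and activity only counts once
    the running maximum itself has reached the threshold fraction of the
    trace-wide unperturbed peak, so sub-threshold stirrings before a bump
    has ever formed do not read as sequence activity.
    """
    if not 0.0 < activity_threshold < 1.0:
        raise ValueError(
            f"activity_threshold must lie in (0, 1), got {activity_threshold}"
        )
    if trace.times.size == 0:
        raise ValueError("empty trace")
    excite = trace.r_RA + trace.r_X
    amplitude = excite.sum(axis=1)
    pulsed = trace.pulse_applied.sum(axis=1) > 0
    n_settle = int(round(settle_ms / (trace.times[1] - trace.times[0])))
    if n_settle > 0 and pulsed.any():
        idx = np.flatnonzero(pulsed)
        for k in idx[np.flatnonzero(np.diff(idx, append=idx[-1] + 2) > 1)]:
            pulsed[k : k + n_settle + 1] = True
    unperturbed = ~pulsed
    amp_unpert = np.where(unperturbed, amplitude, 0.0)
    running_max = np.maximum.accumulate(amp_unpert)
    scale = float(amp_unpert.max(initial=0.0))
    active = (
        (amplitude >= activity_threshold * running_max)
        & (running_max >= activity_threshold * scale)
        & (scale > 0)
    )
    position = np.full(amplitude.shape, np.nan)
    nz = amplitude > 0
    idx = np.arange(trace.N, dtype=float)
    position[nz] = (excite[nz] @ idx) / amplitude[nz]
    position[~active] = np.nan
    return BumpTrack(
        times=trace.times,
        position=position,
        amplitude=amplitude,
        active=active,
        N=trace.N,
        threshold=activity_threshold,
    )


def _bridge_dips(active: np.ndarray, max_steps: int) -> np.ndarray:
    """Close inactive runs of <= max_steps steps flanked by activity.

    Sub-threshold dips shorter than the bridge window are measurement
    flicker (e.g. the fast excitation/suppression cycling while a strong
    pulse fights the global inhibitory unit), not real sequence ends.
    """
    if max_steps <= 0:
        return active
    active = active.copy()
    k = 0
    n = len(active)
    while k < n:
        if not active[k]:
            j = k
            while j < n and not active[j]:
                j += 1
            if 0 < k and j < n and (j - k) <= max_steps:
                active[k:j] = True
            k = j
        else:
            k += 1
    return active


def detect_events(
    track: BumpTrack,
    protocol: InputProtocol,
    params: NetworkParameters,
    gap_definition: float = 100.0,
    bridge_ms: float = 2.0,
) -> pd.DataFrame:
    """Event table (initiation / truncation / natural_end / restart).

    An active onset is an initiation (or a restart, when it follows an
    earlier sequence end at a position inside the initial region); an
    active offset inside the terminal region is a natural end, anywhere
    else a truncation. Truncations within ``gap_definition`` ms of a pulse
    onset are attributed to the pulse, otherwise to the single-unit rate
    noise. Restart latency is measured from the preceding offset;
    pulse-truncation latency from the most recent pulse onset.
    """
    dt = track.dt
    active = _bridge_dips(track.active, int(round(bridge_ms / dt)))
    margin = boundary_region_width(params)
    terminal_start = (track.N - 1) - margin
    pulse_onsets = sorted(ev.onset for ev in protocol.pulse_events)

    rows: list[dict] = []
    prev_offset_time: float | None = None
    changes = np.flatnonzero(np.diff(active.astype(np.int8)))
    for k in changes:
        t = float(track.times[k + 1])
        if active[k + 1]:  # onset
            pos = float(track.position[k + 1]) if active[k + 1] else np.nan
            if np.isnan(pos):
                # position defined only while active; take first finite
                nxt = np.flatnonzero(np.isfinite(track.position[k + 1 :]))
                pos = float(track.position[k + 1 + nxt[0]]) if nxt.size else np.nan
            if prev_offset_time is not None and pos <= margin:
                rows.append(
                    dict(
                        kind="restart",
                        time_ms=t,
                        cause="uva_gate",
                        position=pos,
                        latency_ms=t - prev_offset_time,
                    )
                )
            else:
                rows.append(
                    dict(
                        kind="initiation",
                        time_ms=t,
                        cause="uva_gate",
                        position=pos,
                        latency_ms=np.nan,
                    )
                )
        else:  # offset
            pos = float(track.position[k])  # last active step
            prev_offset_time = t
            if pos >= terminal_start:
                rows.append(
                    dict(
                        kind="natural_end",
                        time_ms=t,
                        cause="boundary",
                        position=pos,
                        latency_ms=np.nan,
                    )
                )
            else:
                recent = [p for p in pulse_onsets if p <= t <= p + gap_definition]
                if recent:
                    cause = "pulse"
                    latency = t - recent[-1]
                else:
                    cause = "degradation_noise"
                    latency = np.nan
                rows.append(
                    dict(
                        kind="truncation",
                        time_ms=t,
                        cause=cause,
                        position=pos,
                        latency_ms=latency,
                    )
                )
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def sequence_length(events: pd.DataFrame, track: BumpTrack) -> np.ndarray:
    """Fraction of the chain covered by each traversal, in [0, 1].

    One traversal runs from an initiation/restart onset to the next
    sequence end (or the end of the trace if still active); its length is
    the maximum bump position reached, normalized by N - 1.
    """
    return traversal_table(events, track).length.to_numpy()


def traversal_table(
    events: pd.DataFrame,
    track: BumpTrack,
    params: NetworkParameters | None = None,
) -> pd.DataFrame:
    """Per-traversal summary: (t_start, t_end, length, complete, launched).

    ``complete`` marks traversals that reached a terminating event before
    the trace ended; ``launched`` marks traversals whose bump escaped the
    initial region (mirroring the behavioural distinction between a motif
    and a failed motif start). Without ``params`` every traversal counts
    as launched.
    """
    onsets = events[events.kind.isin(("initiation", "restart"))]
    ends = events[events.kind.isin(("truncation", "natural_end"))]
    margin_frac = (
        boundary_region_width(params) / (track.N - 1) if params is not None else 0.0
    )
    rows = []
    t_final = float(track.times[-1])
    for t0 in onsets.time_ms:
        later_ends = ends.time_ms[ends.time_ms > t0]
        complete = not later_ends.empty
        t1 = float(later_ends.iloc[0]) if complete else t_final
        seg = track.position[(track.times >= t0) & (track.times <= t1)]
        if np.all(np.isnan(seg)):
            continue
        length = float(np.nanmax(seg)) / (track.N - 1)
        rows.append(
            dict(
                t_start=float(t0),
                t_end=t1,
                length=length,
                complete=complete,
                launched=length > margin_frac,
            )
        )
    return pd.DataFrame(
        rows, columns=["t_start", "t_end", "length", "complete", "launched"]
    )


def degradation_sweep(
    params: NetworkParameters,
    p_grid: list[float],
    seeds_per_p: int,
    duration: float = 900.0,
    base_seed: int = 0,
    activity_threshold: float = 0.1,
) -> pd.DataFrame:
    """Mean sequence length vs degraded proportion of HVC_X output.

    For each proportion ``p`` and replicate, the boundary-compensated
    connectivity is degraded with a fresh seed, the network is simulated
    with per-unit rate noise on, and the replicate's statistic is the mean
    length of its completed, launched traversals (failed launches — bumps
    that never escape the initial region — are tallied separately, the way
    failed motif starts are scored apart from motifs behaviourally; a
    traversal still running when the horizon ends is discarded). The noise
    is what randomizes the termination position: weights are fixed within
    a replicate (a "day"), so run-to-run scatter comes from single-unit
    variability. Output is sorted by p.
    """
    if seeds_per_p < 2:
        raise ValueError("seeds_per_p must be >= 2 (sd undefined otherwise)")
    if any(not 0.0 <= p <= 1.0 for p in p_grid):
        raise ValueError("all p values must lie in [0, 1]")
    if params.noise_fano <= 0:
        raise ValueError(
            "degradation_sweep requires noise_fano > 0; the rate noise is the "
            "source of random termination positions"
        )
    base = build_connectivity(params)
    base = apply_boundary_compensation(base, params)
    rows = []
    for ip, p in enumerate(sorted(p_grid)):
        rep_means = []
        restarts = 0
        failed_starts = 0
        for rep in range(seeds_per_p):
            ss = np.random.SeedSequence((base_seed, ip, rep))
            degrade_seed, sim_seed = (int(s) % (2**31) for s in ss.generate_state(2))
            conn = degrade_hvcx_output(
                base, p, params.degradation_sigma_W, degrade_seed
            )
            protocol = InputProtocol(
                uva_drive=((0.0, params.I_Uva),), noise_enabled=True
            )
            trace = simulate(params, conn, protocol, duration, seed=sim_seed)
            track = track_bump(trace, activity_threshold)
            events = detect_events(track, protocol, params)
            trav = traversal_table(events, track, params)
            keep = trav[trav.complete & trav.launched]
            failed_starts += int((~trav.launched).sum())
            if not keep.empty:
                rep_means.append(float(keep.length.mean()))
            restarts += int((events.kind == "restart").sum())
        rows.append(
            dict(
                p=p,
                mean_length=float(np.mean(rep_means)) if rep_means else 0.0,
                sd_length=(
                    float(np.std(rep_means, ddof=1)) if len(rep_means) > 1 else np.nan
                ),
                restart_count=restarts,
                failed_starts=failed_starts,
                n_replicates=len(rep_means),
            )
        )
    return pd.DataFrame(rows)
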