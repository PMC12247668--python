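"""Behavioural statistics for stimulation-trial records.

Implements the bespoke estimators used to quantify song truncation and
restart behaviour: the 300 ms stimulation-contingency rule for calling an
amplitude decay a truncation, percent-motif-advancement binning (10% bins
on a motif-minus-100ms axis, with a -20-0% region for events near or
across the motif boundary), the normalized motif-reset probability
raw / (1 - 1/M) where M is the mean motifs-per-bout, per-animal cumulative
latency distributions, bout-termination probability, and the ratio-based
lesion-extent extrapolation from retrograde cell counts.

Trial, bout and cell-count tables are plain DataFrames with the CSV
schemas declared in :mod:`hvcseq.synth`; strict readers with line-numbered
errors live at the bottom of this module.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ParameterError
from .synth import BOUT_COLUMNS, CATEGORIES, CELLCOUNT_COLUMNS, TRIAL_COLUMNS

__all__ = [
    "validate_truncation",
    "advancement_bin",
    "normalized_reset_probability",
    "reset_probability_from_trials",
    "latency_cdf",
    "group_latency_cdf",
    "bout_termination_probability",
    "lesion_extent",
    "category_fractions",
    "wilson_interval",
    "read_trials",
    "read_bouts",
    "read_cellcounts",
    "SchemaError",
]

MAX_TRUNCATION_LATENCY_MS = 300.0
POST_WINDOW_MS = 1000.0  # outcome categories are assessed in this window


class SchemaError(ValueError):
    """A table violates its documented CSV schema."""


# ----------------------------------------------------------------------
def validate_truncation(trial: Mapping, max_latency: float = MAX_TRUNCATION_LATENCY_MS) -> bool:
    """True iff the trial is a stimulation-contingent truncation.

    A truncation must follow stimulation within ``max_latency`` ms
    (default 300 ms); slower amplitude decays are not attributed to the
    stimulation. Non-truncated trials are False regardless of latency.
    """
    if not trial["truncated"]:
        return False
    latency = trial["truncation_latency_ms"]
    if latency is None or (isinstance(latency, float) and math.isnan(latency)):
        raise SchemaError("truncated trial lacks truncation_latency_ms")
    return float(latency) <= max_latency


def advancement_bin(trial: Mapping, event_time_ref: float) -> tuple[int, int] | None:
    """Percent-motif-advancement bin of an event, as a (lo, hi) pair.

    100% is the motif duration minus 100 ms, so bins are comparable across
    birds and the ambiguous final 100 ms is kept off the positive axis.
    ``event_time_ref`` is the event time from motif (syllable-A) onset;
    events in the last 100 ms of the motif, and events during intro notes
    or inter-motif connectors, are mapped into the -20-0% bins by their
    temporal distance to the next syllable-A onset (for intro/connector
    context pass that distance as a negative ``event_time_ref``). Returns
    None when the event cannot be referenced to a syllable-A onset
    (excluded from analysis).
    """
    motif = float(trial["motif_duration_ms"])
    if motif <= 100.0:
        raise ParameterError(f"motif duration must exceed 100 ms, got {motif}")
    span = motif - 100.0
    context = trial.get("context", "within_motif")

    if event_time_ref is None or (
        isinstance(event_time_ref, float) and math.isnan(event_time_ref)
    ):
        return None  # no syllable-A reference -> excluded

    if context == "intro_or_connector":
        if event_time_ref > 0:
            raise SchemaError(
                "intro/connector events are referenced by (negative) distance "
                "to the next syllable-A onset"
            )
        distance = -float(event_time_ref)
    elif event_time_ref > motif - 100.0 or context == "last_100ms":
        distance = motif - float(event_time_ref)
    else:
        if event_time_ref < 0:
            raise SchemaError(
                "negative event time without intro_or_connector context"
            )
        pct = float(event_time_ref) / span * 100.0
        lo = min(int(pct // 10) * 10, 90)  # 100% closes the last bin
        return (lo, lo + 10)

    pct = -distance / span * 100.0
    if pct < -20.0:
        return None  # beyond the -20-0% region
    lo = -20 if pct < -10.0 else -10
    return (lo, lo + 10)


def normalized_reset_probability(raw_reset_prob: float, mean_motifs_per_bout: float) -> float:
    """raw / (1 - 1/M): reset probability normalized by the chance that a
    motif is followed by another motif within the bout.

    May exceed 1 when resets are more likely than natural motif chaining.
    """
    if not 0.0 <= raw_reset_prob <= 1.0:
        raise ParameterError(f"raw probability must lie in [0, 1], got {raw_reset_prob}")
    if mean_motifs_per_bout <= 1.0:
        raise ParameterError(
            f"mean motifs per bout must exceed 1 for normalization, got "
            f"{mean_motifs_per_bout}"
        )
    return raw_reset_prob / (1.0 - 1.0 / mean_motifs_per_bout)


def reset_probability_from_trials(
    trials: pd.DataFrame,
    bouts: pd.DataFrame,
    max_latency: float = MAX_TRUNCATION_LATENCY_MS,
) -> tuple[pd.DataFrame, dict]:
    """Per-bird (raw, M, normalized) reset probabilities plus group summary.

    raw = fraction of validated truncations whose outcome is motif_reset;
    M = the bird's mean motifs-per-bout; normalized = raw / (1 - 1/M).
    The group summary aggregates per-bird values as mean +/- SEM (matching
    per-animal-first reporting); Wilson 95% intervals are attached to the
    per-bird raw probabilities.
    """
    rows = []
    for bird, tb in trials.groupby("bird_id"):
        valid = tb[[validate_truncation(r, max_latency) for _, r in tb.iterrows()]]
        if valid.empty:
            raise ValueError(f"no validated truncations for {bird}; raw undefined")
        bb = bouts[bouts.bird_id == bird]
        if bb.empty:
            raise ValueError(f"no bouts for {bird}; M undefined")
        raw = float((valid.category == "motif_reset").mean())
        M = float(bb.motifs_in_bout.mean())
        lo, hi = wilson_interval(int((valid.category == "motif_reset").sum()), len(valid))
        rows.append(
            dict(
                bird_id=bird,
                n_truncations=len(valid),
                raw=raw,
                raw_wilson_low=lo,
                raw_wilson_high=hi,
                M=M,
                normalized=normalized_reset_probability(raw, M),
            )
        )
    per_bird = pd.DataFrame(rows)
    n = len(per_bird)
    summary = {
        "raw_mean": float(per_bird.raw.mean()),
        "raw_sem": float(per_bird.raw.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "M_mean": float(per_bird.M.mean()),
        "normalized_mean": float(per_bird.normalized.mean()),
        "normalized_sem": (
            float(per_bird.normalized.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        ),
        "n_birds": n,
    }
    return per_bird, summary


def latency_cdf(latencies: Sequence[float], bin_width: float = 10.0) -> pd.DataFrame:
    """Cumulative probability curve over fixed-width latency bins.

    Right-continuous: each row gives the fraction of latencies <= the bin
    edge; the curve reaches 1 at the maximal latency. Default 10 ms bins.
    """
    lat = np.asarray(list(latencies), dtype=float)
    if lat.size == 0:
        raise ValueError("latency_cdf requires at least one latency")
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    edges = np.arange(0.0, np.ceil(lat.max() / bin_width) * bin_width + bin_width, bin_width)
    cum = np.array([(lat <= e).mean() for e in edges])
    return pd.DataFrame({"edge_ms": edges, "cum_prob": cum})


def group_latency_cdf(
    per_animal: Mapping[str, Sequence[float]], bin_width: float = 10.0
) -> pd.DataFrame:
    """Average of per-animal cumulative curves with SEM, on a common grid."""
    if not per_animal:
        raise ValueError("no animals supplied")
    curves = {k: latency_cdf(v, bin_width) for k, v in per_animal.items()}
    max_edge = max(c.edge_ms.iloc[-1] for c in curves.values())
    edges = np.arange(0.0, max_edge + bin_width, bin_width)
    mat = np.vstack(
        [
            np.interp(edges, c.edge_ms, c.cum_prob, right=1.0)
            for c in curves.values()
        ]
    )
    n = mat.shape[0]
    return pd.DataFrame(
        {
            "edge_ms": edges,
            "cum_prob_mean": mat.mean(axis=0),
            "cum_prob_sem": mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        }
    )


def bout_termination_probability(bouts: pd.DataFrame, condition: str) -> float:
    """Fraction of bouts in a condition whose bout ended at the stimulation.

    ``condition`` is ``"stimulated"`` (light across the motif-motif
    transition) or ``"sham"``.
    """
    if condition not in ("stimulated", "sham"):
        raise ParameterError(f"condition must be 'stimulated' or 'sham', got {condition!r}")
    sel = bouts[bouts.stimulated_across_transition == (condition == "stimulated")]
    if sel.empty:
        raise ValueError(f"no bouts in condition {condition!r}")
    return float(sel.terminated_at_stim.mean())


def category_fractions(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-bird fractions of the five post-truncation outcome levels.

    Computed over validated truncations; the four vocal categories plus
    the explicit ``none`` level (no vocal resumption within the 1 s
    window) are exclusive and sum to 1 per bird.
    """
    rows = []
    for bird, tb in trials.groupby("bird_id"):
        valid = tb[[validate_truncation(r) for _, r in tb.iterrows()]]
        if valid.empty:
            continue
        fracs = {c: float((valid.category == c).mean()) for c in CATEGORIES}
        rows.append(dict(bird_id=bird, n=len(valid), **fracs))
    return pd.DataFrame(rows)


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        raise ValueError("wilson_interval requires n > 0")
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


# ----------------------------------------------------------------------
def lesion_extent(
    counts_control: pd.DataFrame,
    counts_lesioned: pd.DataFrame,
    reference: str,
    targets: Iterable[str],
) -> pd.DataFrame:
    """Ratio-based lesion extrapolation from retrograde cell counts.

    For each target nucleus, the mean control-hemisphere ratio
    (target count / reference count) converts the lesioned animal's intact
    reference count into an expected target count; percent lesion is
    100 * (1 - observed / expected), clamped to [0, 100] (observed counts
    can exceed expected through sampling noise; negative lesion is
    reported as 0).
    """
    targets = list(targets)
    ctrl = counts_control.pivot(index="hemisphere_id", columns="nucleus", values="cell_count")
    if reference not in ctrl.columns:
        raise ValueError(f"reference nucleus {reference!r} absent from control table")
    if (ctrl[reference] == 0).any():
        raise ValueError("zero reference count in a control hemisphere")
    missing = [t for t in targets if t not in ctrl.columns]
    if missing:
        raise ValueError(f"targets absent from control table: {missing}")
    ratios = {t: float((ctrl[t] / ctrl[reference]).mean()) for t in targets}

    les = counts_lesioned.pivot(index="hemisphere_id", columns="nucleus", values="cell_count")
    if reference not in les.columns:
        raise ValueError(f"reference nucleus {reference!r} absent from lesioned table")
    if (les[reference] == 0).any():
        raise ValueError("zero reference count in a lesioned hemisphere")
    rows = []
    for hemi, row in les.iterrows():
        for t in targets:
            if t not in les.columns or pd.isna(row[t]):
                continue
            expected = ratios[t] * float(row[reference])
            observed = float(row[t])
            pct = 100.0 * (1.0 - observed / expected)
            rows.append(
                dict(
                    hemisphere_id=hemi,
                    nucleus=t,
                    control_ratio=ratios[t],
                    reference_count=float(row[reference]),
                    observed=observed,
                    expected=expected,
                    pct_lesion=float(np.clip(pct, 0.0, 100.0)),
                )
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def _read_table(path: str | Path, columns: Sequence[str], dtypes: Mapping[str, type]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    extra = [c for c in df.columns if c not in columns]
    if missing or extra:
        raise SchemaError(
            f"{path.name}: header mismatch (missing {missing}, unexpected {extra})"
        )
    for i, row in df.iterrows():
        for col, typ in dtypes.items():
            val = row[col]
            if typ is float and pd.isna(val):
                continue
            try:
                typ(val)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path.name} line {i + 2}: column {col!r} has invalid value {val!r}"
                ) from None
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    df = _read_table(
        path,
        TRIAL_COLUMNS,
        {"motif_duration_ms": float, "stim_onset_ms": float, "truncation_latency_ms": float},
    )
    bad = ~df.category.isin(CATEGORIES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise SchemaError(f"{Path(path).name} line {line}: unknown category {df.category[bad].iloc[0]!r}")
    return df


def read_bouts(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, BOUT_COLUMNS, {"motifs_in_bout": int})
    if (df.motifs_in_bout < 1).any():
        line = int(df.index[df.motifs_in_bout < 1][0]) + 2
        raise SchemaError(f"{Path(path).name} line {line}: motifs_in_bout must be >= 1")
    return df


def read_cellcounts(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, CELLCOUNT_COLUMNS, {"cell_count": int})
    if (df.cell_count < 0).any():
        line = int(df.index[df.cell_count < 0][0]) + 2
        raise SchemaError(f"{Path(path).name} line {line}: negative cell count")
    if df.duplicated(["hemisphere_id", "nucleus"]).any():
        raise SchemaError(f"{Path(path).name}: duplicate (hemisphere, nucleus) rows")
    return df
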