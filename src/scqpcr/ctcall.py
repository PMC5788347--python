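"""Cycle-threshold calling from per-chamber real-time fluorescence traces.

Traces are baseline-corrected by subtracting the mean fluorescence over an
early-cycle window, then CT is the first sustained, linearly interpolated
crossing of a single chip-wide threshold — one dashed line for the whole
device, as on the instrument.  A chamber that never crosses within the
40-cycle protocol is UNDETECTED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ChipConfig
from .simulate import ChipRun

__all__ = [
    "BaselineStats",
    "CTCall",
    "baseline_correct",
    "call_ct",
    "auto_threshold",
    "call_run",
    "DEFAULT_BASELINE_WINDOW",
]

#: Default baseline window, cycles 3–10 inclusive (1-based): skips cycle-1/2
#: optical settling while staying below the earliest plausible crossings.
DEFAULT_BASELINE_WINDOW = (3, 10)


@dataclass(frozen=True)
class BaselineStats:
    mean: float
    sd: float
    window: tuple[int, int]


@dataclass(frozen=True)
class CTCall:
    """One chamber's call: fractional CT or None when undetected."""

    ct: float | None
    threshold: float
    baseline: BaselineStats

    @property
    def detected(self) -> bool:
        return self.ct is not None


def baseline_correct(
    trace: np.ndarray, window: tuple[int, int] = DEFAULT_BASELINE_WINDOW
) -> tuple[np.ndarray, BaselineStats]:
    """Subtract the mean fluorescence over ``window`` (1-based, inclusive).

    Idempotent: re-correcting a corrected trace subtracts zero.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = window
    if hi - lo + 1 < 3:
        raise ValueError("baseline window must span at least 3 cycles")
    if lo < 1 or hi > trace.size:
        raise ValueError(
            f"baseline window {window} outside trace of {trace.size} cycles"
        )
    seg = trace[lo - 1 : hi]
    stats = BaselineStats(mean=float(seg.mean()), sd=float(seg.std(ddof=1)),
                          window=(lo, hi))
    return trace - stats.mean, stats


def call_ct(
    trace: np.ndarray,
    threshold: float,
    window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    baseline_corrected: bool = False,
) -> CTCall:
    """Call the cycle threshold of one trace.

    CT is the fractional cycle where the corrected fluorescence first crosses
    ``threshold``, linearly interpolated between the bracketing cycles.  A
    crossing must be sustained (the following cycle also above threshold) to
    reject single-cycle spikes; the final cycle needs no confirmation.
    Crossings at or before the baseline window end are not considered.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    trace = np.asarray(trace, dtype=float)
    if baseline_corrected:
        corrected = trace
        seg = trace[window[0] - 1 : window[1]]
        stats = BaselineStats(mean=0.0, sd=float(seg.std(ddof=1)), window=window)
    else:
        corrected, stats = baseline_correct(trace, window)

    n = corrected.size
    start = window[1]  # first eligible crossing cycle is window_end + 1
    for c in range(start + 1, n + 1):  # 1-based cycle index
        if corrected[c - 1] >= threshold:
            sustained = c == n or corrected[c] >= threshold
            if not sustained:
                continue
            prev = corrected[c - 2]
            if prev >= threshold:
                # Already above threshold at the window end: the crossing is
                # censored; report the first eligible cycle.
                ct = float(c)
            else:
                ct = (c - 1) + (threshold - prev) / (corrected[c - 1] - prev)
            return CTCall(ct=float(ct), threshold=threshold, baseline=stats)
    return CTCall(ct=None, threshold=threshold, baseline=stats)


def auto_threshold(
    traces: np.ndarray,
    window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    k: float = 10.0,
    plateau_clip: float = 0.5,
    positive_plateau_fraction: float = 0.05,
) -> float:
    """One chip-wide detection threshold from a run's traces.

    Threshold = ``k`` × median baseline SD, clipped from above at
    ``plateau_clip`` × the 10th percentile of positive-trace plateaus, where
    a trace counts as positive when its corrected maximum exceeds
    ``positive_plateau_fraction`` of the largest plateau on the chip.  On
    noiseless runs (all baseline SDs zero) the plateau clip alone sets the
    threshold.  Deterministic, and equivariant under rescaling all
    fluorescence values jointly.
    """
    traces = np.asarray(traces, dtype=float)
    traces = traces.reshape(-1, traces.shape[-1])
    if traces.shape[0] < 10:
        raise ValueError("auto_threshold needs at least 10 traces")
    corrected = np.empty_like(traces)
    sds = np.empty(traces.shape[0])
    for i, t in enumerate(traces):
        corrected[i], stats = baseline_correct(t, window)
        sds[i] = stats.sd
    plateaus = corrected.max(axis=1)
    top = plateaus.max()
    if top <= 0:
        raise ValueError("no amplification anywhere on the chip")
    positive = plateaus > positive_plateau_fraction * top
    ceiling = plateau_clip * np.percentile(plateaus[positive], 10)
    candidate = k * float(np.median(sds))
    if candidate <= 0 or candidate > ceiling:
        return float(ceiling)
    return float(candidate)


def call_run(
    run: ChipRun,
    threshold: float | None = None,
    window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> pd.DataFrame:
    """Call CTs for every chamber of a simulated run.

    Returns a long table with 1-based addressing: subarray, unit, chamber,
    assay, ct (NaN when undetected), detected, threshold.
    """
    cfg: ChipConfig = run.config
    if threshold is None:
        threshold = auto_threshold(run.traces, window=window)
    addr = run.addresses
    records = []
    for u in range(run.truth.n_units):
        for j in range(cfg.chambers_per_unit):
            call = call_ct(run.traces[u, j], threshold, window=window)
            records.append(
                (addr[u, 0], addr[u, 1], j + 1, run.chamber_assays[j],
                 np.nan if call.ct is None else call.ct, call.detected)
            )
    df = pd.DataFrame.from_records(
        records, columns=["subarray", "unit", "chamber", "assay", "ct", "detected"]
    )
    df["threshold"] = threshold
    return df
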