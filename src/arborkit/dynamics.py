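"""Filopodium lifetime/recruitment analysis and calcium-trace event rates.

Filopodia from time-lapse series are categorised by their relationship to
adhesion/active-zone puncta at their base: born on an existing punctum,
recruiting one within a 20-minute window, or never recruiting one.
Lifetimes of the punctum-associated and punctum-free groups are compared
with a Mann-Whitney test and summarised into the survival bins
{<10, 10–20, 20–60, >60 min}.

ΔF/F traces are scanned for transient onsets: a running-percentile
baseline is subtracted, the noise SD is estimated from the sub-baseline
residuals, and events are upward crossings of a multiple of that SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stats import TestResult, chi_square_gof, mann_whitney_u

CATEGORIES = ("origin_punctum", "recruited_within_window", "none")

LIFETIME_BIN_EDGES_MIN = (10.0, 20.0, 60.0)
LIFETIME_BIN_LABELS = ("<10", "10-20", "20-60", ">60")


@dataclass(frozen=True)
class FilopodiumTrack:
    """One filopodium's life history, in frames of a time-lapse series."""

    id: int
    birth_frame: int
    death_frame: int
    first_punctum_frame: int | None = None
    base_position: np.ndarray | None = None  # (frames, 2) µm, optional
    censored: bool = False
    category: str | None = None

    def __post_init__(self) -> None:
        if self.death_frame < self.birth_frame:
            raise ValueError(f"track {self.id}: death before birth")
        if self.first_punctum_frame is not None and not (
                self.birth_frame <= self.first_punctum_frame <= self.death_frame):
            raise ValueError(f"track {self.id}: first punctum outside life span")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def lifetime(self, frame_interval: float = 1.0) -> float:
        """Lifetime in minutes; a lower bound when ``censored``."""
        return (self.death_frame - self.birth_frame) * frame_interval


@dataclass(frozen=True)
class FluorescenceTrace:
    """A ΔF/F signal with per-sample epoch labels (e.g. temperature)."""

    times: np.ndarray      # seconds, strictly increasing
    values: np.ndarray     # ΔF/F
    epochs: np.ndarray     # label per sample

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        e = np.asarray(self.epochs)
        if not (t.shape == v.shape == e.shape) or t.ndim != 1:
            raise ValueError("times, values and epochs must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "epochs", e)


@dataclass
class EventDetectionConfig:
    baseline_percentile: float = 10.0
    threshold_sd_multiple: float = 3.0
    min_separation: float = 2.0      # seconds between event onsets
    baseline_window: float = 30.0    # seconds, running-percentile support
    min_above_samples: int = 2       # consecutive samples to confirm an onset
    recruitment_window: float = 20.0  # minutes, punctum-recruitment window

    def __post_init__(self) -> None:
        if not 0 < self.baseline_percentile <= 50:
            raise ValueError("baseline percentile must be in (0, 50]")
        if self.threshold_sd_multiple <= 0 or self.recruitment_window <= 0:
            raise ValueError("threshold multiple and window must be positive")
        if self.min_separation < 0 or self.baseline_window <= 0:
            raise ValueError("separations/windows must be positive")
        if self.min_above_samples < 1:
            raise ValueError("min_above_samples must be ≥ 1")


# -- filopodium categories ---------------------------------------------------


def classify_filopodia(tracks: Sequence[FilopodiumTrack],
                       cfg: EventDetectionConfig | None = None,
                       frame_interval: float = 1.0) -> list[FilopodiumTrack]:
    """Assign each track a category; returns labelled copies.

    A track is ``origin_punctum`` when a punctum is present at its base on
    the birth frame, ``recruited_within_window`` when the first punctum
    arrives within ``cfg.recruitment_window`` minutes of birth, and
    ``none`` otherwise (including puncta arriving after the window).
    """
    cfg = cfg or EventDetectionConfig()
    window_frames = cfg.recruitment_window / frame_interval
    out = []
    for t in tracks:
        if t.first_punctum_frame is None:
            cat = "none"
        elif t.first_punctum_frame == t.birth_frame:
            cat = "origin_punctum"
        elif t.first_punctum_frame - t.birth_frame <= window_frames:
            cat = "recruited_within_window"
        else:
            cat = "none"
        out.append(replace(t, category=cat))
    return out


def category_frequencies(tracks: Sequence[FilopodiumTrack]) -> dict[str, float]:
    """Category proportions in percent; tracks must be categorised."""
    if not tracks:
        raise ValueError("no tracks")
    counts = {c: 0 for c in CATEGORIES}
    for t in tracks:
        if t.category is None:
            raise ValueError("tracks must be categorised first")
        counts[t.category] += 1
    return {c: 100.0 * n / len(tracks) for c, n in counts.items()}


@dataclass
class LifetimeComparison:
    with_lifetimes: np.ndarray      # minutes, punctum-associated group
    without_lifetimes: np.ndarray   # minutes, punctum-free group
    with_mean: float
    with_sd: float
    without_mean: float
    without_sd: float
    with_censored: int
    without_censored: int
    with_bins: dict[str, float]     # percent per survival bin
    without_bins: dict[str, float]
    test: TestResult


def _bin_percent(lifetimes: np.ndarray) -> dict[str, float]:
    edges = (-np.inf,) + LIFETIME_BIN_EDGES_MIN + (np.inf,)
    counts = np.histogram(lifetimes, bins=edges)[0]
    return dict(zip(LIFETIME_BIN_LABELS, 100.0 * counts / lifetimes.size))


def lifetime_comparison(tracks: Sequence[FilopodiumTrack],
                        frame_interval: float = 1.0) -> LifetimeComparison:
    """Compare lifetimes of punctum-associated vs punctum-free filopodia.

    The associated group pools ``origin_punctum`` and
    ``recruited_within_window``.  Censored tracks (still alive at the end
    of the movie) enter the rank test at their observed lifetime — a
    conservative lower bound — and are counted separately.
    """
    with_g = [t for t in tracks
              if t.category in ("origin_punctum", "recruited_within_window")]
    without_g = [t for t in tracks if t.category == "none"]
    if not with_g or not without_g:
        raise ValueError("both lifetime groups must be non-empty")
    lw = np.array([t.lifetime(frame_interval) for t in with_g])
    lo = np.array([t.lifetime(frame_interval) for t in without_g])
    return LifetimeComparison(
        with_lifetimes=lw, without_lifetimes=lo,
        with_mean=float(lw.mean()), with_sd=float(lw.std(ddof=1)) if lw.size > 1 else 0.0,
        without_mean=float(lo.mean()),
        without_sd=float(lo.std(ddof=1)) if lo.size > 1 else 0.0,
        with_censored=sum(t.censored for t in with_g),
        without_censored=sum(t.censored for t in without_g),
        with_bins=_bin_percent(lw), without_bins=_bin_percent(lo),
        test=mann_whitney_u(lw, lo),
    )


def association_frequency_test(category_counts: dict[str, int],
                               expected_fraction: float = 0.5) -> TestResult:
    """χ² goodness-of-fit of (associated, not associated) counts against an
    expected associated fraction (a conservative 50 % by default)."""
    associated = (category_counts.get("origin_punctum", 0)
                  + category_counts.get("recruited_within_window", 0))
    non = category_counts.get("none", 0)
    if associated + non == 0:
        raise ValueError("no filopodia counted")
    if not 0 < expected_fraction < 1:
        raise ValueError("expected fraction must lie strictly in (0, 1)")
    return chi_square_gof([associated, non],
                          [expected_fraction, 1 - expected_fraction])


# -- calcium events ----------------------------------------------------------


def detect_events(trace: FluorescenceTrace,
                  cfg: EventDetectionConfig | None = None) -> np.ndarray:
    """Detect transient onsets; returns onset times in seconds.

    A running percentile (``cfg.baseline_percentile``) over a
    ``cfg.baseline_window``-second window removes slow drift while ignoring
    transients.  The noise SD is then the half-normal estimate from
    residuals below their own median — the lower half of the residual
    distribution is untouched by (upward) transients and, for Gaussian
    noise, has conditional second moment σ² about the median.  Events are
    crossings of median + ``threshold_sd_multiple``·SD that hold for
    ``min_above_samples`` consecutive samples (suppressing single-sample
    noise excursions) and are separated by ≥ ``min_separation`` seconds.
    A constant trace yields no events.
    """
    cfg = cfg or EventDetectionConfig()
    t, v = trace.times, trace.values
    if t.size < 20:
        raise ValueError("trace needs at least 20 samples")
    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(cfg.baseline_window / dt)) | 1)  # odd size
    baseline = ndimage.percentile_filter(v, cfg.baseline_percentile, size=win,
                                         mode="nearest")
    resid = v - baseline
    centre = float(np.median(resid))
    below = resid[resid < centre] - centre
    sd = float(np.sqrt(np.mean(below ** 2))) if below.size else 0.0
    if sd == 0:
        return np.empty(0)
    above = resid > centre + cfg.threshold_sd_multiple * sd
    k = cfg.min_above_samples
    if k > 1:  # confirmed: k consecutive supra-threshold samples
        kernel = np.ones(k, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == k
        confirmed = np.zeros_like(above)
        confirmed[:runs.size] = runs
    else:
        confirmed = above
    prev = np.concatenate([[False], confirmed[:-1]])
    onsets = np.flatnonzero(confirmed & ~prev)
    # hysteresis: once triggered, re-arm only after the signal falls back
    # to within 1 SD of the baseline (suppresses decay-tail re-triggers)
    rearm = resid < centre + sd
    times: list[float] = []
    last_idx = -1
    for i in onsets:
        if times:
            if t[i] - times[-1] < cfg.min_separation:
                continue
            if not np.any(rearm[last_idx:i]):
                continue
        times.append(float(t[i]))
        last_idx = i
    return np.asarray(times)


def event_rates_by_epoch(event_times: np.ndarray,
                         trace: FluorescenceTrace) -> dict[str, float]:
    """Events per minute within each labelled epoch of the trace.

    Epoch duration is the summed sample spacing carried by each label;
    events are attributed to the epoch of the nearest sample at the event
    onset.
    """
    event_times = np.asarray(event_times, dtype=float)
    t, labels = trace.times, trace.epochs
    dt = float(np.median(np.diff(t)))
    rates: dict[str, float] = {}
    for label in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        mask = labels == label
        duration_min = mask.sum() * dt / 60.0
        if duration_min <= 0:
            raise ValueError(f"epoch {label!r} has zero duration")
        if event_times.size:
            idx = np.searchsorted(t, event_times).clip(0, t.size - 1)
            n = int(np.count_nonzero(mask[idx]))
        else:
            n = 0
        rates[str(label)] = n / duration_min
    return rates
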