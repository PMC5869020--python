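"""Stick-and-grow synthetic data: arbor time series with filopodium
turnover, puncta coupled to bases/tips, ΔF/F traces with Poisson-timed
transients, and 2-D spot images.

The arbor generator emulates the growth mode the analyses assume: branches
extend stepwise in the plane while filopodia nucleate along them, live
under a memoryless (exponential) death hazard whose mean depends on
whether a punctum occupies their base, and mature into new branches if
they survive long enough.  Every output is a valid input for the I/O,
puncta and dynamics modules, and the generator records the ground truth
(track categories, lifetimes, event times, spot positions) needed to score
the pipeline against known parameters.  It is a test fixture with the
right statistical structure, not a biophysical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arbor_io import ArborSkeleton, SkeletonNode
from .dynamics import CATEGORIES, FilopodiumTrack, FluorescenceTrace


@dataclass
class GrowthConfig:
    """Stick-and-grow parameters.

    Rates are per frame; lifetimes are exponential means in minutes with
    ``mean_life_with_punctum`` ≥ ``mean_life_no_punctum``.  ``origin_prob``
    is the probability a filopodium nucleates on an existing punctum
    (independent of the per-frame ``capture_prob``, which also applies on
    the birth frame); leave it ``None`` to use ``capture_prob`` alone.
    Defaults follow the imaging regime the package analyses: 2-minute
    frames, ~4 vs ~20 minute mean lifetimes and a 36 % born-on-punctum
    fraction.
    """

    nucleation_rate: float = 0.02      # filopodia per µm of branch per frame
    capture_prob: float = 0.6          # per-frame punctum acquisition
    origin_prob: float | None = 0.36   # punctum already present at birth
    mean_life_no_punctum: float = 4.0  # minutes (tau_0)
    mean_life_with_punctum: float = 20.0  # minutes (tau_1)
    maturation_age: int = 10           # frames to stabilise into a branch
    branch_step: float = 1.0           # µm extension per frame
    turn_sd: float = 15.0              # degrees of heading noise per step
    filopodium_length: float = 1.5     # µm, nascent protrusion length
    n_frames: int = 40
    frame_interval: float = 2.0        # minutes
    z_jitter_sd: float = 0.0           # µm, optional out-of-plane noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleation_rate < 0 or not 0 <= self.capture_prob <= 1:
            raise ValueError("invalid nucleation rate or capture probability")
        if self.origin_prob is not None and not 0 <= self.origin_prob <= 1:
            raise ValueError("origin_prob must be a probability")
        if not 0 < self.mean_life_no_punctum <= self.mean_life_with_punctum:
            raise ValueError("need tau_1 ≥ tau_0 > 0")
        if self.maturation_age < 1 or self.n_frames < 2:
            raise ValueError("maturation_age ≥ 1 and n_frames ≥ 2 required")
        if min(self.branch_step, self.frame_interval,
               self.filopodium_length) <= 0:
            raise ValueError("steps and intervals must be positive")
        if self.turn_sd < 0 or self.z_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class TraceConfig:
    """Fluorescence-trace parameters.

    ``epochs`` is an ordered sequence of (label, duration s); events arrive
    as a Poisson process at ``event_rates[label]`` per minute and add an
    instantaneous-rise, exponential-decay transient.  Defaults mirror a
    two-temperature stimulation protocol: a quiet restrictive epoch
    (~0.93 events/min) followed by an active permissive epoch
    (~6.15 events/min).
    """

    epochs: tuple[tuple[str, float], ...] = (("restrictive", 120.0),
                                             ("permissive", 120.0))
    event_rates: dict[str, float] = field(
        default_factory=lambda: {"restrictive": 0.93, "permissive": 6.15})
    sample_dt: float = 0.2     # seconds
    amplitude: float = 1.0     # ΔF/F
    decay_tau: float = 1.0     # seconds
    noise_sd: float = 0.05     # ΔF/F
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_dt <= 0 or self.decay_tau <= 0:
            raise ValueError("sample_dt and decay_tau must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if not self.epochs:
            raise ValueError("at least one epoch required")
        for label, dur in self.epochs:
            if dur <= 0:
                raise ValueError(f"epoch {label!r} has non-positive duration")
            if self.event_rates.get(label, 0.0) < 0:
                raise ValueError(f"negative rate for epoch {label!r}")


@dataclass
class ArborTimeseries:
    """Output bundle of :func:`generate_arbor_timeseries`."""

    skeletons: list[ArborSkeleton]
    puncta: pd.DataFrame        # frame, punctum_id, x_um, y_um, channel
    tracks: list[FilopodiumTrack]
    truth: pd.DataFrame         # per track: frames, category, lifetime_min


class _Sim:
    """Mutable growth state shared by the per-frame update steps."""

    def __init__(self, cfg: GrowthConfig) -> None:
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.next_node = 1
        self.nodes: dict[int, dict] = {}
        self.order: list[int] = []
        root = self._add_node(np.zeros(2), -1, "branch")
        first = self._add_node(np.array([cfg.branch_step, 0.0]), root, "branch")
        self.tips: list[dict] = [{"node": first, "heading": 0.0}]
        self.filopodia: dict[int, dict] = {}
        self.next_track = 0
        self.closed: list[dict] = []
        self.puncta_rows: list[dict] = []
        self.next_punctum = 0

    def _add_node(self, pos: np.ndarray, parent: int, label: str) -> int:
        nid = self.next_node
        self.next_node += 1
        self.nodes[nid] = {"pos": np.asarray(pos, float), "parent": parent,
                           "label": label}
        self.order.append(nid)
        return nid

    def _spawn_punctum(self, filo: dict, frame: int) -> None:
        filo["first_punctum_frame"] = frame
        base = self.nodes[filo["base"]]["pos"]
        self.puncta_rows.append({"punctum_id": self.next_punctum,
                                 "birth_frame": frame,
                                 "x_um": base[0], "y_um": base[1]})
        self.next_punctum += 1

    def branch_length(self) -> float:
        total = 0.0
        for nid, n in self.nodes.items():
            if n["label"] == "branch" and n["parent"] != -1:
                total += float(np.linalg.norm(
                    n["pos"] - self.nodes[n["parent"]]["pos"]))
        return total

    # -- per-frame steps ----------------------------------------------------

    def extend_branches(self) -> None:
        cfg = self.cfg
        for tip in self.tips:
            tip["heading"] += np.deg2rad(cfg.turn_sd) * self.rng.standard_normal()
            step = cfg.branch_step * np.array([np.cos(tip["heading"]),
                                               np.sin(tip["heading"])])
            new = self._add_node(self.nodes[tip["node"]]["pos"] + step,
                                 tip["node"], "branch")
            tip["node"] = new

    def nucleate(self, frame: int) -> None:
        cfg = self.cfg
        n_new = self.rng.poisson(cfg.nucleation_rate * self.branch_length())
        branch_ids = [i for i in self.order if self.nodes[i]["label"] == "branch"]
        for _ in range(n_new):
            base = int(self.rng.choice(branch_ids))
            angle = self.rng.uniform(0, 2 * np.pi)
            tip_pos = self.nodes[base]["pos"] + cfg.filopodium_length * \
                np.array([np.cos(angle), np.sin(angle)])
            tip = self._add_node(tip_pos, base, "filopodium")
            filo = {"id": self.next_track, "base": base, "tip": tip,
                    "birth": frame, "first_punctum_frame": None}
            self.next_track += 1
            p_birth = cfg.capture_prob if cfg.origin_prob is None \
                else cfg.origin_prob
            if self.rng.random() < p_birth:
                self._spawn_punctum(filo, frame)
            self.filopodia[filo["id"]] = filo

    def capture(self, frame: int) -> None:
        # birth-frame acquisition is handled at nucleation (origin_prob)
        for filo in self.filopodia.values():
            if filo["birth"] < frame \
                    and filo["first_punctum_frame"] is None \
                    and self.rng.random() < self.cfg.capture_prob:
                self._spawn_punctum(filo, frame)

    def kill_and_mature(self, frame: int) -> None:
        cfg = self.cfg
        for fid in list(self.filopodia):
            filo = self.filopodia[fid]
            if filo["birth"] == frame:
                continue  # a filopodium survives the frame it appears in
            tau = cfg.mean_life_no_punctum \
                if filo["first_punctum_frame"] is None \
                else cfg.mean_life_with_punctum
            hazard = min(1.0, cfg.frame_interval / tau)
            if self.rng.random() < hazard:
                self._close(fid, death=frame, censored=False)
                tip = filo["tip"]
                del self.nodes[tip]
                self.order.remove(tip)
                del self.filopodia[fid]
            elif frame - filo["birth"] >= cfg.maturation_age:
                # stabilised: the protrusion becomes an extending branch
                self.nodes[filo["tip"]]["label"] = "branch"
                base = self.nodes[filo["base"]]["pos"]
                tip_pos = self.nodes[filo["tip"]]["pos"]
                heading = float(np.arctan2(*(tip_pos - base)[::-1]))
                self.tips.append({"node": filo["tip"], "heading": heading})
                self._close(fid, death=frame, censored=True)
                del self.filopodia[fid]

    def _close(self, fid: int, death: int, censored: bool) -> None:
        filo = self.filopodia[fid]
        self.closed.append({"id": fid, "birth": filo["birth"], "death": death,
                            "first_punctum_frame": filo["first_punctum_frame"],
                            "censored": censored})

    def snapshot(self, frame: int) -> ArborSkeleton:
        cfg = self.cfg
        nodes = []
        for nid in self.order:
            n = self.nodes[nid]
            z = cfg.z_jitter_sd * self.rng.standard_normal() \
                if cfg.z_jitter_sd else 0.0
            nodes.append(SkeletonNode(
                id=nid, position=np.array([n["pos"][0], n["pos"][1], z]),
                parent_id=n["parent"], structure_label=n["label"]))
        return ArborSkeleton(nodes, frame=frame,
                             frame_interval=cfg.frame_interval)


def generate_arbor_timeseries(cfg: GrowthConfig) -> ArborTimeseries:
    """Simulate stick-and-grow arbor growth; see :class:`GrowthConfig`.

    Per frame: branch tips extend, filopodia nucleate as
    Poisson(rate × branch cable length), puncta are acquired at bases
    (capture precedes the death draw within a frame), filopodia die with
    per-frame hazard ``frame_interval/τ``, and survivors older than
    ``maturation_age`` frames convert into extending branches (their
    tracks are censored at maturation since the protrusion persists).
    """
    sim = _Sim(cfg)
    skeletons = [sim.snapshot(0)]
    for frame in range(1, cfg.n_frames):
        sim.extend_branches()
        sim.nucleate(frame)
        sim.capture(frame)
        sim.kill_and_mature(frame)
        skeletons.append(sim.snapshot(frame))
    last = cfg.n_frames - 1
    for fid in sorted(sim.filopodia):
        sim._close(fid, death=last, censored=True)
    sim.closed.sort(key=lambda r: r["id"])

    window_frames = 20.0 / cfg.frame_interval  # truth window: 20 min
    tracks, truth_rows = [], []
    for rec in sim.closed:
        fp = rec["first_punctum_frame"]
        if fp is None:
            category = "none"
        elif fp == rec["birth"]:
            category = "origin_punctum"
        elif fp - rec["birth"] <= window_frames:
            category = "recruited_within_window"
        else:
            category = "none"
        tracks.append(FilopodiumTrack(
            id=rec["id"], birth_frame=rec["birth"], death_frame=rec["death"],
            first_punctum_frame=fp, censored=rec["censored"]))
        truth_rows.append({
            "track_id": rec["id"], "birth_frame": rec["birth"],
            "death_frame": rec["death"], "censored": rec["censored"],
            "first_punctum_frame": -1 if fp is None else fp,
            "category": category,
            "lifetime_min": (rec["death"] - rec["birth"]) * cfg.frame_interval})

    puncta_rows = []
    for row in sim.puncta_rows:
        for frame in range(row["birth_frame"], cfg.n_frames):
            puncta_rows.append({"frame": frame,
                                "punctum_id": row["punctum_id"],
                                "x_um": row["x_um"], "y_um": row["y_um"],
                                "channel": "synthetic"})
    puncta = pd.DataFrame(
        puncta_rows,
        columns=["frame", "punctum_id", "x_um", "y_um", "channel"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["track_id", "birth_frame", "death_frame", "censored",
                 "first_punctum_frame", "category", "lifetime_min"])
    return ArborTimeseries(skeletons=skeletons, puncta=puncta,
                           tracks=tracks, truth=truth)


def generate_trace(cfg: TraceConfig) -> tuple[FluorescenceTrace, np.ndarray]:
    """Simulate a ΔF/F trace; returns (trace, true event onset times in s)."""
    rng = np.random.default_rng(cfg.seed)
    total = sum(d for _, d in cfg.epochs)
    times = np.arange(0.0, total, cfg.sample_dt)
    labels = np.empty(times.size, dtype=object)
    event_times: list[float] = []
    start = 0.0
    for label, dur in cfg.epochs:
        labels[(times >= start) & (times < start + dur)] = label
        rate_per_s = cfg.event_rates.get(label, 0.0) / 60.0
        n = rng.poisson(rate_per_s * dur)
        event_times.extend(np.sort(rng.uniform(start, start + dur, n)))
        start += dur
    values = np.zeros_like(times)
    for t0 in event_times:
        after = times >= t0
        values[after] += cfg.amplitude * np.exp(-(times[after] - t0)
                                                / cfg.decay_tau)
    if cfg.noise_sd:
        values = values + cfg.noise_sd * rng.standard_normal(times.size)
    trace = FluorescenceTrace(times=times, values=values, epochs=labels)
    return trace, np.asarray(event_times)


def generate_spot_image(n_spots: int, sigma_px: float = 2.0,
                        noise_sd: float = 0.05, size: tuple[int, int] = (128, 128),
                        seed: int = 0, max_tries: int = 10_000,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sum of unit-amplitude Gaussian spots plus noise.

    Spots are placed by rejection sampling with centres at least 8σ apart
    and 4σ from the border; returns (image, (n, 2) true (row, col)
    positions).  Raises if the packing is infeasible within ``max_tries``.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    margin = 4.0 * sigma_px
    min_sep = 8.0 * sigma_px
    centres: list[np.ndarray] = []
    tries = 0
    while len(centres) < n_spots:
        if tries >= max_tries:
            raise RuntimeError("could not place non-overlapping spots")
        tries += 1
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if all(np.linalg.norm(cand - c) >= min_sep for c in centres):
            centres.append(cand)
    rows, cols = np.mgrid[0:h, 0:w]
    image = np.zeros((h, w))
    for r, c in centres:
        image += np.exp(-((rows - r) ** 2 + (cols - c) ** 2)
                        / (2 * sigma_px ** 2))
    if noise_sd:
        image = image + noise_sd * rng.standard_normal((h, w))
    truth = np.vstack(centres) if centres else np.empty((0, 2))
    return image, truth
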