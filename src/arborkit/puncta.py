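"""Puncta-to-skeleton association, FWHM sizing and active-zone density.

Fluorescent puncta (e.g. Bruchpilot, Neuroligin-1 or Liprin-α accumulations)
are point detections in the same coordinate frame as the traced skeleton.
Each punctum is assigned to the nearest skeleton landmark within a radius
threshold: a branch point (node with ≥ 2 children), the base of a
filopodium (the junction node where a filopodium-labelled path joins a
branch), or a filopodium tip.  Puncta near the cable but away from any
landmark are "shaft"; puncta away from the skeleton entirely are "orphan".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .arbor_io import ArborSkeleton
from .errors import NoPeakError, TruncatedPeakError, UndefinedValueError
from .stats import SummaryStats, TestResult, f_test_variances

LOCALISATION_CLASSES = ("branch_point", "filopodium_base", "filopodium_tip",
                        "shaft", "orphan")


@dataclass(frozen=True)
class PunctumRecord:
    """One punctum detection; ``localisation`` and ``nearest_node`` are
    populated by :func:`classify_puncta`."""

    id: int
    frame: int
    position: np.ndarray  # (2,) or (3,), µm
    channel: str = ""
    localisation: str | None = None
    nearest_node: int | None = None
    diameter_nm: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape == (2,):
            pos = np.append(pos, 0.0)
        if pos.shape != (3,):
            raise ValueError("punctum position must be 2- or 3-vector")
        object.__setattr__(self, "position", pos)
        if self.diameter_nm is not None and self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")


@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D line-scan across a punctum: positions (nm) and intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.shape != inten.shape:
            raise ValueError("positions and intensities must be equal-length 1-D")
        if pos.size < 3:
            raise ValueError("profile needs at least 3 samples")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)


@dataclass
class AssociationSummary:
    fraction_puncta_at_nodes: float   # percent at branch points/filopodium bases
    fraction_nodes_with_puncta: float  # percent of those landmarks hosting one
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for f in (self.fraction_puncta_at_nodes, self.fraction_nodes_with_puncta):
            if not 0.0 <= f <= 100.0:
                raise ValueError("fractions are percentages in [0, 100]")


# -- landmark extraction -----------------------------------------------------


def skeleton_landmarks(skeleton: ArborSkeleton) -> dict[str, list[int]]:
    """Landmark node ids by class.

    Filopodium bases are the non-filopodium parents of filopodium-labelled
    chains; a junction hosting a filopodium is reported as a base rather
    than a plain branch point (the two are pooled in the association
    fractions anyway).  Filopodium tips are terminal filopodium nodes.
    """
    filo_ids = {n.id for n in skeleton if n.structure_label == "filopodium"}
    bases: set[int] = set()
    tips: list[int] = []
    for fid in filo_ids:
        parent = skeleton.node(fid).parent_id
        if parent != -1 and parent not in filo_ids:
            bases.add(parent)
        if not skeleton.children(fid):
            tips.append(fid)
    branch_points = [i for i in skeleton.branch_point_ids() if i not in bases]
    return {"branch_point": branch_points,
            "filopodium_base": sorted(bases),
            "filopodium_tip": sorted(tips)}


def _min_edge_distance(points: np.ndarray, skeleton: ArborSkeleton) -> np.ndarray:
    """Distance from each query point to the nearest skeleton edge segment."""
    edges = skeleton.edges()
    if not edges:
        only = skeleton.positions()
        if only.size == 0:
            return np.full(len(points), np.inf)
        return np.linalg.norm(points[:, None, :] - only[None, :, :],
                              axis=2).min(axis=1)
    a = skeleton.positions([p for p, _ in edges])
    b = skeleton.positions([c for _, c in edges])
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    # project every point onto every segment, clamped to [0, 1]
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("pij,ij->pi", ap, ab) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2).min(axis=1)


def classify_puncta(skeleton: ArborSkeleton,
                    puncta: Sequence[PunctumRecord],
                    radius_thresh: float = 2.0) -> list[PunctumRecord]:
    """Assign each punctum a localisation class; returns labelled copies.

    The class is that of the nearest landmark within ``radius_thresh`` µm;
    failing that, "shaft" if the nearest skeleton edge is within the
    threshold, else "orphan".  The partition is total.  All puncta must
    share the skeleton's frame index.
    """
    for p in puncta:
        if p.frame != skeleton.frame:
            raise ValueError(f"punctum {p.id} frame {p.frame} != skeleton "
                             f"frame {skeleton.frame}")
    if not puncta:
        return []
    landmarks = skeleton_landmarks(skeleton)
    lm_ids = [i for cls in LOCALISATION_CLASSES[:3] for i in landmarks[cls]]
    lm_cls = [cls for cls in LOCALISATION_CLASSES[:3] for _ in landmarks[cls]]
    positions = np.vstack([p.position for p in puncta])
    labelled: list[PunctumRecord] = []
    if lm_ids:
        lm_pos = skeleton.positions(lm_ids)
        dists = np.linalg.norm(positions[:, None, :] - lm_pos[None, :, :], axis=2)
        nearest = dists.argmin(axis=1)
        nearest_d = dists[np.arange(len(puncta)), nearest]
    else:
        nearest = np.zeros(len(puncta), dtype=int)
        nearest_d = np.full(len(puncta), np.inf)
    edge_d = _min_edge_distance(positions, skeleton)
    for k, p in enumerate(puncta):
        if nearest_d[k] <= radius_thresh:
            cls = lm_cls[nearest[k]]
            node = lm_ids[nearest[k]]
        elif edge_d[k] <= radius_thresh:
            cls, node = "shaft", None
        else:
            cls, node = "orphan", None
        labelled.append(replace(p, localisation=cls, nearest_node=node))
    return labelled


def association_summary(labelled: Sequence[PunctumRecord],
                        skeleton: ArborSkeleton) -> AssociationSummary:
    """Fractions of puncta at branch points/filopodium bases and of such
    landmarks hosting at least one punctum (both in percent)."""
    if not labelled:
        raise UndefinedValueError("association fractions undefined: no puncta")
    counts = {cls: 0 for cls in LOCALISATION_CLASSES}
    hosting: set[int] = set()
    for p in labelled:
        if p.localisation is None:
            raise ValueError("puncta must be classified first")
        counts[p.localisation] += 1
        if p.localisation in ("branch_point", "filopodium_base"):
            hosting.add(p.nearest_node)
    landmarks = skeleton_landmarks(skeleton)
    node_like = set(landmarks["branch_point"]) | set(landmarks["filopodium_base"])
    at_nodes = counts["branch_point"] + counts["filopodium_base"]
    frac_puncta = 100.0 * at_nodes / len(labelled)
    frac_nodes = (100.0 * len(hosting & node_like) / len(node_like)
                  if node_like else 0.0)
    return AssociationSummary(frac_puncta, frac_nodes, counts)


# -- FWHM sizing -------------------------------------------------------------


def fwhm_diameter(profile: IntensityProfile) -> float:
    """Full width at half maximum of the profile's peak, in nm.

    Background is the mean of the first and last samples, subtracted before
    locating the half-maximum level; the two crossings are found by linear
    interpolation on either side of the peak, taking the outermost crossing
    when a plateau produces several (widest-width tie-break).
    """
    pos, inten = profile.positions, profile.intensities
    background = 0.5 * (inten[0] + inten[-1])
    corrected = inten - background
    ipk = int(np.argmax(corrected))
    if ipk == 0 or ipk == len(pos) - 1 or corrected[ipk] <= 0:
        raise NoPeakError("no interior maximum above background")
    half = corrected[ipk] / 2.0

    def interp(i: int, j: int) -> float:
        frac = (half - corrected[i]) / (corrected[j] - corrected[i])
        return float(pos[i] + frac * (pos[j] - pos[i]))

    # upward crossings left of the peak, scanning outward-in; the outermost
    # one gives the widest width (plateau/oscillation tie-break)
    left = next((interp(i, i + 1) for i in range(0, ipk)
                 if corrected[i] < half <= corrected[i + 1]), None)
    right = next((interp(i, i - 1) for i in range(len(pos) - 1, ipk, -1)
                  if corrected[i] < half <= corrected[i - 1]), None)
    if left is None or right is None:
        raise TruncatedPeakError("half-maximum not crossed on one side")
    return float(right - left)


def compare_diameter_dispersion(group_a, group_b) -> TestResult:
    """F-test of equality of variances between two diameter samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n ≥ 2")
    return f_test_variances(SummaryStats.from_sample(a),
                            SummaryStats.from_sample(b))


def active_zone_density(punctum_count: int, traced_area: float) -> float:
    """Active-zone density in µm⁻²: puncta per unit traced bouton area."""
    if traced_area <= 0:
        raise ValueError("traced_area must be positive")
    if punctum_count < 0:
        raise ValueError("punctum_count must be non-negative")
    return punctum_count / traced_area


# -- spot detection ----------------------------------------------------------


def detect_puncta(image: np.ndarray, min_diameter_px: int = 3,
                  threshold: float | None = None) -> np.ndarray:
    """Detect punctate spots in a 2-D image; returns (n, 2) centroids
    in (row, col) pixel coordinates.

    Candidate spots are local maxima above ``threshold`` (default:
    background median + 5 MADs) whose above-half-maximum connected region
    spans at least ``min_diameter_px`` pixels along its widest axis.
    Centroids are intensity-weighted over that region.
    """
    from scipy import ndimage
    from skimage.feature import peak_local_max

    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("image must be a finite 2-D array")
    if threshold is None:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        threshold = med + 5 * 1.4826 * (mad if mad > 0 else np.finfo(float).eps)
    peaks = peak_local_max(img, min_distance=max(1, min_diameter_px // 2),
                           threshold_abs=threshold, exclude_border=False)
    background = float(np.median(img))
    centroids: list[np.ndarray] = []
    for r, c in peaks:
        half = background + (img[r, c] - background) / 2.0
        mask = img >= half
        lab, _ = ndimage.label(mask)
        region = lab == lab[r, c]
        rows, cols = np.nonzero(region)
        extent = max(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
        if extent < min_diameter_px:
            continue
        w = img[region] - background
        w = np.clip(w, 0, None)
        if w.sum() <= 0:
            continue
        centroids.append(np.array([np.average(rows, weights=w),
                                   np.average(cols, weights=w)]))
    if not centroids:
        return np.empty((0, 2))
    # merge duplicates: several peaks can share one above-half-max region
    out: list[np.ndarray] = []
    for cen in centroids:
        if all(np.linalg.norm(cen - o) > min_diameter_px for o in out):
            out.append(cen)
    return np.vstack(out)
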