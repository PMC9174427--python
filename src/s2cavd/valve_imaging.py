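"""Volumetric quantification of aortic-valve calcification.

Two-channel confocal Z-stacks per valve cusp are binarized with one common
intensity threshold: the autofluorescence channel yields the total leaflet
volume and the calcium-probe (OsteoSense) channel the calcified volume.
Percent calcification by volume is the positive probe voxel count within
the leaflet mask over the leaflet voxel count.  Subject-level burden across
cusps then drives the disease labeling rule: Control mice are Healthy;
adenine-diet mice are CKD+CAVD if their burden exceeds 0% and CKD otherwise.

A synthetic stack generator plants exact volume fractions inside an
ellipsoidal leaflet, with calcific blobs clustered near the leaflet base,
so recovery of the planted fraction is testable to voxel precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

CUSPS = ("NCC", "LCC", "RCC")


@dataclass
class LeafletStack:
    """Two aligned 3-D intensity grids (slice, row, column) for one cusp."""

    osteo_channel: np.ndarray
    auto_channel: np.ndarray
    cusp: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.osteo_channel.shape != self.auto_channel.shape:
            raise ValueError(
                f"channel shapes differ: {self.osteo_channel.shape} vs {self.auto_channel.shape}"
            )
        if np.any(self.osteo_channel < 0) or np.any(self.auto_channel < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class CalcificationMeasure:
    positive_osteo_voxels: int
    positive_auto_voxels: int
    percent_by_volume: float
    cusp: str
    subject_id: str


@dataclass
class SubjectLabel:
    subject_id: str
    diet_group: str
    aov_calcification_pct: float
    label: str


def _ellipsoid_mask(shape: Tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal leaflet mask filling ~60% of each axis."""
    zz, yy, xx = np.indices(shape)
    cz, cy, cx = [(s - 1) / 2 for s in shape]
    rz, ry, rx = [0.38 * s for s in shape]
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_stack(
    shape: Tuple[int, int, int] = (12, 48, 48),
    planted_fraction: float = 0.1,
    noise_std: float = 0.0,
    seed: int = 0,
    cusp: str = "NCC",
    subject_id: str = "synthetic",
    foreground: float = 200.0,
    background: float = 5.0,
) -> Tuple[LeafletStack, float]:
    """Build a synthetic two-channel stack with an exact planted fraction.

    The autofluorescence channel is an ellipsoidal leaflet; the probe
    channel marks ``round(planted_fraction * leaflet_volume)`` leaflet
    voxels positive, grown as clustered blobs from seed points in the lower
    (base) half of the leaflet.  Returns the stack and the exactly realized
    voxel fraction.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError(f"planted_fraction must lie in [0, 1], got {planted_fraction}")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    leaflet = _ellipsoid_mask(shape)
    n_leaflet = int(leaflet.sum())
    target = int(round(planted_fraction * n_leaflet))

    osteo_mask = np.zeros(shape, dtype=bool)
    if target > 0:
        coords = np.argwhere(leaflet)
        # favor the leaflet base: rank voxels by distance to seed points in
        # the lower rows, then take the closest `target` voxels blob-wise
        base_rows = coords[:, 1] >= np.median(coords[:, 1])
        base_coords = coords[base_rows] if base_rows.any() else coords
        n_seeds = max(1, min(4, target))
        seeds = base_coords[rng.choice(len(base_coords), size=n_seeds, replace=False)]
        d = np.min(
            np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2), axis=1
        )
        order = np.argsort(d, kind="mergesort")
        chosen = coords[order[:target]]
        osteo_mask[tuple(chosen.T)] = True

    auto = np.where(leaflet, foreground, background).astype(float)
    osteo = np.where(osteo_mask, foreground, background).astype(float)
    if noise_std > 0:
        auto = np.clip(auto + noise_std * rng.standard_normal(shape), 0, None)
        osteo = np.clip(osteo + noise_std * rng.standard_normal(shape), 0, None)
    realized = target / n_leaflet
    stack = LeafletStack(osteo_channel=osteo, auto_channel=auto, cusp=cusp, subject_id=subject_id)
    return stack, realized


def binarize(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Voxel positive iff intensity strictly exceeds the threshold.

    The same threshold must be applied to every stack of a dataset run;
    the pipeline enforces that by passing a single configured value.
    """
    channel = np.asarray(channel, dtype=float)
    return channel > threshold


def percent_calcification(
    osteo_mask: np.ndarray, auto_mask: np.ndarray, cusp: str = "", subject_id: str = ""
) -> CalcificationMeasure:
    """Percent calcified volume: probe-positive voxels inside the leaflet.

    Probe positivity is counted only within the leaflet (autofluorescence)
    mask, so the percentage is bounded by 100.
    """
    if osteo_mask.shape != auto_mask.shape:
        raise ValueError("mask shapes differ")
    n_auto = int(np.count_nonzero(auto_mask))
    if n_auto == 0:
        raise ValueError("empty leaflet mask: percent calcification undefined")
    n_osteo = int(np.count_nonzero(osteo_mask & auto_mask))
    return CalcificationMeasure(
        positive_osteo_voxels=n_osteo,
        positive_auto_voxels=n_auto,
        percent_by_volume=100.0 * n_osteo / n_auto,
        cusp=cusp,
        subject_id=subject_id,
    )


def measure_stack(stack: LeafletStack, threshold: float) -> CalcificationMeasure:
    """Binarize both channels at the common threshold and quantify."""
    return percent_calcification(
        binarize(stack.osteo_channel, threshold),
        binarize(stack.auto_channel, threshold),
        cusp=stack.cusp,
        subject_id=stack.subject_id,
    )


def label_subject(
    subject_id: str,
    diet_group: str,
    measures: Sequence[CalcificationMeasure],
    volume_weighted: bool = True,
) -> SubjectLabel:
    """Apply the disease-labeling rule to a subject's cusp measurements.

    Subject-level burden is the volume-weighted mean across available cusps
    (unweighted mean with ``volume_weighted=False``).  Control mice are
    Healthy regardless of measurements; adenine-diet mice are CKD+CAVD when
    the burden exceeds 0% and CKD when it equals 0%.
    """
    if diet_group == "Control":
        pct = _aggregate(measures, volume_weighted) if measures else 0.0
        return SubjectLabel(subject_id, diet_group, pct, "Healthy")
    if not measures:
        raise ValueError(
            f"subject {subject_id} ({diet_group}) has no cusp measurements; cannot label"
        )
    pct = _aggregate(measures, volume_weighted)
    label = "CKD+CAVD" if pct > 0 else "CKD"
    return SubjectLabel(subject_id, diet_group, pct, label)


def _aggregate(measures: Sequence[CalcificationMeasure], volume_weighted: bool) -> float:
    pcts = np.array([m.percent_by_volume for m in measures])
    if volume_weighted:
        weights = np.array([m.positive_auto_voxels for m in measures], dtype=float)
        return float(np.average(pcts, weights=weights))
    return float(np.mean(pcts))
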