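"""Reported quantities for a solved case.

Maxima are always taken over tissue elements only (the probe interior is
excluded — the comparison metric is the strain the implant induces in the
surrounding tissue). Strains are element-centroid values without nodal
averaging, so maxima are smoothing-independent; nodal-averaged solvers may
report systematically different peak values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fem import StrainField
from .geometry import REGION_TISSUE, DomainSpec, HexMesh

__all__ = [
    "StrainProfile",
    "max_tissue_strain",
    "classify_max_location",
    "normalize_to_baseline",
    "percent_reduction",
    "strain_profile",
    "decay_span",
]

#: Fig-9-style profile start for mid/top sections: distance of the first
#: sample from the probe axial axis, um.
PROFILE_AXIS_START = 62.5


def max_tissue_strain(field: StrainField, mesh: HexMesh) -> tuple[float, np.ndarray]:
    """Maximum Von Mises strain over tissue elements and its centroid
    location (um). Ties break to the smallest element index."""
    tissue = np.flatnonzero(field.region == REGION_TISSUE)
    if tissue.size == 0:
        raise ValueError("strain field contains no tissue elements")
    vm = field.von_mises[tissue]
    k = tissue[int(np.argmax(vm))]  # argmax returns the first maximum
    centroid = mesh.nodes[mesh.elements[k]].mean(axis=0)
    return float(field.von_mises[k]), centroid


def classify_max_location(location: np.ndarray, spec: DomainSpec) -> str:
    """Classify an axial position into thirds of the embedded length:
    ``top`` (upper third), ``mid``, ``tip`` (lower third and below)."""
    y = float(np.asarray(location)[1])
    if y <= spec.embed_depth / 3.0:
        return "top"
    if y >= 2.0 * spec.embed_depth / 3.0:
        return "tip"
    return "mid"


def normalize_to_baseline(value: float, baseline_value: float) -> float:
    """Strain normalised against a baseline (stiff-probe) strain."""
    if baseline_value <= 0:
        raise ValueError("baseline must be positive")
    return value / baseline_value


def percent_reduction(value: float, baseline: float) -> float:
    """Percent reduction of ``value`` relative to ``baseline``:
    ``100 * (1 - value / baseline)``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (1.0 - value / baseline)


@dataclass
class StrainProfile:
    """Von Mises strain versus perpendicular distance from the probe.

    ``distances`` are measured from the probe thickness face (um), strictly
    increasing; ``values`` are the per-distance maxima over the tissue
    elements of the section band.
    """

    section: str
    distances: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        d, v = np.asarray(self.distances, float), np.asarray(self.values, float)
        if d.size != v.size or d.size == 0:
            raise ValueError("profile needs matching, non-empty samples")
        if np.any(np.diff(d) <= 0):
            raise ValueError("profile distances must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("Von Mises values must be non-negative")
        self.distances, self.values = d, v


_SECTION_FRACTION = {"top": 0.0, "mid": 0.5, "tip": 1.0}


def strain_profile(field: StrainField, mesh: HexMesh, spec: DomainSpec,
                   section: str, max_distance: float = 200.0,
                   band: float | None = None) -> StrainProfile:
    """Extract a strain-decay profile perpendicular to the probe thickness
    face at a section height.

    The section height is ``top`` (probe top), ``mid`` (half the embedded
    depth) or ``tip`` (the probe tip). Tissue elements whose axial extent
    intersects the section plane (or, when ``band`` is given, whose centroid
    lies within ``band`` um of it) and that sit laterally within the probe
    width are grouped by their centroid distance along z from the probe
    face; the profile value at each distance is the maximum Von Mises
    strain in the group. For the ``mid`` and ``top`` sections sampling
    starts 62.5 um from the probe axial axis. A ``max_distance`` beyond the
    tissue boundary is truncated with a warning.
    """
    if section not in _SECTION_FRACTION:
        raise ValueError(f"unknown section {section!r}")
    height = _SECTION_FRACTION[section] * spec.embed_depth

    z_face = spec.probe_thickness / 2.0
    z_limit = spec.tissue_length / 2.0 - z_face
    if max_distance > z_limit:
        warnings.warn(
            f"profile distance {max_distance} um truncated to the tissue "
            f"boundary ({z_limit:.1f} um)", stacklevel=2)
        max_distance = z_limit

    c = mesh.element_centroids()
    dist = c[:, 2] - z_face
    start = 0.0
    if section in ("mid", "top"):
        start = PROFILE_AXIS_START - z_face
    if band is None:
        ey = mesh.nodes[mesh.elements][:, :, 1]
        in_section = (ey.min(axis=1) <= height) & (ey.max(axis=1) >= height)
    else:
        in_section = np.abs(c[:, 1] - height) <= band
    sel = (
        in_section
        & (field.region == REGION_TISSUE)
        & (np.abs(c[:, 0]) <= spec.probe_width / 2.0)
        & (dist >= start) & (dist <= max_distance)
    )
    if not np.any(sel):
        raise ValueError(f"no tissue elements in the {section} section band")

    d = np.round(dist[sel], 6)
    vm = field.von_mises[sel]
    uniq, inv = np.unique(d, return_inverse=True)
    vals = np.zeros_like(uniq)
    np.maximum.at(vals, inv, vm)
    return StrainProfile(section=section, distances=uniq, values=vals)


def decay_span(profile: StrainProfile,
               threshold_fraction: float = 0.01) -> tuple[float, bool]:
    """Distance at which the profile first falls below
    ``threshold_fraction`` times its first (probe-adjacent) value.

    Returns ``(distance, reached)``; when the threshold is never reached the
    maximum sampled distance is returned with ``reached = False``.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    cutoff = threshold_fraction * profile.values[0]
    below = np.flatnonzero(profile.values <= cutoff)
    if below.size == 0:
        return float(profile.distances[-1]), False
    return float(profile.distances[below[0]]), True
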