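"""Radial positioning of chromatin within the simulated territory.

B-compartment loci carry the most favourable mutual interactions and form a
stable interior core, expelling A-compartment loci toward the territory
surface — the polymer analogue of hydrophobic collapse.  This module
quantifies that: per-group radial density profiles (A, B, all loci) as a
function of the normalised radial distance r/R from the per-frame territory
centre, and distributions of the radial distance of a segment's centre of
mass.  It applies to simulated ensembles, where the confinement radius R is
known; traced microscopy segments cover too little of the chromosome to
define a territory centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

A_TYPES = ("A1", "A2")
B_TYPES = ("B1", "B2", "B3")


def ab_labels_from_types(type_labels) -> np.ndarray:
    """Map chromatin types to compartments: A1/A2 -> A, B1/B2/B3 -> B, else NA."""
    out = np.full(len(type_labels), "NA", dtype=object)
    labels = np.asarray(type_labels, dtype=object)
    out[np.isin(labels, A_TYPES)] = "A"
    out[np.isin(labels, B_TYPES)] = "B"
    return out


@dataclass
class RadialProfile:
    """Shell-volume-normalised density per normalised-radius bin per group."""

    bin_centers: np.ndarray
    density: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    n_frames: int

    def mean_radius(self, group: str) -> float:
        """Density-weighted mean normalised radial distance of a group."""
        c = self.counts[group]
        return float((self.bin_centers * c).sum() / c.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"r_over_R": self.bin_centers})
        for g, d in self.density.items():
            df[f"density_{g}"] = d
        return df


def _frame_radii(coords: np.ndarray) -> np.ndarray:
    """Radial distance of each locus from the frame's all-locus centroid."""
    center = coords.mean(axis=0)
    return np.linalg.norm(coords - center, axis=1)


def radial_density(ensemble, compartment_labels, n_bins: int = 20,
                   r_max: float = 1.2) -> RadialProfile:
    """Radial density of A, B and all loci over an ensemble.

    Distances are normalised by the confinement radius R; per-group
    histograms are divided by the spherical-shell volume of each bin and
    normalised so each group's density integrates to 1 over shell volumes.
    """
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    labels = np.asarray(compartment_labels, dtype=object)
    coords = ensemble.coords_array()
    if len(labels) != coords.shape[1]:
        raise InvalidArgumentError("labels length must equal locus count")
    R = float(ensemble.confinement_radius)
    if R <= 0:
        raise InvalidArgumentError("ensemble must carry a confinement radius")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    groups = {"A": labels == "A", "B": labels == "B",
              "all": np.ones(len(labels), dtype=bool)}
    counts = {g: np.zeros(n_bins) for g in groups}
    for frame in coords:
        r = _frame_radii(frame) / R
        for g, mask in groups.items():
            if mask.any():
                counts[g] += np.histogram(r[mask], bins=edges)[0]
    density = {}
    for g, c in counts.items():
        total = c.sum()
        density[g] = (c / shell_vol) / total if total > 0 else np.full(n_bins, np.nan)
    return RadialProfile(bin_centers=centers, density=density, counts=counts,
                         n_frames=coords.shape[0])


def segment_com_distribution(ensemble, segment: tuple[int, int],
                             n_bins: int = 20,
                             r_max: float = 1.2) -> pd.DataFrame:
    """Distribution of the radial distance of a segment's centre of mass.

    ``segment`` is a half-open locus interval [start, stop).  Returns the
    per-frame normalised distances in column ``r_over_R`` plus a histogram
    summary (``bin_center``, ``probability``) as DataFrame attrs.
    """
    start, stop = segment
    coords = ensemble.coords_array()
    n = coords.shape[1]
    if not (0 <= start < stop <= n):
        raise InvalidArgumentError("segment must be a non-empty interval in range")
    R = float(ensemble.confinement_radius)
    samples = np.empty(coords.shape[0])
    for f, frame in enumerate(coords):
        center = frame.mean(axis=0)
        com = frame[start:stop].mean(axis=0)
        samples[f] = np.linalg.norm(com - center) / R
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges)
    df = pd.DataFrame({"r_over_R": samples})
    df.attrs["bin_center"] = 0.5 * (edges[:-1] + edges[1:])
    df.attrs["probability"] = hist / hist.sum() if hist.sum() else hist
    return df
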