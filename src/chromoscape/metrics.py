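"""Structural order parameters and heterogeneity analysis.

The similarity between two conformations a and b of the same segment is

    Q(a, b) = (1/N) sum_{i<j} exp(-(r_ij^a - r_ij^b)^2 / (2 delta^2))

over pairs of loci resolved in both structures, with delta = 0.165 um (1.0
sigma in reduced units), the resolution scale below which distance
deviations count as similar.  1 - Q is a metric-like dissimilarity used for
agglomerative clustering of an ensemble into conformational states (e.g.
closed vs open dumbbells); cluster occupancies give apparent free-energy
differences ln(N_major/N_minor) in kBT, and the radius of gyration provides
a complementary one-dimensional order parameter whose histogram yields a
potential of mean force, PMF(Rg) = -kBT ln P(Rg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, UndefinedResultError
from .structures import Structure3D
from .units import q_delta_for


@dataclass(frozen=True)
class QParams:
    """Q resolution length (same units as the structures) and pair filter."""

    delta: float
    min_pair_separation: int = 1

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise InvalidArgumentError("delta must be positive")
        if self.min_pair_separation < 1:
            raise InvalidArgumentError("min_pair_separation must be >= 1")

    @classmethod
    def for_units(cls, units: str, min_pair_separation: int = 1) -> "QParams":
        return cls(delta=q_delta_for(units),
                   min_pair_separation=min_pair_separation)


@dataclass
class ClusteringResult:
    """Agglomerative clustering of an ensemble under 1 - Q."""

    linkage_matrix: np.ndarray
    labels: np.ndarray
    distance_condensed: np.ndarray
    method: str

    @property
    def n_structures(self) -> int:
        return len(self.labels)

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.labels == cluster)[0]

    def subcluster(self, cluster: int, k: int,
                   method: str | None = None) -> "ClusteringResult":
        """Re-cluster one cluster's members into k sub-clusters."""
        idx = self.members(cluster)
        if len(idx) < k:
            raise InvalidArgumentError("cluster smaller than requested k")
        sub = squareform(self.distance_condensed)[np.ix_(idx, idx)]
        return hcluster(sub, method=method or self.method, k=k)


def _usable_pair_mask(n_loci: int, min_sep: int) -> np.ndarray:
    """Condensed-form mask of pairs with |i-j| >= min_sep."""
    iu, ju = np.triu_indices(n_loci, k=1)
    return (ju - iu) >= min_sep


def _condensed_distances(structure: Structure3D) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pairwise distances and per-pair co-resolution mask."""
    coords = structure.coords
    ok = structure.resolved_mask
    safe = np.where(ok[:, None], coords, 0.0)
    d = pdist(safe)
    iu, ju = np.triu_indices(len(ok), k=1)
    return d, ok[iu] & ok[ju]


def q_similarity(a: Structure3D, b: Structure3D,
                 params: QParams | None = None) -> float:
    """Q order parameter between two structures (missing-aware).

    A pair (i, j) contributes only when both loci are resolved in both
    structures; N is the number of contributing pairs.  Raises when no pair
    is usable.
    """
    if a.n_loci != b.n_loci:
        raise InvalidArgumentError("structures must share locus count")
    if a.units != b.units:
        raise InvalidArgumentError("structures must share units")
    params = params or QParams.for_units(a.units)
    da, ma = _condensed_distances(a)
    db, mb = _condensed_distances(b)
    mask = ma & mb & _usable_pair_mask(a.n_loci, params.min_pair_separation)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedResultError("no co-resolved pair between structures")
    diff = da[mask] - db[mask]
    return float(np.exp(-diff ** 2 / (2.0 * params.delta ** 2)).mean())


def q_matrix(ensemble, params: QParams | None = None,
             chunk: int = 16) -> np.ndarray:
    """Pairwise Q similarity matrix of an ensemble (vectorised, missing-aware).

    Accepts a TracedEnsemble/SimEnsemble (or any object with ``structures``
    or ``frames`` of Structure3D).  Raises if any structure pair has no
    co-resolved locus pair, listing the offending pairs.
    """
    structures = getattr(ensemble, "structures", None) or getattr(
        ensemble, "frames", None) or list(ensemble)
    if len(structures) < 2:
        raise InvalidArgumentError("need at least two structures")
    params = params or QParams.for_units(structures[0].units)
    n_loci = structures[0].n_loci
    pair_ok = _usable_pair_mask(n_loci, params.min_pair_separation)
    dists, masks = [], []
    for s in structures:
        d, m = _condensed_distances(s)
        dists.append(d)
        masks.append(m & pair_ok)
    D = np.asarray(dists)            # (S, P)
    M = np.asarray(masks)            # (S, P)
    D = np.where(M, D, 0.0)
    S = len(structures)
    q = np.empty((S, S))
    inv2d2 = 1.0 / (2.0 * params.delta ** 2)
    complete = bool(M.all())
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        diff = D[lo:hi, None, :] - D[None, :, :]          # (c, S, P)
        np.multiply(diff, diff, out=diff)
        np.multiply(diff, -inv2d2, out=diff)
        np.exp(diff, out=diff)
        if complete:
            q[lo:hi] = diff.mean(-1)
        else:
            both = M[lo:hi, None, :] & M[None, :, :]
            counts = both.sum(-1)
            if np.any(counts == 0):
                bad = [(int(i + lo), int(j))
                       for i, j in zip(*np.where(counts == 0))]
                raise UndefinedResultError(
                    f"structure pairs with no co-resolved loci: {bad[:10]}")
            diff[~both] = 0.0
            q[lo:hi] = diff.sum(-1) / counts
    q = 0.5 * (q + q.T)
    np.fill_diagonal(q, 1.0)
    return q


def hcluster(distance, method: str = "average", k: int | None = None,
             height: float | None = None) -> ClusteringResult:
    """Agglomerative clustering of a (1 - Q style) distance matrix.

    ``distance`` is a square symmetric matrix with zero diagonal (pass
    ``1 - q_matrix(...)``).  Cut either at ``k`` clusters or at a merge
    ``height``; labels are 1-based cluster ids.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidArgumentError("distance must be a square matrix")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise InvalidArgumentError("distance diagonal must be zero")
    if not np.allclose(d, d.T, atol=1e-8):
        raise InvalidArgumentError("distance must be symmetric")
    n = d.shape[0]
    if k is not None and k > n:
        raise InvalidArgumentError("k cannot exceed the number of structures")
    condensed = squareform(np.clip(0.5 * (d + d.T), 0, None), checks=False)
    Z = linkage(condensed, method=method)
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        raise InvalidArgumentError("specify either k or height")
    return ClusteringResult(linkage_matrix=Z, labels=np.asarray(labels),
                            distance_condensed=condensed, method=method)


def radius_of_gyration(s: Structure3D) -> float:
    """Root-mean-square distance of resolved loci from their centroid."""
    coords = s.coords[s.resolved_mask]
    if coords.shape[0] < 2:
        raise UndefinedResultError("radius of gyration needs >= 2 resolved loci")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def ensemble_rg(ensemble) -> np.ndarray:
    """Radius of gyration per structure (NaN where undefined)."""
    structures = getattr(ensemble, "structures", None) or getattr(
        ensemble, "frames", None) or list(ensemble)
    out = np.empty(len(structures))
    for i, s in enumerate(structures):
        try:
            out[i] = radius_of_gyration(s)
        except UndefinedResultError:
            out[i] = np.nan
    return out


@dataclass
class PMFProfile:
    """Histogram-based potential of mean force (kBT units)."""

    bin_centers: np.ndarray
    probability: np.ndarray
    pmf: np.ndarray
    kBT: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "probability": self.probability,
                             "pmf": self.pmf})


def pmf_from_samples(values, bin_width: float = 25.0,
                     kBT: float = 1.0) -> PMFProfile:
    """PMF(x) = -kBT ln P(x) from samples, anchored so the minimum is 0.

    Empty bins have undefined (NaN) PMF.  The default 25-unit bin width
    suits Rg values in nm.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise InvalidArgumentError("need at least one finite sample")
    if bin_width <= 0:
        raise InvalidArgumentError("bin width must be positive")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(v, bins=edges)
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        pmf = np.where(prob > 0, -kBT * np.log(prob), np.nan)
    pmf -= np.nanmin(pmf)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PMFProfile(bin_centers=centers, probability=prob, pmf=pmf, kBT=kBT)


def occupancy_free_energy(n_major: int, n_minor: int, kBT: float = 1.0) -> float:
    """Apparent free-energy gap ln(N_major / N_minor) in kBT.

    For the closed/open dumbbell split this is E_open - E_closed under an
    effective-equilibrium reading of the cluster occupancies.
    """
    if n_major < 1 or n_minor < 1:
        raise UndefinedResultError(
            "both occupancies must be >= 1; with a zero count report a bound "
            "ln(N_major / 1) instead")
    return float(kBT * np.log(n_major / n_minor))
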