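"""Contact maps from ensembles and map comparison utilities.

Two map constructions are supported: the in-silico ligation map
``p_ij = <f(r_ij)>`` (ensemble average of the crosslinking probability) for
simulated ensembles, and the hard-cutoff contact frequency used for traced
microscopy data, where a contact is a pair within 330 nm (2 sigma) and the
denominator of each entry counts only structures with both loci resolved.

Comparisons: Pearson correlation per genomic distance, compartment (A/B)
annotation by the leading eigenvector of the observed/expected correlation
matrix, and correlation between annotation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedResultError
from .michrom import MU, RC
from .structures import TracedEnsemble
from .units import UNIT_REDUCED, contact_cutoff_for


@dataclass
class ContactMap:
    """Symmetric locus x locus map; NaN marks undefined entries."""

    matrix: np.ndarray
    kind: str  # "probability" | "frequency"
    resolution: int = 50_000
    start: int = 0
    n_structures: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidArgumentError("contact map must be square")
        if not np.allclose(m, m.T, equal_nan=True, atol=1e-12):
            raise InvalidArgumentError("contact map must be symmetric")
        if np.nanmin(m, initial=0) < 0 or np.nanmax(m, initial=0) > 1 + 1e-9:
            raise InvalidArgumentError("entries must lie in [0, 1]")
        self.matrix = m

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix).to_csv(path, sep="\t", header=False,
                                         index=False, float_format="%.8g")


@dataclass
class CompartmentProfile:
    """Signed per-locus compartment score; positive = A, negative = B."""

    score: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)

    @property
    def labels(self) -> np.ndarray:
        out = np.where(self.score > 0, "A", "B").astype(object)
        out[~np.isfinite(self.score)] = "NA"
        return out


def _coords_and_units(ensemble):
    """Accept TracedEnsemble or SimEnsemble."""
    if isinstance(ensemble, TracedEnsemble):
        return ensemble.coords_array(), ensemble.units, ensemble.resolution, ensemble.start
    coords = ensemble.coords_array()
    return coords, ensemble.units, 50_000, 0


def probability_map(ensemble, mu: float = MU, rc: float = RC) -> ContactMap:
    """In-silico ligation map: p_ij = mean over frames of f(r_ij).

    Requires reduced units (mu and rc are expressed in sigma).  The diagonal
    is retained as f(0).
    """
    coords, units, resolution, start = _coords_and_units(ensemble)
    if units != UNIT_REDUCED:
        raise InvalidArgumentError("probability_map expects reduced units")
    if coords.shape[0] < 1:
        raise InvalidArgumentError("need at least one frame")
    n = coords.shape[1]
    acc = np.zeros((n, n))
    for frame in coords:
        diff = frame[:, None, :] - frame[None, :, :]
        r = np.sqrt((diff ** 2).sum(-1))
        acc += 0.5 * (1.0 + np.tanh(mu * (rc - r)))
    acc /= coords.shape[0]
    acc = 0.5 * (acc + acc.T)  # exact symmetry against fp noise
    return ContactMap(matrix=acc, kind="probability", resolution=resolution,
                      start=start, n_structures=coords.shape[0])


def cutoff_map(ensemble, cutoff: float | None = None) -> ContactMap:
    """Contact frequency under a hard distance cutoff, missing-aware.

    ``cutoff`` defaults to 330 nm for nm-unit ensembles and 2.0 sigma for
    reduced units.  Entry (i, j) is the fraction of structures in which both
    loci are resolved and r_ij <= cutoff; pairs never co-resolved are NaN.
    """
    coords, units, resolution, start = _coords_and_units(ensemble)
    if cutoff is None:
        cutoff = contact_cutoff_for(units)
    n_s, n = coords.shape[0], coords.shape[1]
    contacts = np.zeros((n, n))
    co_resolved = np.zeros((n, n))
    for frame in coords:
        ok = np.all(np.isfinite(frame), axis=1)
        pair_ok = np.outer(ok, ok)
        safe = np.where(ok[:, None], frame, 0.0)
        diff = safe[:, None, :] - safe[None, :, :]
        r = np.sqrt((diff ** 2).sum(-1))
        contacts += pair_ok & (r <= cutoff)
        co_resolved += pair_ok
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = contacts / co_resolved
    freq[co_resolved == 0] = np.nan
    freq = np.where(np.isnan(freq) & ~np.isnan(freq.T), freq.T, freq)
    return ContactMap(matrix=freq, kind="frequency", resolution=resolution,
                      start=start, n_structures=n_s)


def pearson_by_distance(map_a: ContactMap, map_b: ContactMap) -> pd.DataFrame:
    """Pearson's R across pairs (i, i+d) for each genomic separation d >= 1.

    Distances with fewer than three jointly defined pairs, or zero variance
    on either diagonal, are reported as NaN.
    """
    a, b = map_a.matrix, map_b.matrix
    if a.shape != b.shape:
        raise InvalidArgumentError("maps must have equal shape")
    n = a.shape[0]
    rows = []
    for d in range(1, n):
        va = np.diagonal(a, offset=d)
        vb = np.diagonal(b, offset=d)
        ok = np.isfinite(va) & np.isfinite(vb)
        r = np.nan
        if ok.sum() >= 3:
            x, y = va[ok], vb[ok]
            if x.std() > 0 and y.std() > 0:
                r = float(np.corrcoef(x, y)[0, 1])
        rows.append((d, d * map_a.resolution, r, int(ok.sum())))
    return pd.DataFrame(rows, columns=["distance_loci", "distance_bp",
                                       "pearson_r", "n_pairs"])


def observed_over_expected(matrix: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its (nan-aware) mean; main diagonal excluded."""
    n = matrix.shape[0]
    oe = np.full((n, n), np.nan)
    for d in range(1, n):
        idx = np.arange(n - d)
        vals = matrix[idx, idx + d]
        mean = np.nanmean(vals) if np.any(np.isfinite(vals)) else np.nan
        if np.isfinite(mean) and mean > 0:
            oe[idx, idx + d] = vals / mean
            oe[idx + d, idx] = vals / mean
    return oe


def ab_annotation(cmap: ContactMap,
                  reference_a: np.ndarray | None = None) -> CompartmentProfile:
    """Compartment profile from the leading eigenvector of the O/E correlation.

    The map is normalised per diagonal (observed/expected), converted to a
    Pearson correlation matrix across columns, and the eigenvector of the
    largest eigenvalue is mean-centred to give the signed score.  The sign is
    fixed so the score correlates positively with ``reference_a`` (e.g. an
    A-type fraction per locus) when given, else so the first non-zero entry
    is positive.
    """
    n = cmap.n_loci
    if n < 10:
        raise InvalidArgumentError("ab_annotation needs at least 10 loci")
    oe = observed_over_expected(cmap.matrix)
    finite = oe[np.isfinite(oe)]
    if finite.size == 0 or finite.std() <= 1e-12 * max(1.0, abs(finite.mean())):
        raise UndefinedResultError(
            "degenerate map: observed/expected has no variance")
    # pairwise-complete Pearson correlation between locus profiles
    dfc = pd.DataFrame(oe)
    corr = dfc.corr(min_periods=3).to_numpy()
    if not np.all(np.isfinite(corr)):
        corr = np.nan_to_num(corr, nan=0.0)
    var = np.nanvar(corr, axis=0)
    if np.all(var == 0):
        raise UndefinedResultError("zero-variance correlation matrix")
    w, v = np.linalg.eigh(corr)
    lead = v[:, np.argmax(w)]
    score = lead - lead.mean()
    if reference_a is not None:
        ref = np.asarray(reference_a, dtype=float)
        if np.std(ref) > 0 and np.corrcoef(score, ref)[0, 1] < 0:
            score = -score
    else:
        nz = np.flatnonzero(score)
        if len(nz) and score[nz[0]] < 0:
            score = -score
    return CompartmentProfile(score=score)


def annotation_correlation(profile_a: CompartmentProfile,
                           profile_b: CompartmentProfile) -> float:
    """Pearson correlation of two signed compartment scores (pairwise-complete)."""
    a, b = profile_a.score, profile_b.score
    if len(a) != len(b):
        raise InvalidArgumentError("profiles must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise InvalidArgumentError("need at least 3 jointly defined loci")
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedResultError("zero variance in a profile")
    return float(np.corrcoef(x, y)[0, 1])


def read_map_tsv(path, kind: str = "frequency",
                 resolution: int = 50_000) -> ContactMap:
    m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return ContactMap(matrix=m, kind=kind, resolution=resolution)
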