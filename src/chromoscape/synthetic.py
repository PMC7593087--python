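"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for: blocky chromatin-type sequences; per-mark signal tracks with
type-dependent emission (a stand-in for real ChIP-Seq signal statistics);
loop-anchor lists; and traced ensembles mixing closed-dumbbell,
open-dumbbell and disordered conformers with tracing dropout.  Everything is
bit-reproducible under a fixed seed, and dumbbell ensembles record their
per-structure conformer class so downstream clustering can be scored against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chipseq import (CHROMATIN_TYPES, HISTONE_MARKS, ChromatinTypeSequence,
                      SignalTrack)
from .errors import ConfigurationError, InvalidArgumentError
from .michrom import LoopList, make_loop_list
from .structures import Structure3D, TracedEnsemble
from .units import UNIT_NM


@dataclass
class EmissionModel:
    """Per-(type, mark) location/spread of continuous signal emission.

    Signals are drawn as ``max(0, Normal(location, spread))``; locations
    should sit a few spreads above zero so the clip is immaterial.
    """

    locations: dict[str, dict[str, float]]
    spreads: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for t, per_mark in self.spreads.items():
            for m, s in per_mark.items():
                if s < 0:
                    raise ConfigurationError(f"negative spread for ({t}, {m})")

    def covers(self, types, marks) -> bool:
        return all(t in self.locations and all(m in self.locations[t] for m in marks)
                   for t in types)


#: signature of elevated marks per chromatin type (active marks for A types,
#: repressive marks for B types); values are emission locations.
_HIGH, _MID, _LOW = 6.0, 3.5, 1.5
_SIGNATURE: dict[str, dict[str, float]] = {
    "A1": {"H2AFZ": _HIGH, "H3K27ac": _HIGH, "H3K4me2": _HIGH,
           "H3K4me3": _HIGH, "H3K9ac": _HIGH},
    "A2": {"H3K36me3": _HIGH, "H3K4me1": _HIGH, "H3K79me2": _HIGH,
           "H3K27ac": _MID},
    "B1": {"H3K27me3": _HIGH, "H2AFZ": _MID},
    "B2": {"H3K9me3": _HIGH, "H4K20me1": _MID},
    "B3": {"H3K9me3": _MID},
}


def default_emission_model(spread: float = 0.75) -> EmissionModel:
    """Emission model with a distinct mark signature per chromatin type."""
    locations = {t: {m: _SIGNATURE.get(t, {}).get(m, _LOW) for m in HISTONE_MARKS}
                 for t in CHROMATIN_TYPES}
    spreads = {t: {m: spread for m in HISTONE_MARKS} for t in CHROMATIN_TYPES}
    return EmissionModel(locations=locations, spreads=spreads)


def gen_type_sequence(n_loci: int, mean_block_len: float = 20.0,
                      type_weights: dict[str, float] | None = None,
                      seed: int = 0, resolution: int = 50_000,
                      chrom: str = "chrS") -> ChromatinTypeSequence:
    """Blocky chromatin-type sequence with geometric block lengths.

    Block lengths are Geometric(1/mean_block_len); each new block's type is
    drawn from ``type_weights`` with the previous block's type excluded so
    adjacent blocks differ and the realised mean block length matches the
    nominal one.
    """
    if n_loci < 1:
        raise InvalidArgumentError("n_loci must be >= 1")
    if mean_block_len <= 0:
        raise InvalidArgumentError("mean_block_len must be positive")
    weights = dict(type_weights or {t: 0.2 for t in CHROMATIN_TYPES})
    types = [t for t in CHROMATIN_TYPES if weights.get(t, 0) > 0]
    if not types:
        raise InvalidArgumentError("type_weights must put mass on some type")
    w = np.array([weights[t] for t in types], dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise InvalidArgumentError("type_weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    prev = None
    while len(labels) < n_loci:
        p = w.copy()
        if prev is not None and len(types) > 1:
            p[types.index(prev)] = 0.0
            p /= p.sum()
        t = rng.choice(types, p=p)
        length = rng.geometric(min(1.0, 1.0 / mean_block_len))
        labels.extend([t] * length)
        prev = t
    return ChromatinTypeSequence(labels=np.asarray(labels[:n_loci], dtype=object),
                                 resolution=resolution, chrom=chrom)


def gen_chipseq_tracks(types: ChromatinTypeSequence,
                       model: EmissionModel | None = None,
                       seed: int = 0) -> dict[str, SignalTrack]:
    """One signal track per mark with type-dependent emission.

    Each locus emits ``max(0, Normal(location[type][mark], spread))`` as one
    bedGraph-style interval spanning the locus.
    """
    model = model or default_emission_model()
    marks = HISTONE_MARKS
    present = sorted(set(types.labels.tolist()) - {"NA"})
    if not model.covers(present, marks):
        raise ConfigurationError("emission model does not cover every type present")
    rng = np.random.default_rng(seed)
    n = types.n_loci
    res = types.resolution
    starts = types.start + np.arange(n, dtype=np.int64) * res
    tracks: dict[str, SignalTrack] = {}
    for mark in marks:
        loc = np.array([model.locations[t][mark] if t != "NA" else 0.0
                        for t in types.labels])
        spr = np.array([model.spreads[t][mark] if t != "NA" else 0.0
                        for t in types.labels])
        values = np.maximum(0.0, loc + spr * rng.standard_normal(n))
        tracks[mark] = SignalTrack(chrom=types.chrom or "chrS", starts=starts,
                                   ends=starts + res, values=values,
                                   mark_name=mark)
    return tracks


@dataclass
class GroundTruthEnsemble:
    """Traced ensemble plus per-structure conformer class and generator record."""

    ensemble: TracedEnsemble
    labels: np.ndarray  # "closed" | "open" | "disordered"
    center_distances: np.ndarray  # true head-tail blob centre separation (nm)
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != self.ensemble.n_structures:
            raise InvalidArgumentError("labels must match structure count")


def _blob_walk(n: int, radius: float, rng: np.random.Generator,
               center: np.ndarray) -> np.ndarray:
    """Loci placed by a random walk rejected outside a sphere of ``radius``."""
    step = max(radius / 2.0, 1e-6)
    pts = np.empty((n, 3))
    pos = np.zeros(3)
    for i in range(n):
        for _ in range(100):
            cand = pos + step * rng.standard_normal(3)
            if np.linalg.norm(cand) <= radius:
                pos = cand
                break
        else:
            pos = np.zeros(3)
        pts[i] = pos
    return pts + center


def gen_dumbbell_ensemble(n_structures: int, n_loci: int = 60,
                          head_range: tuple[int, int] = (0, 25),
                          tail_range: tuple[int, int] = (35, 60),
                          open_fraction: float = 0.1,
                          disordered_fraction: float = 0.0,
                          blob_radius: float = 300.0,
                          linker_noise: float = 50.0,
                          missing_rate: float = 0.0,
                          seed: int = 0,
                          resolution: int = 50_000,
                          chrom: str = "chr21") -> GroundTruthEnsemble:
    """Traced ensemble of closed/open dumbbells (nm) with tracing dropout.

    Closed conformers place the head and tail blob centres within 2 x
    blob_radius of each other, open conformers at >= 4 x blob_radius; linker
    loci interpolate between the blobs with isotropic jitter.  Each locus is
    independently missing with ``missing_rate``.
    """
    if n_structures < 1 or n_loci < 2:
        raise InvalidArgumentError("need at least one structure and two loci")
    h0, h1 = head_range
    t0, t1 = tail_range
    if not (0 <= h0 < h1 <= t0 < t1 <= n_loci):
        raise InvalidArgumentError("head/tail ranges must be disjoint, ordered "
                                   "and within [0, n_loci)")
    for p, name in ((open_fraction, "open_fraction"),
                    (disordered_fraction, "disordered_fraction"),
                    (missing_rate, "missing_rate")):
        if not (0 <= p <= 1):
            raise InvalidArgumentError(f"{name} must be a probability")
    if open_fraction + disordered_fraction > 1:
        raise InvalidArgumentError("class fractions exceed 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(["open", "disordered", "closed"], size=n_structures,
                         p=[open_fraction, disordered_fraction,
                            1 - open_fraction - disordered_fraction])
    structures: list[Structure3D] = []
    center_d = np.empty(n_structures)
    for s in range(n_structures):
        coords = np.empty((n_loci, 3))
        cls = classes[s]
        if cls == "disordered":
            coords[:] = _blob_walk(n_loci, 3 * blob_radius, rng, np.zeros(3))
            center_d[s] = np.nan
        else:
            if cls == "closed":
                sep = blob_radius * rng.uniform(1.0, 2.0)
            else:
                sep = blob_radius * rng.uniform(4.0, 6.0)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            head_c = np.zeros(3)
            tail_c = sep * direction
            center_d[s] = sep
            coords[h0:h1] = _blob_walk(h1 - h0, blob_radius, rng, head_c)
            coords[t0:t1] = _blob_walk(t1 - t0, blob_radius, rng, tail_c)
            # linker and flanks: interpolate + isotropic jitter
            a, b = coords[h1 - 1], coords[t0]
            n_link = t0 - h1
            for k in range(n_link):
                frac = (k + 1) / (n_link + 1)
                coords[h1 + k] = (1 - frac) * a + frac * b \
                    + linker_noise * rng.standard_normal(3)
            coords[:h0] = coords[h0] + linker_noise * rng.standard_normal((h0, 3))
            coords[t1:] = coords[t1 - 1] \
                + linker_noise * rng.standard_normal((n_loci - t1, 3))
        if missing_rate > 0:
            drop = rng.random(n_loci) < missing_rate
            coords[drop] = np.nan
        structures.append(Structure3D(coords=coords, units=UNIT_NM,
                                      structure_id=f"s{s:05d}"))
    ensemble = TracedEnsemble(structures=structures, chrom=chrom,
                              resolution=resolution)
    params = dict(n_structures=n_structures, n_loci=n_loci,
                  head_range=head_range, tail_range=tail_range,
                  open_fraction=open_fraction,
                  disordered_fraction=disordered_fraction,
                  blob_radius=blob_radius, linker_noise=linker_noise,
                  missing_rate=missing_rate, seed=seed)
    return GroundTruthEnsemble(ensemble=ensemble, labels=classes,
                               center_distances=center_d,
                               generator_params=params)


def gen_loop_list(anchor_pairs, n_loci: int | None = None) -> LoopList:
    """Validated, deduplicated loop list (thin wrapper over make_loop_list)."""
    return make_loop_list(anchor_pairs, n_loci=n_loci)
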