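"""Histone-mark signal processing and chromatin-type calling.

The front end of the pipeline turns raw ChIP-Seq-like signal tracks into
50-kb binned, 20-state discretized feature vectors and then into per-locus
chromatin-type (sub-compartment) calls over the alphabet A1, A2, B1, B2, B3
(plus NA for masked loci such as centromeres).

The type caller exposes the windowed-argmax interface

    type(l) = argmax_t P(t | states at loci l-2 .. l+2, all marks)

with a pluggable probability model.  The shipped model is a naive-Bayes
factorization over (mark, window offset) fitted from labelled loci; any
model exposing per-(type, mark, offset, state) conditionals can be plugged
in through the same :class:`TypePredictor` container.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: canonical chromatin types, in fixed tie-break order, plus the masked label
CHROMATIN_TYPES = ("A1", "A2", "B1", "B2", "B3")
NA_TYPE = "NA"
TYPE_ALPHABET = CHROMATIN_TYPES + (NA_TYPE,)

#: the 11 histone modification marks used throughout
HISTONE_MARKS = (
    "H2AFZ", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1", "H3K4me2",
    "H3K4me3", "H3K79me2", "H3K9ac", "H3K9me3", "H4K20me1",
)

N_STATES = 20


@dataclass
class SignalTrack:
    """Interval signal for one mark on one chromosome (0-based half-open)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    mark_name: str

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise InvalidArgumentError("starts/ends/values length mismatch")
        if np.any(self.ends <= self.starts):
            raise InvalidArgumentError("intervals must have end > start")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidArgumentError("values must be finite and non-negative")
        order = np.argsort(self.starts, kind="stable")
        if np.any(self.ends[order][:-1] > self.starts[order][1:]):
            raise InvalidArgumentError("intervals overlap within the chromosome")


@dataclass
class BinnedTrack:
    """Per-locus summed signal at fixed resolution."""

    values: np.ndarray
    resolution: int = 50_000
    chrom: str = ""
    mark_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise InvalidArgumentError("binned values must be finite, >= 0")


@dataclass
class DiscretizedTracks:
    """Loci x marks matrix of integer signal states in 1..20."""

    states: np.ndarray
    marks: tuple[str, ...]
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.marks):
            raise InvalidArgumentError("states must be (loci, marks)")
        if self.states.min(initial=1) < 1 or self.states.max(initial=1) > N_STATES:
            raise InvalidArgumentError("states must lie in 1..20")

    @property
    def n_loci(self) -> int:
        return self.states.shape[0]


@dataclass
class ChromatinTypeSequence:
    """Per-50-kb-locus chromatin-type labels."""

    labels: np.ndarray
    resolution: int = 50_000
    chrom: str = ""
    start: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        bad = set(labels.tolist()) - set(TYPE_ALPHABET)
        if bad:
            raise InvalidArgumentError(f"unknown chromatin-type labels {bad}")
        self.labels = labels

    @property
    def n_loci(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TypePredictor:
    """Windowed conditional model for chromatin-type calling.

    ``log_cond[t, m, o, s]`` is log P(state s+1 | type t, mark m, offset
    o - window_halfwidth); ``log_prior[t]`` the log prior of type t.
    """

    marks: tuple[str, ...]
    log_cond: np.ndarray
    log_prior: np.ndarray
    window_halfwidth: int = 2

    def __post_init__(self) -> None:
        n_off = 2 * self.window_halfwidth + 1
        expected = (len(CHROMATIN_TYPES), len(self.marks), n_off, N_STATES)
        if self.log_cond.shape != expected:
            raise ConfigurationError(
                f"log_cond shape {self.log_cond.shape} != {expected}")
        # conditionals and prior must be normalised distributions
        if not np.allclose(np.exp(self.log_cond).sum(axis=-1), 1.0, atol=1e-8):
            raise ConfigurationError("conditional tables must normalise over states")
        if not np.isclose(np.exp(self.log_prior).sum(), 1.0, atol=1e-8):
            raise ConfigurationError("prior must normalise over types")

    def to_json(self, path) -> None:
        payload = {
            "marks": list(self.marks),
            "window_halfwidth": self.window_halfwidth,
            "prior": np.exp(self.log_prior).tolist(),
            "conditionals": np.exp(self.log_cond).tolist(),
            "types": list(CHROMATIN_TYPES),
            "n_states": N_STATES,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TypePredictor":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(marks=tuple(payload["marks"]),
                   log_cond=np.log(np.asarray(payload["conditionals"])),
                   log_prior=np.log(np.asarray(payload["prior"])),
                   window_halfwidth=int(payload["window_halfwidth"]))


# ---------------------------------------------------------------------------
# bedGraph / text IO


def read_bedgraph(path, mark_name: str, chrom: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise FormatError("bedGraph must cover exactly one chromosome per track")
    return SignalTrack(chrom=str(chroms[0]), starts=df["start"].to_numpy(),
                       ends=df["end"].to_numpy(), values=df["value"].to_numpy(),
                       mark_name=mark_name)


def write_bedgraph(track: SignalTrack, path) -> None:
    pd.DataFrame({"chrom": track.chrom, "start": track.starts,
                  "end": track.ends, "value": track.values}
                 ).to_csv(path, sep="\t", header=False, index=False)


def read_type_sequence(path, resolution: int = 50_000,
                       chrom: str = "") -> ChromatinTypeSequence:
    """Read a two-column (locus start bp, label) text file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["start", "label"])
    start = int(df["start"].iloc[0]) if len(df) else 0
    return ChromatinTypeSequence(labels=df["label"].to_numpy(dtype=object),
                                 resolution=resolution, chrom=chrom, start=start)


def write_type_sequence(seq: ChromatinTypeSequence, path) -> None:
    starts = seq.start + np.arange(seq.n_loci) * seq.resolution
    pd.DataFrame({"start": starts, "label": seq.labels}
                 ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# binning and discretization


def bin_signal(track: SignalTrack, resolution: int = 50_000,
               chrom_length: int | None = None) -> BinnedTrack:
    """Sum interval signal into fixed-width bins.

    Each interval contributes value * (overlap length / interval length) to
    every bin it intersects, so the total signal is conserved under binning.
    """
    if resolution <= 0:
        raise InvalidArgumentError("resolution must be positive")
    if chrom_length is None:
        chrom_length = int(track.ends.max()) if len(track.ends) else resolution
    if len(track.ends) and track.ends.max() > chrom_length:
        raise FormatError("interval extends beyond chrom_length")
    if len(track.starts) and track.starts.min() < 0:
        raise FormatError("interval start below 0")
    n_bins = -(-chrom_length // resolution)
    values = np.zeros(n_bins)
    for s, e, v in zip(track.starts, track.ends, track.values):
        length = e - s
        b0, b1 = s // resolution, (e - 1) // resolution
        for b in range(b0, b1 + 1):
            lo = max(s, b * resolution)
            hi = min(e, (b + 1) * resolution)
            values[b] += v * (hi - lo) / length
    return BinnedTrack(values=values, resolution=resolution,
                       chrom=track.chrom, mark_name=track.mark_name)


def discretize(binned: dict[str, BinnedTrack]) -> DiscretizedTracks:
    """Map pooled binned signal to 20 discrete states per mark.

    The top 5% of loci by signal (k = ceil(0.05 n), ties included) get state
    20; the remaining signal range [min, q) is partitioned into 19
    equal-width intervals mapped to states 1..19 by value.  Pool all loci of
    all chromosomes of one cell type into a single call for the intended
    percentile scope.
    """
    if not binned:
        raise InvalidArgumentError("at least one mark required")
    marks = tuple(binned.keys())
    n_loci = len(next(iter(binned.values())).values)
    if n_loci < N_STATES:
        raise InvalidArgumentError("need at least 20 loci to discretize")
    states = np.empty((n_loci, len(marks)), dtype=np.int64)
    thresholds: dict[str, np.ndarray] = {}
    k = -(-n_loci * 5 // 100)  # ceil(0.05 n)
    for m, mark in enumerate(marks):
        v = binned[mark].values
        if len(v) != n_loci:
            raise InvalidArgumentError("all marks must cover the same loci")
        q = np.sort(v)[n_loci - k]  # k-th largest value
        lo = v.min()
        if q <= lo:
            warnings.warn(f"mark {mark}: degenerate signal, all loci in top 5%")
            states[:, m] = N_STATES
            thresholds[mark] = np.array([lo, q])
            continue
        width = (q - lo) / (N_STATES - 1)
        s = np.floor((v - lo) / width).astype(np.int64) + 1
        s = np.clip(s, 1, N_STATES - 1)
        s[v >= q] = N_STATES
        states[:, m] = s
        thresholds[mark] = np.concatenate([lo + width * np.arange(N_STATES - 1), [q]])
    return DiscretizedTracks(states=states, marks=marks, thresholds=thresholds)


# ---------------------------------------------------------------------------
# surrogate predictor


def fit_surrogate_predictor(discretized: DiscretizedTracks,
                            labels: ChromatinTypeSequence,
                            pseudocount: float = 1.0,
                            window_halfwidth: int = 2) -> TypePredictor:
    """Fit the naive-Bayes windowed model from labelled loci.

    Conditionals are pseudocount-smoothed empirical state frequencies per
    (type, mark, offset); the prior is the smoothed label frequency.  NA loci
    are excluded from fitting.
    """
    if labels.n_loci != discretized.n_loci:
        raise InvalidArgumentError("labels must align with discretized loci")
    n_types, n_marks = len(CHROMATIN_TYPES), len(discretized.marks)
    n_off = 2 * window_halfwidth + 1
    counts = np.zeros((n_types, n_marks, n_off, N_STATES))
    prior_counts = np.zeros(n_types)
    states0 = discretized.states - 1
    n = discretized.n_loci
    for t, tname in enumerate(CHROMATIN_TYPES):
        loci = np.where(labels.labels == tname)[0]
        prior_counts[t] = len(loci)
        if len(loci) == 0:
            warnings.warn(f"type {tname} absent from labels; uniform tables used")
            continue
        for o in range(-window_halfwidth, window_halfwidth + 1):
            src = loci + o
            ok = (src >= 0) & (src < n)
            sts = states0[src[ok]]  # (n_ok, marks)
            for m in range(n_marks):
                counts[t, m, o + window_halfwidth] += np.bincount(
                    sts[:, m], minlength=N_STATES)
    cond = counts + pseudocount
    cond /= cond.sum(axis=-1, keepdims=True)
    prior = prior_counts + pseudocount
    prior /= prior.sum()
    return TypePredictor(marks=discretized.marks, log_cond=np.log(cond),
                         log_prior=np.log(prior),
                         window_halfwidth=window_halfwidth)


def predict_types(predictor: TypePredictor, discretized: DiscretizedTracks,
                  na_mask: np.ndarray | None = None,
                  resolution: int = 50_000, chrom: str = "",
                  start: int = 0) -> ChromatinTypeSequence:
    """Call a chromatin type per locus by windowed argmax.

    Each locus l is scored per type by log prior + sum over marks and window
    offsets -w..+w of the log conditional of the observed state at l+offset;
    the window is truncated at chromosome ends.  Ties break to the lowest
    type in the fixed order A1 < A2 < B1 < B2 < B3.  Loci under ``na_mask``
    are labelled NA and excluded from scoring.
    """
    if predictor.marks != discretized.marks:
        raise ConfigurationError("predictor and data must share marks/ordering")
    w = predictor.window_halfwidth
    n = discretized.n_loci
    states0 = discretized.states - 1
    scores = np.tile(predictor.log_prior[:, None], (1, n))
    for o in range(-w, w + 1):
        src = np.arange(n) + o
        ok = (src >= 0) & (src < n)
        sts = states0[src[ok]]  # (n_ok, marks)
        for m in range(len(predictor.marks)):
            scores[:, ok] += predictor.log_cond[:, m, o + w, :][:, sts[:, m]]
    best = np.argmax(scores, axis=0)  # argmax returns first max: fixed-order ties
    n_ties = int(np.sum((scores == scores[best, np.arange(n)]).sum(axis=0) > 1))
    if n_ties:
        logger.info("predict_types: %d tied loci broken to lowest type", n_ties)
    labels = np.asarray(CHROMATIN_TYPES, dtype=object)[best]
    if na_mask is not None:
        labels[np.asarray(na_mask, dtype=bool)] = NA_TYPE
    return ChromatinTypeSequence(labels=labels, resolution=resolution,
                                 chrom=chrom, start=start)


def type_frequency_profile(annotations: list[ChromatinTypeSequence]) -> pd.DataFrame:
    """Per-locus frequency of each label across a set of annotations.

    Rows (loci) sum to 1 over the six-letter alphabet; this is the stacked
    per-locus type-distribution profile used to compare cell types.
    """
    if not annotations:
        raise InvalidArgumentError("need at least one annotation")
    n = annotations[0].n_loci
    if any(a.n_loci != n for a in annotations):
        raise InvalidArgumentError("annotations must share locus count")
    freq = np.zeros((n, len(TYPE_ALPHABET)))
    for a in annotations:
        for t, tname in enumerate(TYPE_ALPHABET):
            freq[:, t] += a.labels == tname
    freq /= len(annotations)
    return pd.DataFrame(freq, columns=list(TYPE_ALPHABET))
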