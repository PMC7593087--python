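"""In-memory containers for 3D chromatin structures.

A :class:`Structure3D` is one conformation of a chromatin segment: one 3D
point per genomic locus, with unresolved (missing) loci stored as NaN rows.
A :class:`TracedEnsemble` bundles many conformations of the same segment
together with the genomic interval they cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .units import VALID_UNITS


@dataclass
class Structure3D:
    """A single conformation: ``coords`` is (n_loci, 3), NaN where missing.

    A locus counts as resolved only when all three coordinates are finite;
    rows with any non-finite entry are normalised to all-NaN on construction.
    """

    coords: np.ndarray
    units: str
    structure_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidArgumentError(f"coords must be (n,3); got {coords.shape}")
        if self.units not in VALID_UNITS:
            raise InvalidArgumentError(f"units must be one of {VALID_UNITS}")
        coords = coords.copy()
        bad = ~np.all(np.isfinite(coords), axis=1)
        coords[bad] = np.nan
        self.coords = coords

    @property
    def n_loci(self) -> int:
        return self.coords.shape[0]

    @property
    def resolved_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.coords), axis=1)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~self.resolved_mask

    @property
    def resolved_fraction(self) -> float:
        return float(self.resolved_mask.mean())

    def with_coords(self, coords: np.ndarray, units: str | None = None) -> "Structure3D":
        return Structure3D(coords=coords, units=units or self.units,
                           structure_id=self.structure_id)


@dataclass
class TracedEnsemble:
    """Conformations of one genomic segment (0-based half-open, hg19 default)."""

    structures: list[Structure3D]
    chrom: str = "chr21"
    start: int = 0
    end: int = 0
    resolution: int = 50_000
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise InvalidArgumentError("resolution must be positive")
        if self.structures:
            n = self.structures[0].n_loci
            for s in self.structures:
                if s.n_loci != n:
                    raise InvalidArgumentError("all structures must share n_loci")
            if self.end <= self.start:
                # fill genomic extent from the locus count when not provided
                self.end = self.start + n * self.resolution
            if (self.end - self.start) != n * self.resolution:
                raise InvalidArgumentError(
                    "genomic extent inconsistent with locus count and resolution")

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def n_loci(self) -> int:
        return self.structures[0].n_loci if self.structures else 0

    @property
    def units(self) -> str:
        return self.structures[0].units if self.structures else "nm"

    def coords_array(self) -> np.ndarray:
        """Stacked (n_structures, n_loci, 3) coordinates, NaN where missing."""
        return np.stack([s.coords for s in self.structures])

    def replace_structures(self, structures: list[Structure3D]) -> "TracedEnsemble":
        return TracedEnsemble(structures=structures, chrom=self.chrom,
                              start=self.start, end=self.end,
                              resolution=self.resolution, assembly=self.assembly)
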