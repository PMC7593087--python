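"""Read, filter, convert and write traced-structure ensembles.

Microscopy DNA-tracing datasets ship as long-format CSV tables: one row per
(cell, locus) with a structure id, a segment index and x/y/z positions in nm,
where unresolved loci appear as blank or non-finite entries.  A
:class:`CsvDialect` maps those columns onto the package's data model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InvalidArgumentError
from .structures import Structure3D, TracedEnsemble
from .units import NM_PER_REDUCED, UNIT_NM, UNIT_REDUCED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for a long-format traced-structure CSV.

    ``index_base`` is the base of the locus (segment) index column in the
    file; deposited tracing tables commonly count segments from 1, while the
    package uses 0-based indices internally.
    """

    structure_col: str = "Chromosome index"
    locus_col: str = "Segment index"
    x_col: str = "X"
    y_col: str = "Y"
    z_col: str = "Z"
    delimiter: str = ","
    index_base: int = 1
    units: str = UNIT_NM

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.structure_col, self.locus_col,
                self.x_col, self.y_col, self.z_col)


def read_traced_csv(path, dialect: CsvDialect = CsvDialect(), *,
                    chrom: str = "chr21", start: int = 0,
                    resolution: int = 50_000,
                    n_loci: int | None = None) -> TracedEnsemble:
    """Parse a long-format CSV into a :class:`TracedEnsemble`.

    Structures keep their source order and source ids; locus indices are
    shifted to 0-based; rows with blank or non-finite coordinates become
    missing loci, as do loci absent from the file entirely.
    """
    df = pd.read_csv(path, sep=dialect.delimiter)
    missing_cols = [c for c in dialect.required_columns if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"dialect names columns {missing_cols} not present in {path}; "
            f"file has {list(df.columns)}")
    if df.duplicated(subset=[dialect.structure_col, dialect.locus_col]).any():
        raise FormatError(f"duplicate (structure, locus) rows in {path}")

    loci = pd.to_numeric(df[dialect.locus_col], errors="raise").astype(int)
    loci = loci - dialect.index_base
    if (loci < 0).any():
        raise FormatError("locus index below declared index_base")
    if n_loci is None:
        n_loci = int(loci.max()) + 1
    elif int(loci.max()) >= n_loci:
        raise FormatError("locus index beyond declared n_loci")

    xyz = df[[dialect.x_col, dialect.y_col, dialect.z_col]].apply(
        pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    structures: list[Structure3D] = []
    # preserve source order of first appearance
    for sid, idx in df.groupby(dialect.structure_col, sort=False).indices.items():
        coords = np.full((n_loci, 3), np.nan)
        coords[loci.iloc[idx].to_numpy()] = xyz[idx]
        structures.append(Structure3D(coords=coords, units=dialect.units,
                                      structure_id=str(sid)))
    return TracedEnsemble(structures=structures, chrom=chrom, start=start,
                          end=start + n_loci * resolution, resolution=resolution)


def write_traced_csv(ensemble: TracedEnsemble, path,
                     dialect: CsvDialect = CsvDialect()) -> None:
    """Emit the same long-format dialect ``read_traced_csv`` accepts.

    Missing loci are written with blank coordinate fields so a round trip
    preserves the missing mask exactly.
    """
    rows = []
    for s in ensemble.structures:
        for i in range(s.n_loci):
            x, y, z = s.coords[i]
            rows.append((s.structure_id, i + dialect.index_base, x, y, z))
    df = pd.DataFrame(rows, columns=[dialect.structure_col, dialect.locus_col,
                                     dialect.x_col, dialect.y_col, dialect.z_col])
    df.to_csv(path, sep=dialect.delimiter, index=False, na_rep="")


def filter_usable(ensemble: TracedEnsemble,
                  min_resolved_fraction: float = 0.9) -> TracedEnsemble:
    """Keep structures whose resolved fraction is strictly above the threshold.

    The default reproduces the "over 90% of loci resolved" usability rule for
    traced structures: a structure at exactly 90.0% is dropped.
    """
    if not (0 < min_resolved_fraction <= 1):
        raise InvalidArgumentError("min_resolved_fraction must be in (0, 1]")
    if not ensemble.structures:
        warnings.warn("filter_usable called on an empty ensemble")
        return ensemble
    kept = [s for s in ensemble.structures
            if s.resolved_fraction > min_resolved_fraction]
    logger.info("filter_usable: kept %d of %d structures (> %.1f%% resolved)",
                len(kept), ensemble.n_structures, 100 * min_resolved_fraction)
    return ensemble.replace_structures(kept)


def convert_units(obj, scale: float = NM_PER_REDUCED):
    """Convert a structure or ensemble between nm and reduced units.

    ``scale`` is the length of one reduced unit in nm (default 165 nm, the
    0.165-um calibration).  Converting to the unit already tagged is a no-op
    with a warning.
    """
    if scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    if isinstance(obj, TracedEnsemble):
        return obj.replace_structures([convert_units(s, scale)
                                       for s in obj.structures])
    if not isinstance(obj, Structure3D):
        raise InvalidArgumentError("expected Structure3D or TracedEnsemble")
    if obj.units == UNIT_NM:
        return obj.with_coords(obj.coords / scale, units=UNIT_REDUCED)
    if obj.units == UNIT_REDUCED:
        return obj.with_coords(obj.coords * scale, units=UNIT_NM)
    raise InvalidArgumentError(f"unknown unit tag {obj.units!r}")


def to_units(obj, target: str, scale: float = NM_PER_REDUCED):
    """Convert only if needed; warns (and returns input) when already there."""
    units = obj.units
    if units == target:
        warnings.warn(f"already in {target}; conversion is a no-op")
        return obj
    return convert_units(obj, scale)
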