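"""Unit conventions.

Coordinates are tagged either ``nm`` (microscopy traces) or ``reduced``
(simulation, monomer diameter sigma = 1).  One sigma corresponds to 0.165 um,
the length calibration obtained from FISH; the same length sets the
resolution scale delta of the Q order parameter and makes the 330-nm trace
contact cutoff exactly 2 sigma.
"""

UNIT_NM = "nm"
UNIT_REDUCED = "reduced"

#: nm per reduced length unit (sigma); 0.165 um FISH calibration.
NM_PER_REDUCED = 165.0

#: Q resolution length scale, 0.165 um, expressed in each unit system.
Q_DELTA_NM = 165.0
Q_DELTA_REDUCED = 1.0

#: distance defining a contact between two traced loci.
TRACE_CONTACT_CUTOFF_NM = 330.0
TRACE_CONTACT_CUTOFF_REDUCED = TRACE_CONTACT_CUTOFF_NM / NM_PER_REDUCED

VALID_UNITS = (UNIT_NM, UNIT_REDUCED)


def q_delta_for(units: str) -> float:
    """Default Q resolution length for a unit system."""
    if units == UNIT_NM:
        return Q_DELTA_NM
    if units == UNIT_REDUCED:
        return Q_DELTA_REDUCED
    raise ValueError(f"unknown unit tag {units!r}")


def contact_cutoff_for(units: str) -> float:
    """Default trace contact cutoff for a unit system."""
    if units == UNIT_NM:
        return TRACE_CONTACT_CUTOFF_NM
    if units == UNIT_REDUCED:
        return TRACE_CONTACT_CUTOFF_REDUCED
    raise ValueError(f"unknown unit tag {units!r}")
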