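"""The minimal chromatin model (MiChroM) energy function.

A chromosome is a chain of 50-kb monomers in reduced units (length sigma,
energy epsilon, kB = 1).  The potential is a sum of

* a homopolymer backbone (bonds, angles, soft-core excluded volume),
* type-to-type contact interactions ``alpha_kl * f(r_ij)`` between loci of
  chromatin types k, l in {A1, A2, B1, B2, B3} (NA loci are inert here),
* CTCF-loop anchors ``chi * f(r_ij)`` for listed pairs,
* the ideal-chromosome term ``gamma(d) * f(r_{i,i+d})`` for genomic
  separations d = 3..500, capturing lengthwise compaction,
* a half-harmonic spherical wall preserving a chromatin volume fraction.

``f`` is the crosslinking probability ``f(r) = (1 + tanh(mu (rc - r))) / 2``
with mu = 3.22, rc = 1.78.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .chipseq import CHROMATIN_TYPES
from .errors import InvalidArgumentError
from .structures import Structure3D

CHI_LOOP = -1.612990
GAMMA_COEFFS = (-0.030, -0.351, -3.727)
MU = 3.22
RC = 1.78


@dataclass(frozen=True)
class LoopList:
    """Validated, deduplicated list of loop-anchor pairs (i < j, 0-based)."""

    pairs: tuple[tuple[int, int], ...] = ()

    def __len__(self) -> int:
        return len(self.pairs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)


def make_loop_list(anchor_pairs, n_loci: int | None = None) -> LoopList:
    """Validate and deduplicate anchor pairs; each pair must satisfy i < j."""
    seen = []
    for i, j in anchor_pairs:
        i, j = int(i), int(j)
        if i >= j:
            raise InvalidArgumentError(f"loop pair ({i},{j}) must have i < j")
        if i < 0 or (n_loci is not None and j >= n_loci):
            raise InvalidArgumentError(f"loop pair ({i},{j}) out of range")
        if (i, j) not in seen:
            seen.append((i, j))
    return LoopList(pairs=tuple(seen))


@dataclass
class MiChroMParams:
    """Every knob of the energy function.

    ``alpha`` maps unordered type pairs to interaction strengths in epsilon,
    e.g. ``{("A1", "B3"): -0.27, ...}``.  Homopolymer and wall constants are
    package configuration choices, not fitted quantities.
    """

    alpha: dict[tuple[str, str], float]
    chi: float = CHI_LOOP
    gamma_coeffs: tuple[float, float, float] = GAMMA_COEFFS
    mu: float = MU
    rc: float = RC
    d_min: int = 3
    d_max: int = 500
    cutoff: float = 3.0
    include_loops: bool = True
    # homopolymer configuration
    bond_k: float = 300.0
    bond_r0: float = 1.0
    angle_k: float = 2.0
    rep_e: float = 20.0
    rep_r0: float = 1.0
    wall_k: float = 80.0

    def __post_init__(self) -> None:
        if self.d_min < 2:
            raise InvalidArgumentError("d_min must be >= 2")
        if self.cutoff <= self.rc:
            raise InvalidArgumentError("cutoff must exceed rc")
        # symmetrize the alpha table
        sym: dict[tuple[str, str], float] = {}
        for (a, b), v in self.alpha.items():
            if (b, a) in self.alpha and not np.isclose(self.alpha[(b, a)], v):
                raise InvalidArgumentError(f"alpha not symmetric at ({a},{b})")
            sym[(a, b)] = sym[(b, a)] = float(v)
        self.alpha = sym

    def alpha_matrix(self) -> np.ndarray:
        m = np.zeros((len(CHROMATIN_TYPES), len(CHROMATIN_TYPES)))
        for i, a in enumerate(CHROMATIN_TYPES):
            for j, b in enumerate(CHROMATIN_TYPES):
                m[i, j] = self.alpha.get((a, b), 0.0)
        return m

    def gamma_table(self) -> np.ndarray:
        """gamma(d) for d = 0..d_max (zero outside [d_min, d_max])."""
        tab = np.zeros(self.d_max + 1)
        d = np.arange(self.d_min, self.d_max + 1)
        tab[self.d_min:] = gamma_of_d(d, *self.gamma_coeffs)
        return tab


def contact_function(r, mu: float = MU, rc: float = RC):
    """Crosslinking probability f(r) = (1 + tanh(mu (rc - r))) / 2.

    Strictly decreasing in r, bounded in (0, 1), with f(rc) = 1/2 exactly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidArgumentError("distances must be non-negative")
    out = 0.5 * (1.0 + np.tanh(mu * (rc - r)))
    return float(out) if out.ndim == 0 else out


def gamma_of_d(d, gamma1: float = GAMMA_COEFFS[0], gamma2: float = GAMMA_COEFFS[1],
               gamma3: float = GAMMA_COEFFS[2]):
    """Ideal-chromosome coupling gamma(d) = g1/ln(d) + g2/d + g3/d^2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 2):
        raise InvalidArgumentError("gamma(d) is defined for d >= 2")
    out = gamma1 / np.log(d) + gamma2 / d + gamma3 / d ** 2
    return float(out) if out.ndim == 0 else out


def confinement_radius(n_loci: int, volume_fraction: float = 0.1,
                       monomer_radius: float = 0.5) -> float:
    """Territory radius such that monomers occupy ``volume_fraction`` of it."""
    if not (0 < volume_fraction < 1) and volume_fraction != 1:
        raise InvalidArgumentError("volume_fraction must be in (0, 1]")
    if n_loci < 1:
        raise InvalidArgumentError("n_loci must be >= 1")
    return monomer_radius * (n_loci / volume_fraction) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# energy evaluation (vectorised; the dynamics kernel has its own fused loops)


def types_to_indices(type_labels) -> np.ndarray:
    """Map labels to 0..4 (NA and unknown -> -1, inert in type-type term)."""
    lookup = {t: i for i, t in enumerate(CHROMATIN_TYPES)}
    return np.asarray([lookup.get(t, -1) for t in type_labels], dtype=np.int64)


def energy(state: Structure3D, type_labels, loops: LoopList | None,
           params: MiChroMParams,
           confinement_radius_sigma: float | None = None) -> dict[str, float]:
    """Per-term potential energy of one conformation (reduced units).

    Returns a dict with keys ``homopolymer``, ``type_type``, ``loops``,
    ``ideal``, ``confinement`` and ``total``.  Pairwise f-terms apply for
    genomic separation >= d_min within the distance cutoff; NA loci are
    excluded from the type-type term only.
    """
    x = np.asarray(state.coords, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("energy requires a fully resolved state")
    n = x.shape[0]
    tidx = types_to_indices(type_labels)
    if len(tidx) != n:
        raise InvalidArgumentError("types length must equal locus count")

    diff = x[:, None, :] - x[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    iu, ju = np.triu_indices(n, k=1)
    d = ju - iu
    rij = r[iu, ju]
    f = 0.5 * (1.0 + np.tanh(params.mu * (params.rc - rij)))

    # homopolymer: bonds, angles, capped soft-core repulsion
    bond_r = r[np.arange(n - 1), np.arange(1, n)]
    e_bond = 0.5 * params.bond_k * ((bond_r - params.bond_r0) ** 2).sum()
    e_angle = 0.0
    if n >= 3:
        b = x[1:] - x[:-1]
        bn = b / np.linalg.norm(b, axis=1, keepdims=True)
        cosphi = (bn[:-1] * bn[1:]).sum(1)
        e_angle = params.angle_k * (1.0 - cosphi).sum()
    rep_mask = (d >= 2) & (rij < params.rep_r0)
    e_rep = (params.rep_e * (1.0 - rij[rep_mask] / params.rep_r0) ** 2).sum()
    e_hp = float(e_bond + e_angle + e_rep)

    within = rij <= params.cutoff
    far_enough = d >= params.d_min

    both_typed = (tidx[iu] >= 0) & (tidx[ju] >= 0)
    sel = within & far_enough & both_typed
    amat = params.alpha_matrix()
    e_tt = float((amat[tidx[iu[sel]], tidx[ju[sel]]] * f[sel]).sum())

    gam = params.gamma_table()
    sel_i = within & (d >= params.d_min) & (d <= params.d_max)
    e_ideal = float((gam[d[sel_i]] * f[sel_i]).sum())

    e_loops = 0.0
    if params.include_loops and loops is not None and len(loops):
        lp = loops.as_array()
        rl = r[lp[:, 0], lp[:, 1]]
        e_loops = float((params.chi *
                         0.5 * (1.0 + np.tanh(params.mu * (params.rc - rl)))).sum())

    e_conf = 0.0
    if confinement_radius_sigma is not None:
        rad = np.linalg.norm(x, axis=1)
        over = np.maximum(rad - confinement_radius_sigma, 0.0)
        e_conf = float(0.5 * params.wall_k * (over ** 2).sum())

    terms = {"homopolymer": e_hp, "type_type": e_tt, "loops": e_loops,
             "ideal": e_ideal, "confinement": e_conf}
    terms["total"] = sum(terms.values())
    return terms


# ---------------------------------------------------------------------------
# alpha tables


def toy_alpha(a_a: float = -0.10, a_b: float = -0.10,
              b_b: float = -0.40) -> dict[tuple[str, str], float]:
    """Small two-scale interaction table for tests and reduced-scale studies.

    B-B contacts are the most favourable, A-A and A-B comparable and weaker,
    matching the stated ordering of the trained model.
    """
    a_types = ("A1", "A2")
    b_types = ("B1", "B2", "B3")
    tab: dict[tuple[str, str], float] = {}
    for i, t1 in enumerate(CHROMATIN_TYPES):
        for t2 in CHROMATIN_TYPES[i:]:
            if t1 in a_types and t2 in a_types:
                tab[(t1, t2)] = a_a
            elif t1 in b_types and t2 in b_types:
                tab[(t1, t2)] = b_b
            else:
                tab[(t1, t2)] = a_b
    return tab


def load_default_alpha() -> dict[tuple[str, str], float]:
    """Load the shipped default type-type table.

    The shipped table is synthetic: the trained per-pair values are not
    reproduced here, so the file encodes a constructed set honouring the
    known ordering (B-B strongest, A-A and A-B comparable and weaker).
    """
    path = resources.files("chromoscape") / "data" / "alpha_synthetic.json"
    payload = json.loads(path.read_text())
    return {tuple(k.split("-")): v for k, v in payload["alpha"].items()}


def default_params(alpha: dict | None = None, **overrides) -> MiChroMParams:
    """MiChroMParams with the shipped (synthetic) alpha table by default."""
    return MiChroMParams(alpha=alpha or load_default_alpha(), **overrides)
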