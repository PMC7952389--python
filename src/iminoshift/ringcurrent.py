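"""Johnson-Bovey ring-current shielding for RNA imino nuclei.

The model represents each aromatic ring as a pair of circular current loops
at +/- zbar above and below the base plane.  The shielding at an observation
point is

    sigma_rc = sum_j  i_j * B_j * G_j(r)

over all contributing rings j, where i_j is the dimensionless ring-current
intensity relative to benzene, B_j = 3 e^2 / (6 pi m_e a_j c^2) is the
single-ring shielding amplitude (evaluated in CGS-Gaussian units so that
sigma is dimensionless), and G_j is the loop-pair geometry factor expressed
through complete elliptic integrals of the cylindrical coordinates
(rho, z) of the point, measured as ratios to the ring radius a_j.  The
chemical-shift contribution follows as delta = -sigma * 1e6 ppm.

Six ring classes are distinguished (Gua-5, Gua-6, Ade-5, Ade-6, Cyt, Ura).
Two intensity sets are shipped: the proton set ("DC-H") and a 15N set
("calibrated-N") obtained by least-squares calibration against an
experimental base-pair triplet shift table; :func:`calibrate_intensity_factors`
re-runs that calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.special import ellipe, ellipk

from .structure import (
    RING_RADII,
    RingGeometry,
    place_imino_proton,
    ring_geometry,
    ring_ids_for_base,
)

__all__ = [
    "RCParameters",
    "ShiftContribution",
    "geometry_factor",
    "b_factor",
    "ring_rc_shift",
    "rc_shift_at_nucleus",
    "rc_design_row",
    "calibrate_intensity_factors",
    "RING_IDS",
]

# CGS-Gaussian constants for the B factor
E_ESU = 4.8032e-10      # elementary charge, esu
M_E_G = 9.1094e-28      # electron mass, g
C_CM_S = 2.9979e10      # speed of light, cm/s

RING_IDS = ("Gua-5", "Gua-6", "Ade-5", "Ade-6", "Cyt", "Ura")

#: ring radius class per ring identifier
_RING_KIND = {
    "Gua-5": "purine5", "Gua-6": "purine6",
    "Ade-5": "purine5", "Ade-6": "purine6",
    "Cyt": "pyrimidine", "Ura": "pyrimidine",
}


def _load_shipped():
    with resources.files("iminoshift.data").joinpath("rc_intensity.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class RCParameters:
    """Ring-current model parameters.

    Attributes
    ----------
    intensity : dict
        ``{"H": {ring_id: i_j}, "N": {ring_id: i_j}}``.
    radii : dict
        A per ring kind (six-membered 1.39, five-membered 1.182).
    zbar : float
        Loop separation from the base plane, A (default 0.64).
    """

    intensity: dict
    radii: dict = field(default_factory=lambda: dict(RING_RADII))
    zbar: float = 0.64

    @classmethod
    def default(cls):
        """Proton intensities from the DC set; calibrated 15N intensities."""
        data = _load_shipped()
        return cls(
            intensity={"H": dict(data["sets"]["DC-H"]),
                       "N": dict(data["sets"]["calibrated-N"])},
            zbar=float(data["zbar_angstrom"]),
        )

    @classmethod
    def from_json(cls, path):
        """Load a user parameter file with the same layout as the shipped one."""
        with open(path) as fh:
            data = json.load(fh)
        sets = data["sets"]
        hk = "DC-H" if "DC-H" in sets else "H"
        nk = "calibrated-N" if "calibrated-N" in sets else "N"
        return cls(intensity={"H": dict(sets[hk]), "N": dict(sets[nk])},
                   zbar=float(data.get("zbar_angstrom", 0.64)))

    def with_intensities(self, nucleus_class, factors):
        new = dict(self.intensity)
        new[nucleus_class] = dict(factors)
        return replace(self, intensity=new)

    def intensity_for(self, ring_id, nucleus_class):
        try:
            per_class = self.intensity[nucleus_class]
        except KeyError:
            raise KeyError(f"no intensity set for nucleus class {nucleus_class!r}") from None
        try:
            return per_class[ring_id]
        except KeyError:
            raise KeyError(f"unknown ring identifier {ring_id!r}") from None

    def radius_for(self, ring_id):
        return self.radii[_RING_KIND[ring_id]]


@dataclass(frozen=True)
class ShiftContribution:
    """Shielding of one source (ring or charge group) and its shift in ppm."""

    sigma: float
    source: str = ""

    @property
    def delta_ppm(self):
        return -self.sigma * 1e6


def geometry_factor(rho, z, zbar_ratio):
    """Loop-pair geometry factor G(rho, z).

    All three arguments are dimensionless ratios to the ring radius. For each
    loop at z -+ zbar_ratio the term is evaluated with the elliptic-integral
    parameter m = k^2 = 4 rho / ((1+rho)^2 + z_pm^2); G is even in z and
    vanishes in the far field.
    """
    rho = float(rho)
    z = float(z)
    if not (np.isfinite(rho) and np.isfinite(z)) or rho < 0 or zbar_ratio <= 0:
        raise ValueError("rho must be >= 0, zbar_ratio > 0, inputs finite")
    total = 0.0
    for zp in (z - zbar_ratio, z + zbar_ratio):
        denom_in = (1.0 - rho) ** 2 + zp * zp
        if denom_in < 1e-24:
            raise ZeroDivisionError(
                "geometry factor singular at the loop edge (rho=1, z=+-zbar)")
        m = 4.0 * rho / ((1.0 + rho) ** 2 + zp * zp)
        total += (1.0 / math.sqrt((1.0 + rho) ** 2 + zp * zp)) * (
            ellipk(m) + (1.0 - rho * rho - zp * zp) / denom_in * ellipe(m)
        )
    return total


def b_factor(radius_angstrom):
    """Single-ring shielding amplitude B = 3 e^2/(6 pi m_e a c^2), dimensionless.

    Evaluated in CGS-Gaussian units with the radius converted to cm;
    B(1.39 A) ~= 3.23e-6.
    """
    a_cm = radius_angstrom * 1e-8
    return 3.0 * E_ESU**2 / (6.0 * math.pi * M_E_G * a_cm * C_CM_S**2)


def ring_rc_shift(point, ring: RingGeometry, ring_id, params: RCParameters,
                  nucleus_class):
    """Shift contribution of a single ring at an observation point.

    The ring radius of ``ring`` must match the class of ``ring_id``.
    """
    expected = params.radius_for(ring_id)
    if abs(ring.radius - expected) > 1e-6:
        raise ValueError(
            f"ring radius {ring.radius} does not match class of {ring_id} ({expected})")
    i_j = params.intensity_for(ring_id, nucleus_class)
    rho, z = ring.cylindrical_coords(point)
    g = geometry_factor(rho, z, params.zbar / ring.radius)
    sigma = i_j * b_factor(ring.radius) * g
    return ShiftContribution(sigma=sigma, source=ring_id)


def _imino_target(structure, residue, nucleus_class):
    base = structure.residue_name(residue)
    if base == "G":
        n_atom = "N1"
    elif base == "U":
        n_atom = "N3"
    else:
        raise ValueError(f"residue {residue} ({base}) bears no imino group")
    if nucleus_class == "N":
        return structure.position(residue, n_atom)
    if nucleus_class == "H":
        return place_imino_proton(structure, residue)
    raise ValueError(f"unknown nucleus class {nucleus_class!r}")


def _default_sources(structure, residue):
    residue = tuple(residue)
    excluded = {residue}
    partner = structure.pair_partner(residue)
    if partner is not None:
        excluded.add(partner)
    return [r for r in structure.residues if r not in excluded]


def rc_shift_at_nucleus(structure, residue, nucleus_class, sources=None,
                        params: RCParameters | None = None):
    """Total ring-current shift at an imino nucleus, with per-ring breakdown.

    Parameters
    ----------
    residue : (chain_id, residue_index)
        A base-paired G or U; the probed nucleus is N1/H1 (G) or N3/H3 (U).
    sources : iterable of residue keys, optional
        Residues whose rings contribute (purines contribute two rings each).
        By default every residue except the target and, when pairing
        metadata is present, its base-pair partner.

    Returns
    -------
    (float, list[ShiftContribution])
        Total shift in ppm and the per-ring breakdown (which sums to it).
    """
    import warnings

    if params is None:
        params = RCParameters.default()
    point = _imino_target(structure, residue, nucleus_class)
    if sources is None:
        sources = _default_sources(structure, residue)
    sources = [tuple(s) for s in sources]
    if not sources:
        warnings.warn("empty ring-current source set; returning 0")
        return 0.0, []
    breakdown = []
    for src in sources:
        base = structure.residue_name(src)
        for ring_id, ring_kind in ring_ids_for_base(base):
            geom = ring_geometry(structure, src, ring_kind)
            contrib = ring_rc_shift(point, geom, ring_id, params, nucleus_class)
            breakdown.append(ShiftContribution(contrib.sigma, f"{src[0]}/{src[1]}:{ring_id}"))
    total = sum(c.delta_ppm for c in breakdown)
    return total, breakdown


def rc_design_row(structure, residue, nucleus_class, sources=None,
                  params: RCParameters | None = None):
    """Per-ring-class coefficients of the shift, before intensity scaling.

    Returns ``{ring_id: -1e6 * sum(B_j G_j)}`` over the source rings, so the
    total shift is the dot product with the intensity factors. Used by the
    calibration solver, where the shift is linear in the six intensities.
    """
    if params is None:
        params = RCParameters.default()
    point = _imino_target(structure, residue, nucleus_class)
    if sources is None:
        sources = _default_sources(structure, residue)
    row = {rid: 0.0 for rid in RING_IDS}
    for src in (tuple(s) for s in sources):
        base = structure.residue_name(src)
        for ring_id, ring_kind in ring_ids_for_base(base):
            geom = ring_geometry(structure, src, ring_kind)
            rho, z = geom.cylindrical_coords(point)
            g = geometry_factor(rho, z, params.zbar / geom.radius)
            row[ring_id] += -1e6 * b_factor(geom.radius) * g
    return row


def calibrate_intensity_factors(lookup, structures, nucleus_class,
                                params: RCParameters | None = None,
                                group_of=None):
    """Calibrate the six ring intensity factors against a shift lookup table.

    Minimizes ``sum((delta_rc - delta_table)^2)`` over all table entries,
    after removing a per-group mean (the intrinsic shift of each central
    base-pair group is adjusted so calculated and tabulated shifts share the
    same mean). Because the ring-current shift is linear in the intensity
    factors the problem is an exact linear least squares and the solution is
    deterministic.

    Parameters
    ----------
    lookup : dict
        ``{code: shift_ppm}`` where ``code`` is a triplet code (or any
        hashable key accepted by ``group_of``).
    structures : dict
        ``{code: (Structure, target_residue, source_residues)}``.
    group_of : callable, optional
        Maps a code to its mean-centering group; by default the central
        field of a triplet code.

    Returns
    -------
    (dict, float)
        Calibrated ``{ring_id: i_j}`` and the residual sum of squares.
    """
    if params is None:
        params = RCParameters.default()
    if group_of is None:
        group_of = lambda code: code[1] if isinstance(code, tuple) else code
    codes = sorted(lookup, key=repr)
    if not codes:
        raise ValueError("empty lookup table")
    rows = []
    y = []
    groups = []
    for code in codes:
        st, target, srcs = structures[code]
        row = rc_design_row(st, target, nucleus_class, sources=srcs, params=params)
        rows.append([row[rid] for rid in RING_IDS])
        y.append(lookup[code])
        groups.append(group_of(code))
    X = np.array(rows)
    y = np.array(y, float)
    group_keys = sorted(set(groups), key=repr)
    if len(group_keys) < 1:
        raise ValueError("no groups to center")
    # group-wise mean centering of both sides
    Xc = X.copy()
    yc = y.copy()
    for gk in group_keys:
        mask = np.array([g == gk for g in groups])
        Xc[mask] -= X[mask].mean(axis=0)
        yc[mask] -= y[mask].mean()
    sol, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    if rank < len(RING_IDS):
        raise ValueError(
            f"calibration design is rank-deficient (rank {rank} < {len(RING_IDS)}); "
            "fewer than six independent triplet groups")
    resid = float(np.sum((Xc @ sol - yc) ** 2))
    return dict(zip(RING_IDS, sol.tolist())), resid
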