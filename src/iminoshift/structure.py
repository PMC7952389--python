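"""Nucleic-acid coordinate handling for shielding calculations.

This module provides a light-weight coordinate container (:class:`Structure`),
a PDB reader built on gemmi, an idealized A-form duplex generator, and the
base-ring geometry (least-squares plane, cylindrical coordinates) consumed by
the ring-current and electric-field calculators.

The duplex generator places rigid bases, expressed in the standard base-pair
reference frame (origin at the pair center, x toward the major groove, y
along the long axis toward the strand-I C1', base plane in xy), onto an
idealized A-form helix: helical twist 32.7 deg, helical rise 2.81 A,
x-displacement -4.4 A and inclination 15.7 deg, the canonical fiber-model
values for the 11-fold A-RNA helix (the implied local step parameters --
twist ~31.5 deg, roll ~+9 deg, slide ~-1.6 A, rise ~3.4 A -- match
published analyses of fiber A-RNA).  G.U wobbles are built from the Watson-Crick template by
sliding the uridine ~2.2 A toward the major groove so that G(N1-H1)...O2(U)
and G(O6)...H3-N3(U) hydrogen bonds form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "RingGeometry",
    "read_pdb",
    "build_aform_duplex",
    "ring_geometry",
    "RING_ATOMS",
    "ring_ids_for_base",
    "place_imino_proton",
    "WC_PAIRS",
]

RIBONUCLEOTIDES = {"A", "G", "C", "U"}

#: valid duplex pair codes, first letter on the reference (I) strand
WC_PAIRS = ("GC", "CG", "AU", "UA", "GU", "UG")

# Ring atom sets. Purines carry two aromatic rings; pyrimidines one.
RING_ATOMS = {
    "purine6": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "purine5": ("C4", "C5", "N7", "C8", "N9"),
    "pyrimidine": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: six-membered rings use radius 1.39 A, five-membered 1.182 A
RING_RADII = {"purine6": 1.39, "purine5": 1.182, "pyrimidine": 1.39}

# Ring identifiers used by the shielding parameter tables.
_BASE_RINGS = {
    "G": (("Gua-6", "purine6"), ("Gua-5", "purine5")),
    "A": (("Ade-6", "purine6"), ("Ade-5", "purine5")),
    "C": (("Cyt", "pyrimidine"),),
    "U": (("Ura", "pyrimidine"),),
}


def ring_ids_for_base(base: str):
    """Return ``(ring_id, ring_kind)`` tuples for a base letter."""
    try:
        return _BASE_RINGS[base]
    except KeyError:
        raise ValueError(f"unknown base {base!r}") from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, residue identity and Cartesian position in A."""

    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class Structure:
    """Ordered atom collection with residue lookups.

    Residues are addressed by ``(chain_id, residue_index)``. Author residue
    numbering from input files is preserved verbatim.
    """

    def __init__(self, atoms, base_pairs=None):
        self.atoms = list(atoms)
        self._index = {}
        self._residues = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.atom_name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key}")
            self._index[key] = a
            self._residues.setdefault((a.chain_id, a.residue_index), []).append(a)
        #: optional list of ((chain,idx),(chain,idx)) pairing metadata
        self.base_pairs = list(base_pairs) if base_pairs else []

    def __len__(self):
        return len(self.atoms)

    @property
    def residues(self):
        """Residue keys ``(chain_id, residue_index)`` in order of appearance."""
        return list(self._residues)

    def residue_name(self, residue):
        return self._residues[tuple(residue)][0].residue_name

    def residue_atoms(self, residue):
        return list(self._residues[tuple(residue)])

    def has_atom(self, residue, atom_name):
        chain, idx = residue
        return (chain, idx, atom_name) in self._index

    def position(self, residue, atom_name):
        chain, idx = residue
        try:
            return self._index[(chain, idx, atom_name)].position
        except KeyError:
            raise KeyError(f"atom {atom_name} not found in {chain}/{idx}") from None

    def ring_complete(self, residue, ring_kind):
        return all(self.has_atom(residue, n) for n in RING_ATOMS[ring_kind])

    def pair_partner(self, residue):
        """Paired residue from :attr:`base_pairs` metadata, or None."""
        residue = tuple(residue)
        for a, b in self.base_pairs:
            if tuple(a) == residue:
                return tuple(b)
            if tuple(b) == residue:
                return tuple(a)
        return None

    def transformed(self, rotation, translation):
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [
            AtomRecord(a.atom_name, a.residue_name, a.residue_index, a.chain_id,
                       R @ a.position + t)
            for a in self.atoms
        ]
        return Structure(atoms, base_pairs=self.base_pairs)

    def to_pdb(self, path):
        """Write a minimal single-model PDB file for inspection."""
        with open(path, "w") as fh:
            serial = 1
            for a in self.atoms:
                name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
                x, y, z = a.position
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {a.residue_name:>3s} "
                    f"{a.chain_id[:1]}{a.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
                serial += 1
            fh.write("END\n")


@dataclass(frozen=True)
class RingGeometry:
    """Fitted ring plane: center, unit normal and the fixed model radius."""

    center: np.ndarray
    unit_normal: np.ndarray
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, float)
        n = np.asarray(self.unit_normal, float)
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "unit_normal", n)

    def cylindrical_coords(self, point):
        """Cylindrical ``(rho, z)`` of a point as ratios to the ring radius.

        The sign of z is retained but is irrelevant downstream: the
        geometry factor is even in z.
        """
        d = np.asarray(point, float) - self.center
        z = float(d @ self.unit_normal)
        rho = float(np.linalg.norm(d - z * self.unit_normal))
        return rho / self.radius, z / self.radius


# --------------------------------------------------------------------------
# Standard reference-frame base coordinates (heavy base atoms + C1'), in A.
# Base plane in xy, y roughly along the N-glycosidic direction toward C1'.
_STD_BASES = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000),
        "O4": (1.935, 2.094, -0.001),
        "C5": (1.089, 4.311, 0.000),
        "C6": (-0.024, 5.053, 0.000),
    },
}

# Idealized A-form helical parameters (fiber A-RNA: 11-fold helix).
AFORM_TWIST_DEG = 32.7
AFORM_RISE = 2.81
AFORM_XDISP = -4.4
AFORM_INCLINATION_DEG = 15.7

# Rigid in-plane offset applied to the U of a G.U wobble (pair-frame
# coordinates): slides U toward the major groove so O2 faces G N1-H.
_WOBBLE_SHIFT = np.array([2.16, 0.46, 0.0])

_NH_BOND = 1.01  # imino N-H bond length, A

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}


def _rot_x(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)


def _rot_z(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], float)


# 180 deg rotation about x: maps a strand-I standard frame onto strand II.
_FLIP = np.diag([1.0, -1.0, -1.0])


def _pair_template(pair_code):
    """Atoms of one base pair in the pair reference frame.

    Returns ``(strand1_base, atoms1, strand2_base, atoms2)`` where atoms are
    ``{name: xyz}`` dictionaries.
    """
    if pair_code not in WC_PAIRS:
        raise ValueError(f"unknown pair symbol {pair_code!r}")
    b1, b2 = pair_code[0], pair_code[1]
    atoms1 = {n: np.array(p, float) for n, p in _STD_BASES[b1].items()}
    atoms2 = {n: _FLIP @ np.array(p, float) for n, p in _STD_BASES[b2].items()}
    if pair_code in ("GU", "UG"):
        # shift the uridine off the WC position into the wobble geometry;
        # the offset was derived in strand-II (flipped) coordinates
        if b2 == "U":
            atoms2 = {n: p + _WOBBLE_SHIFT for n, p in atoms2.items()}
        else:
            atoms1 = {n: p + _FLIP @ _WOBBLE_SHIFT for n, p in atoms1.items()}
    return b1, atoms1, b2, atoms2


def _imino_proton_position(atoms, base):
    """Imino H 1.01 A from N along the in-plane bisector away from the ring."""
    if base == "G":
        n, a, b = atoms["N1"], atoms["C2"], atoms["C6"]
    elif base == "U":
        n, a, b = atoms["N3"], atoms["C2"], atoms["C4"]
    else:
        raise ValueError(f"base {base} carries no imino proton")
    u = (a - n) / np.linalg.norm(a - n)
    v = (b - n) / np.linalg.norm(b - n)
    bis = -(u + v)
    return n + _NH_BOND * bis / np.linalg.norm(bis)


def place_imino_proton(structure, residue):
    """Position of the imino proton (H1 of G, H3 of U).

    Uses the atom from the structure when present, otherwise places it
    1.01 A from the imino nitrogen along the in-plane C-N-C bisector.
    """
    base = structure.residue_name(residue)
    atom = {"G": "H1", "U": "H3"}.get(base)
    if atom is None:
        raise ValueError(f"residue {residue} ({base}) has no imino proton")
    if structure.has_atom(residue, atom):
        return structure.position(residue, atom)
    names = ("N1", "C2", "C6") if base == "G" else ("N3", "C2", "C4")
    pos = {n: structure.position(residue, n) for n in names}
    if base == "G":
        return _imino_proton_position({"N1": pos["N1"], "C2": pos["C2"], "C6": pos["C6"]}, "G")
    return _imino_proton_position({"N3": pos["N3"], "C2": pos["C2"], "C4": pos["C4"]}, "U")


def build_aform_duplex(pair_list):
    """Generate an idealized A-form duplex from a list of pair codes.

    Parameters
    ----------
    pair_list : sequence of str
        Pair codes drawn from ``{GC, CG, AU, UA, GU, UG}``, listed 5'->3'
        along the reference strand (chain A). The first letter of each code
        is the chain-A base.

    Returns
    -------
    Structure
        Chain A numbered ``1..n`` 5'->3'; chain B numbered ``n+1..2n``
        5'->3' on its own strand, so pair ``i`` joins A:i with B:(2n-i+1).
        Base atoms, C1' and imino protons are included. Pairing metadata is
        attached as :attr:`Structure.base_pairs`.
    """
    pair_list = list(pair_list)
    if not pair_list:
        raise ValueError("pair_list must contain at least one pair")
    n = len(pair_list)
    incl = _rot_x(AFORM_INCLINATION_DEG)
    disp = np.array([AFORM_XDISP, 0.0, 0.0])
    atoms = []
    pairs_meta = []
    for i, code in enumerate(pair_list):
        b1, a1, b2, a2 = _pair_template(code)
        if b1 in ("G", "U"):
            a1 = dict(a1, **{("H1" if b1 == "G" else "H3"): _imino_proton_position(a1, b1)})
        if b2 in ("G", "U"):
            a2 = dict(a2, **{("H1" if b2 == "G" else "H3"): _imino_proton_position(a2, b2)})
        Rz = _rot_z(AFORM_TWIST_DEG * i)
        t = np.array([0.0, 0.0, AFORM_RISE * i])
        res1 = i + 1
        res2 = 2 * n - i
        for name, p in a1.items():
            atoms.append(AtomRecord(name, b1, res1, "A", Rz @ (incl @ p + disp) + t))
        for name, p in a2.items():
            atoms.append(AtomRecord(name, b2, res2, "B", Rz @ (incl @ p + disp) + t))
        pairs_meta.append((("A", res1), ("B", res2)))
    return Structure(atoms, base_pairs=pairs_meta)


def read_pdb(path, model_index=0):
    """Read ribonucleotide atoms of one model from a PDB file.

    Only residues named A/G/C/U (with common variants ``RA, A5, A3, ADE``
    etc. normalized) are kept; author chain ids and residue numbers are
    preserved.
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    if not (0 <= model_index < len(st)):
        raise IndexError(
            f"model_index {model_index} out of range for {len(st)} model(s)")
    model = st[model_index]
    atoms = []
    for chain in model:
        for res in chain:
            base = _normalize_resname(res.name)
            if base is None:
                continue
            for at in res:
                atoms.append(
                    AtomRecord(
                        at.name.replace("*", "'"),
                        base,
                        res.seqid.num,
                        chain.name,
                        np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    if not atoms:
        raise ValueError(f"no ribonucleotide residues found in {path}")
    return Structure(atoms)


def _normalize_resname(name):
    name = name.strip().upper()
    table = {
        "A": "A", "RA": "A", "ADE": "A", "A5": "A", "A3": "A", "AN": "A",
        "G": "G", "RG": "G", "GUA": "G", "G5": "G", "G3": "G", "GN": "G",
        "C": "C", "RC": "C", "CYT": "C", "C5": "C", "C3": "C", "CN": "C",
        "U": "U", "RU": "U", "URA": "U", "URI": "U", "U5": "U", "U3": "U", "UN": "U",
    }
    return table.get(name)


def ring_geometry(structure, residue, ring_kind):
    """Least-squares ring plane for one ring of a residue.

    Parameters
    ----------
    ring_kind : str
        ``purine6``, ``purine5`` or ``pyrimidine`` (see :data:`RING_ATOMS`).

    Returns
    -------
    RingGeometry
        Center is the ring-atom centroid; the normal is the singular vector
        of least variance (sign follows the atom ordering's right-hand
        sense); the radius is the fixed model radius for the ring class.
    """
    names = RING_ATOMS[ring_kind]
    try:
        pts = np.array([structure.position(residue, n) for n in names])
    except KeyError as exc:
        raise ValueError(f"incomplete {ring_kind} ring in {residue}: {exc}") from exc
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise ValueError(f"degenerate (collinear) ring coordinates in {residue}")
    normal = vt[2]
    # orient by the polygon's right-hand sense so the sign is reproducible
    sense = np.cross(centered[0], centered[1])
    for k in range(1, len(pts) - 1):
        sense = sense + np.cross(centered[k], centered[k + 1])
    if normal @ sense < 0:
        normal = -normal
    return RingGeometry(center, normal, RING_RADII[ring_kind])
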