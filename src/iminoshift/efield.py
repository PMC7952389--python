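"""Electric-field-induced proton shift from surrounding partial charges.

Polar groups polarize an X-H bond through their Coulomb field; the
first-order shift of the proton is proportional to the field component along
the bond:

    delta_ef = -sigma_ef * 1e6 = -A * E(XH) * 1e6

where E(XH) is the Coulomb field at the H position projected onto the unit
vector from X to H, and A = -2.98e-12 esu^-1.  Charges are taken from the
Amber ff94 nucleic-acid set (shipped as a plain-text table, user
replaceable), converted to esu; distances are converted to cm so that A*E is
dimensionless.  A field pointing from X toward H (positive projection)
deshields the proton (positive delta).  Higher-order field terms are
neglected, and no 15N version is offered -- the polarization model is a
proton model only.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure import place_imino_proton

__all__ = ["EFParameters", "ef_shift", "ef_shift_imino"]

A_DEFAULT = -2.98e-12   # polarization coefficient, esu^-1
_E_TO_ESU = 4.8032e-10  # elementary charge in esu
_ANG_TO_CM = 1e-8

# alternative atom spellings found in PDB files -> table names
_ALIASES = {
    "O1P": "OP1", "O2P": "OP2",
    "H5'1": "H5'", "H5'2": "H5''",
    "H2'1": "H2'", "HO'2": "HO2'", "HO2": "HO2'", "H2''": "HO2'",
}


def _load_charge_table():
    table = {}
    with resources.files("iminoshift.data").joinpath("ff94_charges.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[(row["residue"], row["atom"])] = float(row["charge"])
    return table


@dataclass(frozen=True)
class EFParameters:
    """Polarization coefficient and partial-charge table.

    The charge table maps ``(residue_name, atom_name)`` to a charge in
    elementary-charge units; the shipped ff94 set sums to the formal charge
    (-1 per internal ribonucleotide) within 1e-4.
    """

    A: float = A_DEFAULT
    charge_table: dict = field(default_factory=_load_charge_table)

    @classmethod
    def from_tsv(cls, path, A=A_DEFAULT):
        table = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                table[(row["residue"], row["atom"])] = float(row["charge"])
        return cls(A=A, charge_table=table)

    def charge(self, residue_name, atom_name):
        atom_name = _ALIASES.get(atom_name, atom_name)
        return self.charge_table.get((residue_name, atom_name))


def ef_shift(structure, bond, sources=None, params: EFParameters | None = None):
    """Electric-field shift of a proton, with per-source-atom breakdown.

    Parameters
    ----------
    bond : ((residue, atom_X), (residue, atom_H))
        The polarized X-H bond; X is the heavy atom. The H position is
        taken from the structure, or placed by the imino rule when the
        named proton is the imino H1/H3 and absent from the file.
    sources : iterable of residue keys, optional
        Residues whose partial charges generate the field; defaults to all
        residues except the bond's own residue and (when pairing metadata
        exists) its base-pair partner. Atoms without a charge entry are
        skipped with a warning.

    Returns
    -------
    (float, list)
        Shift in ppm and per-atom breakdown ``[(residue, atom, ppm), ...]``
        summing to the total.
    """
    if params is None:
        params = EFParameters()
    (res_x, name_x), (res_h, name_h) = bond
    res_x, res_h = tuple(res_x), tuple(res_h)
    if name_h in ("N1", "N3") or name_x in ("H1", "H3"):
        raise ValueError("bond must be given as ((residue, X), (residue, H))")
    x_pos = structure.position(res_x, name_x)
    if structure.has_atom(res_h, name_h):
        h_pos = structure.position(res_h, name_h)
    elif name_h in ("H1", "H3"):
        h_pos = place_imino_proton(structure, res_h)
    else:
        raise KeyError(f"proton {name_h} not found in {res_h}")
    bond_vec = h_pos - x_pos
    norm = np.linalg.norm(bond_vec)
    if norm < 1e-9:
        raise ValueError("zero-length bond vector")
    u = bond_vec / norm

    if sources is None:
        excluded = {res_x, res_h}
        partner = structure.pair_partner(res_h)
        if partner is not None:
            excluded.add(partner)
        sources = [r for r in structure.residues if r not in excluded]
    breakdown = []
    missing = []
    for src in (tuple(s) for s in sources):
        res_name = structure.residue_name(src)
        for atom in structure.residue_atoms(src):
            q = params.charge(res_name, atom.atom_name)
            if q is None:
                missing.append((src, atom.atom_name))
                continue
            r_vec = (h_pos - atom.position) * _ANG_TO_CM
            r2 = float(r_vec @ r_vec)
            if r2 < 1e-20:
                raise ValueError(f"source atom {src}/{atom.atom_name} coincides with H")
            # field of q at H, projected on the X->H unit vector (esu/cm^2)
            e_proj = (q * _E_TO_ESU) / r2 * float(r_vec @ u) / np.sqrt(r2)
            delta = -params.A * e_proj * 1e6
            breakdown.append((src, atom.atom_name, delta))
    if missing:
        warnings.warn(
            f"{len(missing)} source atom(s) lacked a charge entry and were skipped "
            f"(first: {missing[0]})")
    return float(sum(d for *_, d in breakdown)), breakdown


def ef_shift_imino(structure, residue, sources=None, params=None, nucleus_class="H"):
    """EF shift of the imino proton of a G or U residue.

    Only protons are supported: the polarization model has no reliable 15N
    analogue, so ``nucleus_class`` other than ``"H"`` raises.
    """
    if nucleus_class != "H":
        raise ValueError(
            "electric-field shifts are only defined for protons (no 15N model)")
    base = structure.residue_name(residue)
    if base == "G":
        bond = ((residue, "N1"), (residue, "H1"))
    elif base == "U":
        bond = ((residue, "N3"), (residue, "H3"))
    else:
        raise ValueError(f"residue {residue} ({base}) bears no imino proton")
    return ef_shift(structure, bond, sources=sources, params=params)
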