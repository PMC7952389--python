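"""Base-pair triplet extraction, lookup-table prediction and decomposition.

The central objects are the *triplet code* -- three consecutive base pairs
in an A-form helix written as a three-field code, e.g. ``UA-GC-GU`` -- and a
lookup table mapping each code to the imino 15N/1H shifts of the central
base pair.  The first letter of every field is the base on the same strand
as the central imino nucleotide, read 5'->3' on that strand.  Central pairs
are restricted to the four imino-bearing types (GC, UA, GU, UG); with six
possible neighbors on either side this gives 6 x 4 x 6 = 144 codes.

A lookup table can be reconstructed from a decomposed representation

    delta_calc = delta_intrin(central) + delta_5(5' pair) + delta_3(3' pair)

whose default values ship with the package, and conversely a 144-entry
lookup can be decomposed into intrinsic and neighbor terms by anchoring each
neighbor's contribution to its calculated ring-current shift
(:func:`decompose_lookup`).  Register-shift predictions for excited-state
work compare two codes and report |delta omega| in ppm and Hz.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np

from .structure import WC_PAIRS, build_aform_duplex

__all__ = [
    "IminoShift",
    "TripletCode",
    "CENTRAL_PAIRS",
    "parse_secondary_structure",
    "extract_triplets",
    "enumerate_triplet_codes",
    "DecomposedTable",
    "reconstruct_lookup",
    "predict_imino_shifts",
    "predict_hybrid",
    "decompose_lookup",
    "AFormRCProvider",
    "TableRCProvider",
    "RegisterShiftPrediction",
    "register_shift_delta",
    "enumerate_register_slides",
    "read_lookup_tsv",
    "write_lookup_tsv",
]

CENTRAL_PAIRS = ("GC", "UA", "GU", "UG")

#: 15N Larmor frequency per MHz of proton frequency (81.08 MHz at 800 MHz)
N15_PER_H1 = 81.08 / 800.0

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_CANONICAL = set(WC_PAIRS)


class IminoShift(NamedTuple):
    """Imino chemical shifts in ppm (15N, 1HN)."""

    n15: float
    h1: float

    def __add__(self, other):
        return IminoShift(self.n15 + other[0], self.h1 + other[1])

    def __sub__(self, other):
        return IminoShift(self.n15 - other[0], self.h1 - other[1])


class TripletCode(NamedTuple):
    """Three-field base-pair triplet code (5' pair, central pair, 3' pair)."""

    five_prime: str
    central: str
    three_prime: str

    @classmethod
    def make(cls, five, central, three):
        for f in (five, central, three):
            if f not in _CANONICAL:
                raise ValueError(f"invalid pair code {f!r}")
        if central not in CENTRAL_PAIRS:
            raise ValueError(
                f"central pair must be imino-bearing ({CENTRAL_PAIRS}), got {central!r}")
        return cls(five, central, three)

    @classmethod
    def from_string(cls, text):
        parts = text.replace("_", "-").split("-")
        if len(parts) != 3:
            raise ValueError(f"cannot parse triplet code {text!r}")
        return cls.make(*parts)

    def __str__(self):
        return f"{self.five_prime}-{self.central}-{self.three_prime}"


def enumerate_triplet_codes():
    """All 144 valid triplet codes (6 neighbors x 4 centrals x 6 neighbors)."""
    return [
        TripletCode(f, c, t)
        for f in WC_PAIRS for c in CENTRAL_PAIRS for t in WC_PAIRS
    ]


# --------------------------------------------------------------------------
# secondary structure

_OPENERS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}


@dataclass(frozen=True)
class BasePair:
    """One i<->j pairing (1-based) with its classification."""

    i: int
    j: int
    kind: str  # "WC" | "wobble" | "noncanonical"


def _classify(b1, b2):
    duo = b1 + b2
    if duo in ("GC", "CG", "AU", "UA"):
        return "WC"
    if duo in ("GU", "UG"):
        return "wobble"
    return "noncanonical"


def parse_secondary_structure(sequence, dotbracket):
    """Parse dot-bracket notation into classified base pairs.

    Supports ``()``, ``[]`` and ``{}`` pseudoknot layers. Returns a list of
    :class:`BasePair` with 1-based indices, sorted by the opening position.
    """
    sequence = sequence.strip().upper().replace("T", "U")
    dotbracket = dotbracket.strip()
    if len(sequence) != len(dotbracket):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(dotbracket)}")
    stacks = {k: [] for k in _OPENERS}
    pairs = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch in _OPENERS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            i = stacks[opener].pop()
            pairs.append(BasePair(i, pos, _classify(sequence[i - 1], sequence[pos - 1])))
        elif ch not in ".-":
            raise ValueError(f"unexpected structure character {ch!r}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced {opener!r} at position {stack[-1]}")
    return sorted(pairs, key=lambda p: p.i)


def extract_triplets(pairs, sequence):
    """Central residues of canonical base-pair triplets.

    A paired G or U at position i (partner j) is the center of a triplet
    when i-1 pairs j+1, i+1 pairs j-1 and all three pairs are WC or GU
    wobble. Each triplet field is written with the base on the strand of
    residue i first.

    Returns
    -------
    (list, list)
        ``[(i, TripletCode), ...]`` for qualifying residues, and a report of
        ``(i, reason)`` for paired G/U residues that were excluded.
    """
    sequence = sequence.strip().upper().replace("T", "U")
    partner = {}
    for p in pairs:
        partner[p.i] = p.j
        partner[p.j] = p.i
    result = []
    report = []

    def pair_code(i, j):
        return sequence[i - 1] + sequence[j - 1]

    for i in sorted(partner):
        base = sequence[i - 1]
        if base not in ("G", "U"):
            continue
        j = partner[i]
        central = pair_code(i, j)
        if central not in CENTRAL_PAIRS:
            report.append((i, f"central pair {central} not canonical"))
            continue
        if partner.get(i - 1) != j + 1 or partner.get(i + 1) != j - 1:
            report.append((i, "no contiguous flanking base pairs"))
            continue
        five = pair_code(i - 1, j + 1)
        three = pair_code(i + 1, j - 1)
        if five not in _CANONICAL or three not in _CANONICAL:
            report.append((i, f"neighbor pair not WC/GU ({five}, {three})"))
            continue
        result.append((i, TripletCode(five, central, three)))
    return result, report


# --------------------------------------------------------------------------
# decomposed table and reconstruction

class DecomposedTable:
    """Intrinsic central-pair shifts plus 5'/3' neighbor contributions.

    ``intrinsic[central]``, ``five_prime[(neighbor, central)]`` and
    ``three_prime[(neighbor, central)]`` are :class:`IminoShift` values; the
    shipped defaults are the decomposition of the experimental triplet
    table. ``intrinsic_sd`` carries the quoted uncertainties of the
    intrinsic terms.
    """

    def __init__(self, intrinsic, five_prime, three_prime, intrinsic_sd=None):
        self.intrinsic = dict(intrinsic)
        self.five_prime = dict(five_prime)
        self.three_prime = dict(three_prime)
        self.intrinsic_sd = dict(intrinsic_sd or {})
        self._validate()

    def _validate(self):
        missing = [c for c in CENTRAL_PAIRS if c not in self.intrinsic]
        for n in WC_PAIRS:
            for c in CENTRAL_PAIRS:
                if (n, c) not in self.five_prime:
                    missing.append(("5p", n, c))
                if (n, c) not in self.three_prime:
                    missing.append(("3p", n, c))
        if missing:
            raise ValueError(f"incomplete decomposed table; missing {missing[:4]}...")

    @classmethod
    def default(cls):
        with resources.files("iminoshift.data").joinpath(
                "decomposed_shifts.tsv").open() as fh:
            return cls._from_rows(csv.DictReader(fh, delimiter="\t"))

    @classmethod
    def from_tsv(cls, path):
        with open(path) as fh:
            return cls._from_rows(csv.DictReader(fh, delimiter="\t"))

    @classmethod
    def _from_rows(cls, rows):
        intrinsic, five, three, sd = {}, {}, {}, {}
        for row in rows:
            shift = IminoShift(float(row["n15"]), float(row["h1"]))
            if row["term"] == "intrinsic":
                intrinsic[row["central"]] = shift
                if row.get("n15_sd"):
                    sd[row["central"]] = IminoShift(float(row["n15_sd"]),
                                                    float(row["h1_sd"]))
            elif row["term"] == "5p":
                five[(row["neighbor"], row["central"])] = shift
            elif row["term"] == "3p":
                three[(row["neighbor"], row["central"])] = shift
            else:
                raise ValueError(f"unknown term {row['term']!r}")
        return cls(intrinsic, five, three, sd)

    def shift_for(self, code: TripletCode):
        return (self.intrinsic[code.central]
                + self.five_prime[(code.five_prime, code.central)]
                + self.three_prime[(code.three_prime, code.central)])


def reconstruct_lookup(decomposed: DecomposedTable):
    """Full 144-entry lookup ``{TripletCode: IminoShift}`` from the terms."""
    return {code: decomposed.shift_for(code) for code in enumerate_triplet_codes()}


def default_lookup():
    """Lookup table reconstructed from the shipped decomposed contributions."""
    return reconstruct_lookup(DecomposedTable.default())


# --------------------------------------------------------------------------
# prediction

@dataclass(frozen=True)
class Prediction:
    """Per-residue prediction record."""

    index: int
    base: str
    code: TripletCode | None
    shift: IminoShift | None
    note: str = ""


def predict_imino_shifts(sequence, dotbracket, table=None):
    """Predict imino shifts for every paired G/U of a secondary structure.

    Residues centered in a canonical triplet get the table value (rounded
    to 2 decimals, round-half-even, as tabulated); others are reported as
    not predictable with the exclusion reason.
    """
    if table is None:
        table = default_lookup()
    sequence = sequence.strip().upper().replace("T", "U")
    pairs = parse_secondary_structure(sequence, dotbracket)
    triplets, report = extract_triplets(pairs, sequence)
    reasons = dict(report)
    predictions = []
    for i, code in triplets:
        if code not in table:
            raise KeyError(f"triplet code {code} absent from the supplied table")
        s = table[code]
        predictions.append(Prediction(i, sequence[i - 1], code,
                                      IminoShift(round(s.n15, 2), round(s.h1, 2))))
    for i, reason in report:
        predictions.append(Prediction(i, sequence[i - 1], None, None,
                                      note=f"not predictable (noncanonical context): {reason}"))
    return sorted(predictions, key=lambda p: p.index)


def predict_hybrid(central, canonical_neighbor, canonical_side, rc_shift,
                   decomposed: DecomposedTable | None = None, ef_shift_ppm=0.0):
    """Hybrid prediction with one noncanonical neighbor.

    The shift is the sum of three components: the intrinsic shift of the
    central pair, the tabulated contribution of the remaining canonical
    neighbor (``canonical_side`` is ``"5p"`` or ``"3p"``), and the
    ring-current shift ``rc_shift`` (an :class:`IminoShift` or (n15, h1)
    tuple) of the noncanonical moiety computed from a 3D structure, plus an
    optional proton EF term.
    """
    if decomposed is None:
        decomposed = DecomposedTable.default()
    if canonical_side == "5p":
        contrib = decomposed.five_prime[(canonical_neighbor, central)]
    elif canonical_side == "3p":
        contrib = decomposed.three_prime[(canonical_neighbor, central)]
    else:
        raise ValueError("canonical_side must be '5p' or '3p'")
    rc = IminoShift(*rc_shift)
    base = decomposed.intrinsic[central] + contrib + rc
    return IminoShift(base.n15, base.h1 + ef_shift_ppm)


def aform_triplet_structures(codes=None):
    """Idealized A-form structures for a set of triplet codes.

    Returns ``{code: (Structure, target_residue, source_residues)}`` where
    the target is the central imino residue and the sources are the four
    residues of the two flanking base pairs -- the layout used for
    intensity-factor calibration.
    """
    if codes is None:
        codes = enumerate_triplet_codes()
    out = {}
    for code in codes:
        st = build_aform_duplex([code.five_prime, code.central, code.three_prime])
        target = ("A", 2)
        sources = [("A", 1), ("A", 3), ("B", 6), ("B", 4)]
        out[code] = (st, target, sources)
    return out


# --------------------------------------------------------------------------
# decomposition

class AFormRCProvider:
    """Ring-current shifts of a neighbor pair probed by the central pair.

    Builds a two-pair idealized A-form step (neighbor on the requested
    side) and sums the ring contributions of both bases of the neighbor
    pair at the central imino nucleus. Results are cached; protons use the
    proton intensity set, 15N the calibrated set.
    """

    def __init__(self, params=None):
        from .ringcurrent import RCParameters
        self.params = params or RCParameters.default()
        self._cache = {}

    def __call__(self, central, neighbor, direction):
        from .ringcurrent import rc_shift_at_nucleus
        key = (central, neighbor, direction)
        if key not in self._cache:
            if direction == "5p":
                st = build_aform_duplex([neighbor, central])
                target, n = ("A", 2), len(st.base_pairs)
                sources = [("A", 1), ("B", 2 * n)]
            elif direction == "3p":
                st = build_aform_duplex([central, neighbor])
                n = len(st.base_pairs)
                target = ("A", 1)
                sources = [("A", 2), ("B", 2 * n - 1)]
            else:
                raise ValueError("direction must be '5p' or '3p'")
            n15, _ = rc_shift_at_nucleus(st, target, "N", sources, self.params)
            h1, _ = rc_shift_at_nucleus(st, target, "H", sources, self.params)
            self._cache[key] = IminoShift(n15, h1)
        return self._cache[key]


class TableRCProvider:
    """RC provider that replays the contributions of a decomposed table.

    Feeding this provider to :func:`decompose_lookup` makes decomposition
    the exact inverse of :func:`reconstruct_lookup` (identical values on
    both sides of the anchoring step).
    """

    def __init__(self, decomposed: DecomposedTable):
        self.decomposed = decomposed

    def __call__(self, central, neighbor, direction):
        src = (self.decomposed.five_prime if direction == "5p"
               else self.decomposed.three_prime)
        return src[(neighbor, central)]


def decompose_lookup(lookup, rc_provider=None):
    """Split a 144-entry lookup into intrinsic and neighbor contributions.

    For each central pair and each fixed neighbor on one side, the six
    lookup shifts obtained by varying the other side are offset so that
    their mean matches the mean calculated ring-current shift of the varied
    pairs; the offset-corrected values are contributions of the varied
    neighbors.  Averaging the six repetitions (one per fixed neighbor)
    yields 24 five-prime and 24 three-prime contributions per nucleus; the
    intrinsic shift of each central pair is the mean of the 36 residuals
    after subtracting both neighbor terms.

    Parameters
    ----------
    lookup : dict
        Complete ``{TripletCode: IminoShift}`` over all 144 codes.
    rc_provider : callable, optional
        ``f(central, neighbor, direction) -> IminoShift`` giving the RC
        shift of the neighbor pair probed by the central imino nucleus;
        defaults to :class:`AFormRCProvider` on internally built A-form
        steps.

    Returns
    -------
    DecomposedTable
    """
    missing = [c for c in enumerate_triplet_codes() if c not in lookup]
    if missing:
        raise ValueError(f"incomplete lookup: missing {missing[0]} "
                         f"and {len(missing) - 1} more")
    if rc_provider is None:
        rc_provider = AFormRCProvider()

    rc = {(c, n, d): IminoShift(*rc_provider(c, n, d))
          for c in CENTRAL_PAIRS for n in WC_PAIRS for d in ("5p", "3p")}

    five, three = {}, {}
    for central in CENTRAL_PAIRS:
        for direction, store in (("5p", five), ("3p", three)):
            # varied side = direction; fixed neighbor sits on the other side
            samples = {n: [] for n in WC_PAIRS}
            for fixed in WC_PAIRS:
                def code_of(varied):
                    return (TripletCode(varied, central, fixed)
                            if direction == "5p"
                            else TripletCode(fixed, central, varied))
                deltas = np.array([[lookup[code_of(n)].n15, lookup[code_of(n)].h1]
                                   for n in WC_PAIRS])
                rcs = np.array([[rc[(central, n, direction)].n15,
                                 rc[(central, n, direction)].h1]
                                for n in WC_PAIRS])
                offset = deltas.mean(axis=0) - rcs.mean(axis=0)
                corrected = deltas - offset
                for k, n in enumerate(WC_PAIRS):
                    samples[n].append(corrected[k])
            for n in WC_PAIRS:
                store[(n, central)] = IminoShift(*np.mean(samples[n], axis=0))

    intrinsic, intrinsic_sd = {}, {}
    for central in CENTRAL_PAIRS:
        residuals = []
        for f in WC_PAIRS:
            for t in WC_PAIRS:
                s = lookup[TripletCode(f, central, t)]
                r = (np.array(s) - np.array(five[(f, central)])
                     - np.array(three[(t, central)]))
                residuals.append(r)
        residuals = np.array(residuals)
        intrinsic[central] = IminoShift(*residuals.mean(axis=0))
        intrinsic_sd[central] = IminoShift(*residuals.std(axis=0, ddof=1))
    return DecomposedTable(intrinsic, five, three, intrinsic_sd)


# --------------------------------------------------------------------------
# register shifts

@dataclass(frozen=True)
class RegisterShiftPrediction:
    """|delta omega| between two triplet codes, in ppm and Hz."""

    gs_code: TripletCode
    es_code: TripletCode
    delta_n15_ppm: float
    delta_h1_ppm: float
    delta_n15_hz: float
    delta_h1_hz: float


def register_shift_delta(gs_code, es_code, table=None, spectrometer_h1=800.0):
    """Predicted |delta omega| for a ground-state -> excited-state code change.

    Hz values use the stated proton field; the 15N frequency is
    ``spectrometer_h1 * 81.08/800``.
    """
    if table is None:
        table = default_lookup()
    if isinstance(gs_code, str):
        gs_code = TripletCode.from_string(gs_code)
    if isinstance(es_code, str):
        es_code = TripletCode.from_string(es_code)
    for code in (gs_code, es_code):
        if code not in table:
            raise KeyError(f"triplet code {code} absent from table")
    dn = abs(table[es_code].n15 - table[gs_code].n15)
    dh = abs(table[es_code].h1 - table[gs_code].h1)
    return RegisterShiftPrediction(
        gs_code, es_code, dn, dh,
        dn * spectrometer_h1 * N15_PER_H1, dh * spectrometer_h1)


def enumerate_register_slides(table=None, spectrometer_h1=800.0):
    """All code changes reachable by a one-nucleotide register slide.

    Every five-base-pair ground-state context whose middle three pairs form
    a valid code is slid by one nucleotide in either direction; the central
    residue keeps its base but pairs with the partner of its former
    neighbor. Slides whose new central triplet is again fully canonical are
    reported, deduplicated over contexts.

    Returns a list of ``(RegisterShiftPrediction, central_switch)`` where
    ``central_switch`` is True when the central pair type changes (GC<->GU
    or UA<->UG).
    """
    if table is None:
        table = default_lookup()
    seen = {}
    for ctx in itertools.product(WC_PAIRS, repeat=5):
        s = [p[0] for p in ctx]  # reference strand bases
        t = [p[1] for p in ctx]  # partner strand bases
        if ctx[2] not in CENTRAL_PAIRS:
            continue
        gs = TripletCode(ctx[1], ctx[2], ctx[3])
        for step in (+1, -1):
            new = [s[i] + t[i + step] for i in (1, 2, 3)]
            if not all(p in _CANONICAL for p in new) or new[1] not in CENTRAL_PAIRS:
                continue
            es = TripletCode(*new)
            if es == gs:
                continue
            key = (gs, es)
            if key not in seen:
                seen[key] = register_shift_delta(gs, es, table, spectrometer_h1)
    return [(pred, pred.gs_code.central != pred.es_code.central)
            for pred in seen.values()]


# --------------------------------------------------------------------------
# TSV round trip

def write_lookup_tsv(lookup, path, stats=None):
    """Serialize a lookup table as ``code  n15  h1  [n  n15_sd  h1_sd]``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        header = ["code", "n15", "h1"]
        if stats:
            header += ["n", "n15_sd", "h1_sd"]
        w.writerow(header)
        for code in sorted(lookup, key=str):
            row = [str(code), f"{lookup[code].n15:.2f}", f"{lookup[code].h1:.2f}"]
            if stats:
                st = stats.get(code, {})
                row += [st.get("n", ""), st.get("n15_sd", ""), st.get("h1_sd", "")]
            w.writerow(row)


def read_lookup_tsv(path):
    lookup = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            lookup[TripletCode.from_string(row["code"])] = IminoShift(
                float(row["n15"]), float(row["h1"]))
    return lookup
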