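"""Deterministic synthetic data and toy structures for testing.

Everything here is reproducible from an integer seed through a single
``numpy.random.default_rng`` generator, so recovery tests are replayable.
The shift-dataset generator emulates the statistical structure of a
multi-source imino shift corpus: a shared true table, per-dataset
per-nucleus referencing offsets, per-record Gaussian noise, and a small
fraction of gross outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .referencing import NUCLEI, ShiftDataset, ShiftRecord
from .structure import AtomRecord, Structure, build_aform_duplex

__all__ = ["FixtureSpec", "synth_shift_datasets", "toy_ring_structure"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic shift corpus.

    noise_sd and offset_range in ppm; outlier_magnitude in multiples of
    noise_sd. Defaults mimic a well-behaved corpus: 10 sources, 0.05 ppm
    record noise, referencing errors up to +-0.5 ppm, 5% outliers at 6
    sigma.
    """

    seed: int = 0
    n_datasets: int = 10
    noise_sd: float = 0.05
    offset_range: float = 0.5
    outlier_fraction: float = 0.05
    outlier_magnitude: float = 6.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")


def synth_shift_datasets(truth_table, spec: FixtureSpec):
    """Generate datasets from a true lookup table plus known corruptions.

    Parameters
    ----------
    truth_table : dict
        ``{TripletCode: IminoShift}`` ground-truth means.
    spec : FixtureSpec

    Returns
    -------
    (list[ShiftDataset], dict)
        Datasets (the first has zero offsets: the reference seed) and the
        ground truth: ``{"offsets": {...}, "outliers": set, "table": ...}``.
        A dataset's raw shifts are ``truth - offset + noise`` so that the
        alignment procedure should recover ``+offset``.
    """
    rng = np.random.default_rng(spec.seed)
    codes = sorted(truth_table, key=str)
    datasets = []
    truth_offsets = {}
    outliers = set()
    for k in range(spec.n_datasets):
        source = f"synthetic-{k:03d}"
        if k == 0:
            offs = {n: 0.0 for n in NUCLEI}
        else:
            offs = {n: float(rng.uniform(-spec.offset_range, spec.offset_range))
                    for n in NUCLEI}
        truth_offsets[source] = offs
        records = []
        for code in codes:
            for nucleus, true_val in zip(NUCLEI, truth_table[code]):
                val = true_val - offs[nucleus] + rng.normal(0.0, spec.noise_sd)
                label = f"{code}:{nucleus}"
                if spec.outlier_fraction and rng.random() < spec.outlier_fraction:
                    val += float(rng.choice([-1.0, 1.0])) * \
                        spec.outlier_magnitude * spec.noise_sd
                    outliers.add((source, label))
                records.append(ShiftRecord(label, code, nucleus, float(val)))
        datasets.append(ShiftDataset(source, records))
    return datasets, {"offsets": truth_offsets, "outliers": outliers,
                      "table": dict(truth_table)}


def toy_ring_structure(kind):
    """Exact toy structures for geometry tests.

    ``planar-hexagon``: six ring atoms at radius 1.39 A in the xy-plane
    (named as a pyrimidine ring); ``planar-pentagon``: five atoms at radius
    1.182 A (named as a purine five-ring); ``bp-triplet``: a three-pair
    GC-GC-GC A-form duplex from the generator.
    """
    if kind == "planar-hexagon":
        names = ("N1", "C2", "N3", "C4", "C5", "C6")
        radius = 1.39
        resname = "C"
    elif kind == "planar-pentagon":
        names = ("C4", "C5", "N7", "C8", "N9")
        radius = 1.182
        resname = "G"
    elif kind == "bp-triplet":
        return build_aform_duplex(["GC", "GC", "GC"])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    atoms = []
    for k, name in enumerate(names):
        theta = 2.0 * np.pi * k / len(names)
        atoms.append(AtomRecord(name, resname, 1, "X",
                                np.array([radius * np.cos(theta),
                                          radius * np.sin(theta), 0.0])))
    return Structure(atoms)
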