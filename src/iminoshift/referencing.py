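"""Building a triplet shift table from many datasets with re-referencing.

Chemical-shift referencing errors between NMR datasets appear as additive,
spectrometer-wide per-nucleus offsets.  This module aligns a collection of
per-residue imino shift datasets onto a common scale by an iterative
procedure: the first dataset (assumed referenced to DSS) seeds the table;
every other dataset is aligned to the evolving table by the offset that
minimizes the summed squared difference of shifts over common motifs
(triplet codes or tagged motifs), the table means are updated after each
dataset, and the full pass is repeated (three rounds by default) until the
offsets converge.  During each alignment, records deviating from their
motif-group mean by more than ``sigma_k`` times the group rms error are
trimmed: excluded from both the offset fit and the table means, and logged.
Groups with fewer than three records are never trimmed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShiftRecord",
    "ShiftDataset",
    "LookupTableStats",
    "align_dataset_offset",
    "build_lookup_table",
]

NUCLEI = ("N15", "H1")


@dataclass(frozen=True)
class ShiftRecord:
    """One observed shift: residue label, motif key, nucleus, ppm."""

    label: str
    key: object  # TripletCode or motif tag (e.g. "UUCG-G")
    nucleus: str
    shift: float

    def __post_init__(self):
        if self.nucleus not in NUCLEI:
            raise ValueError(f"nucleus must be one of {NUCLEI}")


@dataclass
class ShiftDataset:
    """Records of one source (one BMRB entry / one sample) plus its offsets.

    A record's corrected shift is ``raw + offsets[nucleus]``; offsets start
    at zero and are assigned by the alignment procedure.
    """

    source_id: str
    records: list
    offsets: dict = field(default_factory=lambda: {n: 0.0 for n in NUCLEI})

    @classmethod
    def from_tsv(cls, path, source_id=None):
        """Read ``label  code  nucleus  ppm`` rows; codes parsed when possible."""
        from .triplet import TripletCode

        records = []
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = row["code"]
                try:
                    key = TripletCode.from_string(key)
                except ValueError:
                    pass  # motif tag
                records.append(ShiftRecord(row["label"], key, row["nucleus"],
                                           float(row["ppm"])))
        return cls(source_id or str(path), records)

    def corrected(self, record):
        return record.shift + self.offsets[record.nucleus]


class LookupTableStats:
    """Mean/sd/n per (motif key, nucleus) with the trimmed-record log."""

    def __init__(self):
        self._stats = {}
        self.trimmed = []  # (source_id, label, key, nucleus, corrected, z)

    def set(self, key, nucleus, mean, sd, n):
        self._stats[(key, nucleus)] = (mean, sd, n)

    def mean(self, key, nucleus):
        entry = self._stats.get((key, nucleus))
        return entry[0] if entry else None

    def entries(self):
        return dict(self._stats)

    def __contains__(self, key_nucleus):
        return key_nucleus in self._stats

    def __len__(self):
        return len(self._stats)

    def to_tsv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["code", "nucleus", "mean", "sd", "n"])
            for (key, nuc), (mean, sd, n) in sorted(
                    self._stats.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
                w.writerow([str(key), nuc, f"{mean:.3f}",
                            "" if sd is None else f"{sd:.3f}", n])


def align_dataset_offset(dataset: ShiftDataset, table: LookupTableStats):
    """Per-nucleus offsets aligning a dataset to a table.

    The least-squares offset is the mean residual ``table_mean - raw`` over
    records whose motif exists in the table. Nuclei with no common motif
    get offset 0 with a warning.
    """
    if not dataset.records:
        raise ValueError(f"dataset {dataset.source_id} is empty")
    offsets = {}
    for nucleus in NUCLEI:
        residuals = [
            table.mean(r.key, nucleus) - r.shift
            for r in dataset.records
            if r.nucleus == nucleus and (r.key, nucleus) in table
        ]
        if residuals:
            offsets[nucleus] = float(np.mean(residuals))
        else:
            if any(r.nucleus == nucleus for r in dataset.records):
                warnings.warn(
                    f"dataset {dataset.source_id}: no common {nucleus} motif "
                    "with the table; offset left at 0")
            offsets[nucleus] = 0.0
    return offsets


def _group_stats(items):
    """mean and rms error per (key, nucleus) over corrected values."""
    groups = {}
    for it in items:
        groups.setdefault((it["key"], it["nucleus"]), []).append(it["corr"])
    out = {}
    for gk, vals in groups.items():
        v = np.array(vals)
        out[gk] = (float(v.mean()), float(np.sqrt(np.mean((v - v.mean()) ** 2))),
                   len(vals))
    return out


def build_lookup_table(datasets, rounds=3, sigma_k=3.0):
    """Align datasets, trim outliers, and compute the motif shift table.

    Parameters
    ----------
    datasets : list of ShiftDataset
        The first dataset is the reference seed: its offsets stay at zero.
    rounds : int
        Full alignment passes over all datasets (default 3).
    sigma_k : float
        Trimming threshold in multiples of the group rms error (default 3).

    Returns
    -------
    (LookupTableStats, dict, list)
        Final table, per-dataset offsets ``{source_id: {nucleus: offset}}``,
        and the trimmed-record log.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    ids = [d.source_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset source_ids must be unique")

    # flat working list; corrected values updated as offsets move
    items = []
    for d in datasets:
        if not d.records:
            raise ValueError(f"dataset {d.source_id} is empty")
        for r in d.records:
            items.append({"source": d.source_id, "label": r.label, "key": r.key,
                          "nucleus": r.nucleus, "raw": r.shift, "corr": r.shift})
    offsets = {d.source_id: {n: 0.0 for n in NUCLEI} for d in datasets}
    trimmed_ids = set()

    def refresh(source):
        for it in items:
            if it["source"] == source:
                it["corr"] = it["raw"] + offsets[source][it["nucleus"]]

    def current_table(exclude_source=None):
        return _table_from_items(
            [it for i, it in enumerate(items)
             if it["source"] in included and i not in trimmed_ids
             and it["source"] != exclude_source])

    included = {datasets[0].source_id}
    for rnd in range(rounds):
        for d in datasets:
            is_ref = d.source_id == datasets[0].source_id
            # 1. provisional alignment of this dataset to the current table
            if not is_ref and included - {d.source_id}:
                offsets[d.source_id] = align_dataset_offset(
                    _as_dataset(d, items, trimmed_ids),
                    current_table(exclude_source=d.source_id))
                refresh(d.source_id)
            included.add(d.source_id)
            # 2. trim this dataset's records against leave-one-out group stats;
            # the group rms is floored by the pooled per-nucleus rms so that
            # small groups do not trim on an unstable scatter estimate
            pool = {}
            for i, it in enumerate(items):
                if it["source"] in included and i not in trimmed_ids:
                    pool.setdefault((it["key"], it["nucleus"]), []).append(
                        (i, it["corr"]))
            ss = {n: 0.0 for n in NUCLEI}
            df = {n: 0 for n in NUCLEI}
            for (key, nuc), members in pool.items():
                if len(members) >= 2:
                    v = np.array([c for _, c in members])
                    ss[nuc] += float(np.sum((v - v.mean()) ** 2))
                    df[nuc] += len(v) - 1
            pooled = {n: (np.sqrt(ss[n] / df[n]) if df[n] else 0.0) for n in NUCLEI}
            for idx, it in enumerate(items):
                if it["source"] != d.source_id:
                    continue
                gk = (it["key"], it["nucleus"])
                group = [v for i, v in pool.get(gk, []) if i != idx]
                if len(group) >= 3:
                    g = np.array(group)
                    mean = g.mean()
                    rms = pooled[it["nucleus"]]
                    if rms > 0 and abs(it["corr"] - mean) > sigma_k * rms:
                        trimmed_ids.add(idx)
                        continue
                trimmed_ids.discard(idx)
            # 3. refit the offset on the surviving records
            if not is_ref:
                offsets[d.source_id] = align_dataset_offset(
                    _as_dataset(d, items, trimmed_ids),
                    current_table(exclude_source=d.source_id))
                refresh(d.source_id)

    final_items = [it for i, it in enumerate(items) if i not in trimmed_ids]
    table = _table_from_items(final_items)
    table.trimmed = [
        (it["source"], it["label"], it["key"], it["nucleus"], it["corr"])
        for i, it in enumerate(items) if i in trimmed_ids
    ]
    dropped = set()
    for i in trimmed_ids:
        gk = (items[i]["key"], items[i]["nucleus"])
        if gk not in table and gk not in dropped:
            dropped.add(gk)
            warnings.warn(f"all records of {gk} trimmed; entry dropped")
    for d in datasets:
        d.offsets = dict(offsets[d.source_id])
    return table, offsets, table.trimmed


def _as_dataset(dataset, items, trimmed_ids):
    recs = [
        ShiftRecord(it["label"], it["key"], it["nucleus"], it["raw"])
        for i, it in enumerate(items)
        if it["source"] == dataset.source_id and i not in trimmed_ids
    ]
    return ShiftDataset(dataset.source_id, recs)


def _table_from_items(items):
    table = LookupTableStats()
    groups = {}
    for it in items:
        groups.setdefault((it["key"], it["nucleus"]), []).append(it["corr"])
    for (key, nuc), vals in groups.items():
        v = np.array(vals)
        sd = float(v.std(ddof=1)) if len(v) >= 2 else None
        table.set(key, nuc, float(v.mean()), sd, len(v))
    return table
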