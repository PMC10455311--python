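"""Variant data model: records, labeling, datasets and grouped splits.

A variant is a single amino acid substitution in a two-state folding
protein together with kinetic measurements.  The effect label is a pure
function of the log folding-rate change ``delta_lnkf`` and a symmetric
threshold band (default +/- 0.15): values below the band decrease the
rate, values above increase it, values inside have no effect.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from foldrate.constants import AA_SET

DEFAULT_THRESHOLD = 0.15

#: tolerance when both a rate pair and an explicit delta are supplied
RATE_DELTA_TOLERANCE = 1e-6

_SUBSTITUTION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class Label(str, enum.Enum):
    """Three-class folding-rate effect."""

    DECREASE = "decrease"
    NO_EFFECT = "no_effect"
    INCREASE = "increase"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: fixed class order used for voting tie-breaks and confusion layouts
CLASS_ORDER = (Label.DECREASE, Label.NO_EFFECT, Label.INCREASE)


class VariantError(ValueError):
    """Raised for invalid variant records or datasets."""


def compute_delta_lnkf(kf_var: float, kf_wt: float) -> float:
    """Log folding-rate change ``ln(kf_var) - ln(kf_wt)``.

    Parameters
    ----------
    kf_var, kf_wt
        Folding rates (s^-1) of the variant and wild-type protein.
        Both must be strictly positive.
    """
    if not (isinstance(kf_var, (int, float)) and kf_var > 0):
        raise VariantError(f"kf_var must be a positive rate, got {kf_var!r}")
    if not (isinstance(kf_wt, (int, float)) and kf_wt > 0):
        raise VariantError(f"kf_wt must be a positive rate, got {kf_wt!r}")
    return math.log(kf_var) - math.log(kf_wt)


def classify_delta(delta: float, threshold: float = DEFAULT_THRESHOLD) -> Label:
    """Map a log rate change onto the three-class label.

    The band is closed: ``|delta| == threshold`` counts as no effect.
    """
    if threshold <= 0:
        raise VariantError(f"threshold must be positive, got {threshold}")
    if not math.isfinite(delta):
        raise VariantError(f"delta_lnkf must be finite, got {delta}")
    if delta < -threshold:
        return Label.DECREASE
    if delta > threshold:
        return Label.INCREASE
    return Label.NO_EFFECT


@dataclass(frozen=True)
class VariantRecord:
    """One substitution with kinetic measurements and a derived label."""

    protein_id: str
    wt_aa: str
    position: int
    var_aa: str
    kf_wt: float | None = None
    kf_var: float | None = None
    delta_lnkf: float | None = None
    label: Label = field(init=False)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_SET:
            raise VariantError(f"unknown wild-type residue {self.wt_aa!r}")
        if self.var_aa not in AA_SET:
            raise VariantError(f"unknown variant residue {self.var_aa!r}")
        if self.wt_aa == self.var_aa:
            raise VariantError(
                f"{self.protein_id} {self.wt_aa}{self.position}{self.var_aa}: "
                "wild-type and variant residue are identical"
            )
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")

        have_rates = self.kf_wt is not None and self.kf_var is not None
        if have_rates:
            delta_from_rates = compute_delta_lnkf(self.kf_var, self.kf_wt)
            if self.delta_lnkf is not None:
                if abs(self.delta_lnkf - delta_from_rates) > RATE_DELTA_TOLERANCE:
                    raise VariantError(
                        f"{self.protein_id} {self.mutation}: supplied delta_lnkf "
                        f"{self.delta_lnkf:.6g} disagrees with rates "
                        f"(ln ratio {delta_from_rates:.6g})"
                    )
            else:
                object.__setattr__(self, "delta_lnkf", delta_from_rates)
        elif self.delta_lnkf is None:
            raise VariantError(
                f"{self.protein_id} {self.mutation}: need either both rates "
                "or delta_lnkf"
            )
        object.__setattr__(
            self, "label", classify_delta(self.delta_lnkf, self.threshold)
        )

    @property
    def mutation(self) -> str:
        """Compact ``A25F``-style notation."""
        return f"{self.wt_aa}{self.position}{self.var_aa}"

    @property
    def group_key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


def parse_mutation(text: str) -> tuple[str, int, str]:
    """Parse compact substitution notation like ``A25F``."""
    m = _SUBSTITUTION_RE.match(text.strip().upper())
    if m is None:
        raise VariantError(f"cannot parse substitution {text!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass
class VariantDataset:
    """An ordered collection of records plus their protein sequences."""

    records: list[VariantRecord]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for rec in self.records:
            seq = self.sequences.get(rec.protein_id)
            if seq is None:
                raise VariantError(
                    f"no sequence for protein {rec.protein_id!r}"
                )
            if rec.position > len(seq):
                raise VariantError(
                    f"{rec.protein_id} {rec.mutation}: position beyond "
                    f"sequence length {len(seq)}"
                )
            if seq[rec.position - 1] != rec.wt_aa:
                raise VariantError(
                    f"{rec.protein_id} {rec.mutation}: sequence holds "
                    f"{seq[rec.position - 1]!r} at position {rec.position}, "
                    f"record claims {rec.wt_aa!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[Label, int]:
        counts = Counter(rec.label for rec in self.records)
        return {lab: counts.get(lab, 0) for lab in CLASS_ORDER}

    @property
    def labels(self) -> list[Label]:
        return [rec.label for rec in self.records]

    @property
    def group_keys(self) -> list[tuple[str, int]]:
        return [rec.group_key for rec in self.records]

    def subset(self, indices: Iterable[int]) -> "VariantDataset":
        recs = [self.records[i] for i in indices]
        seqs = {r.protein_id: self.sequences[r.protein_id] for r in recs}
        return VariantDataset(records=recs, sequences=seqs)

    def summary(self) -> pd.DataFrame:
        """Class counts per protein plus a total row."""
        rows = []
        for pid in sorted({r.protein_id for r in self.records}):
            counts = Counter(r.label for r in self.records if r.protein_id == pid)
            rows.append(
                {
                    "protein_id": pid,
                    **{lab.value: counts.get(lab, 0) for lab in CLASS_ORDER},
                }
            )
        total = {"protein_id": "Total"}
        for lab in CLASS_ORDER:
            total[lab.value] = sum(row[lab.value] for row in rows)
        rows.append(total)
        df = pd.DataFrame(rows)
        df["total"] = sum(df[lab.value] for lab in CLASS_ORDER)
        return df


@dataclass(frozen=True)
class SplitSpec:
    """A group-disjoint train/test partition of record indices."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    grouping: str = "protein_id,position"

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.test_indices):
            raise VariantError("train and test indices overlap")


def _records_from_frame(df: pd.DataFrame, threshold: float) -> list[VariantRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if "substitution" in d and isinstance(d.get("substitution"), str):
            wt, pos, var = parse_mutation(d["substitution"])
        else:
            wt, pos, var = str(d["wt_aa"]), int(d["position"]), str(d["var_aa"])

        def _num(key):
            val = d.get(key)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return None
            return float(val)

        records.append(
            VariantRecord(
                protein_id=str(d["protein_id"]),
                wt_aa=wt,
                position=pos,
                var_aa=var,
                kf_wt=_num("kf_wt"),
                kf_var=_num("kf_var"),
                delta_lnkf=_num("delta_lnkf"),
                threshold=threshold,
            )
        )
    return records


def load_dataset(
    variants_path: str | Path,
    fasta_path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
) -> VariantDataset:
    """Load variants from a TSV and sequences from a FASTA file.

    The TSV must carry a header with ``protein_id`` and either a compact
    ``substitution`` column (``A25F``) or explicit ``wt_aa``/``position``/
    ``var_aa`` columns, plus ``kf_wt``+``kf_var`` and/or ``delta_lnkf``.
    Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(variants_path, sep="\t", comment="#")
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    records = _records_from_frame(df, threshold)
    return VariantDataset(records=records, sequences=sequences)


def write_dataset(
    dataset: VariantDataset,
    variants_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Write a dataset back to TSV (+ optional FASTA), including derived
    delta and label columns.  Round-trips exactly through
    :func:`load_dataset`."""
    rows = [
        {
            "protein_id": r.protein_id,
            "wt_aa": r.wt_aa,
            "position": r.position,
            "var_aa": r.var_aa,
            "kf_wt": r.kf_wt,
            "kf_var": r.kf_var,
            "delta_lnkf": repr(r.delta_lnkf),
            "label": r.label.value,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(variants_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for pid, seq in dataset.sequences.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def grouped_split(
    dataset: VariantDataset | Sequence[tuple[str, int]],
    test_fraction: float,
    seed: int,
) -> SplitSpec:
    """Split records into train/test keeping (protein, position) groups
    whole.

    Groups are shuffled with the seed and assigned to the test side
    greedily until the target fraction is reached, so the split is
    deterministic and group-disjoint by construction.
    """
    if not 0 < test_fraction < 1:
        raise VariantError(
            f"test_fraction must be in (0, 1), got {test_fraction}"
        )
    if isinstance(dataset, VariantDataset):
        keys = dataset.group_keys
    else:
        keys = list(dataset)
    n = len(keys)
    groups: dict[tuple[str, int], list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)

    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)

    target = test_fraction * n
    test: list[int] = []
    train: list[int] = []
    for key in order:
        members = groups[key]
        if len(test) < target:
            if len(members) > max(target, n - target):
                warnings.warn(
                    f"group {key} ({len(members)} records) exceeds the "
                    "capacity of one split side; assigned whole",
                    stacklevel=2,
                )
            test.extend(members)
        else:
            train.extend(members)
    return SplitSpec(
        train_indices=tuple(sorted(train)), test_indices=tuple(sorted(test))
    )


def validate_group_disjoint(
    train_keys: Iterable[tuple[str, int]],
    test_keys: Iterable[tuple[str, int]],
) -> None:
    """Raise if any (protein, position) group appears on both sides."""
    leak = set(train_keys) & set(test_keys)
    if leak:
        raise VariantError(
            "group leakage between train and test sets: "
            + ", ".join(f"{p}:{pos}" for p, pos in sorted(leak)[:10])
        )
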