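"""Assemble the full 1161-dimensional feature vector per variant.

Family layout (order is fixed and documented in feature names):

========== ==== =======================================================
family     size content
========== ==== =======================================================
amino_acid  688 553 single AAindex differences (var - wt) + 135
                residue-pair matrix lookups [wt, var]
conservation  3 C-score + two coevolution summaries
variation_type 436 one-hot 20x20 substitution cell + one-hot 6x6
                physicochemical-group cell
neighborhood 25 20 residue-type proportions + 5 class proportions in a
                25-position window centred on the variant site
protein_type  1 relative sequence position of the variant
structural    8 7-state secondary structure one-hot + RSA
========== ==== =======================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from foldrate.constants import (
    AMINO_ACIDS,
    AA_SET,
    SS7_STATES,
    WINDOW_GROUPS,
    six_group_of,
)
from foldrate.features.aaindex import AAIndexTable, load_default_table
from foldrate.features.conservation import (
    FEATURE_NAMES as CONSERVATION_NAMES,
    ConservationAnnotation,
)
from foldrate.features.structure import StructuralAnnotation
from foldrate.variant_data import VariantRecord

FAMILY_SIZES = {
    "amino_acid": 688,
    "conservation": 3,
    "variation_type": 436,
    "neighborhood": 25,
    "protein_type": 1,
    "structural": 8,
}
FAMILY_ORDER = tuple(FAMILY_SIZES)
TOTAL_FEATURES = sum(FAMILY_SIZES.values())  # 1161

DEFAULT_WINDOW_HALFWIDTH = 12  # 25-position window

GROUP_NAMES = ("g1", "g2", "g3", "g4", "g5", "g6")

WINDOW_GROUP_ORDER = ("NonPolarAA", "PolarAA", "ChargedAA", "PosAA", "NegAA")


class FeatureError(ValueError):
    pass


@lru_cache(maxsize=1)
def load_residue_groups(path: str | None = None) -> dict[str, frozenset]:
    """Six-way residue partition for the 6x6 variation-type matrix,
    read from a JSON config mapping group name -> residue string."""
    if path is None:
        path = str(
            resources.files("foldrate.features") / "data" / "residue_groups.json"
        )
    raw = json.loads(Path(path).read_text())
    groups = {name: frozenset(members) for name, members in raw.items()}
    covered = set().union(*groups.values())
    if covered != AA_SET:
        raise FeatureError(
            "residue group partition must cover the 20 standard residues; "
            f"missing {sorted(AA_SET - covered)}"
        )
    for name, members in groups.items():
        for other, others in groups.items():
            if name < other and members & others:
                raise FeatureError(
                    f"groups {name} and {other} overlap: "
                    f"{sorted(members & others)}"
                )
    return groups


@dataclass(frozen=True)
class FeatureVector:
    """Ordered numeric features with names and family ranges."""

    values: np.ndarray
    names: tuple[str, ...]
    families: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise FeatureError("values and names must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise FeatureError(f"unknown feature {name!r}") from None

    def family(self, name: str) -> np.ndarray:
        start, stop = self.families[name]
        return self.values[start:stop]


def aaindex_features(
    wt_aa: str, var_aa: str, table: AAIndexTable | None = None
) -> np.ndarray:
    """688 amino-acid features (see :meth:`AAIndexTable.features`)."""
    table = table or load_default_table()
    return table.features(wt_aa, var_aa)


def variation_type_features(
    wt_aa: str, var_aa: str, groups: Mapping[str, frozenset] | None = None
) -> np.ndarray:
    """One-hot 20x20 substitution cell + one-hot 6x6 group cell.

    436 values with exactly two ones: cell (wt, var) of the residue
    matrix and cell (group(wt), group(var)) of the group matrix.
    """
    for aa in (wt_aa, var_aa):
        if aa not in AA_SET:
            raise FeatureError(f"unknown residue {aa!r}")
    groups = groups or load_residue_groups()
    out = np.zeros(436)
    out[AMINO_ACIDS.index(wt_aa) * 20 + AMINO_ACIDS.index(var_aa)] = 1.0
    names = sorted(groups)
    gi = names.index(six_group_of(wt_aa, groups))
    gj = names.index(six_group_of(var_aa, groups))
    out[400 + gi * len(names) + gj] = 1.0
    return out


def neighborhood_features(
    sequence: str,
    position: int,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> np.ndarray:
    """Residue-type and residue-class proportions around the variant.

    The window spans ``position +/- window_halfwidth`` truncated at the
    sequence ends; proportions are normalised by the number of residues
    actually inside the window (variant site included).
    """
    if not 1 <= position <= len(sequence):
        raise FeatureError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    lo = max(0, position - 1 - window_halfwidth)
    hi = min(len(sequence), position + window_halfwidth)
    window = sequence[lo:hi]
    size = len(window)
    out = np.zeros(25)
    for aa in window:
        if aa in AA_SET:
            out[AMINO_ACIDS.index(aa)] += 1.0
    out[:20] /= size
    for k, gname in enumerate(WINDOW_GROUP_ORDER):
        members = WINDOW_GROUPS[gname]
        out[20 + k] = sum(1 for aa in window if aa in members) / size
    return out


def relative_position(position: int, sequence_length: int) -> float:
    """Variant position normalised by sequence length, in (0, 1]."""
    if not 1 <= position <= sequence_length:
        raise FeatureError(
            f"position {position} out of range 1..{sequence_length}"
        )
    return position / sequence_length


def structural_features(
    annotation: StructuralAnnotation, position: int, residue: str
) -> np.ndarray:
    """7-state secondary-structure one-hot followed by RSA."""
    if not annotation.covers(position):
        from foldrate.features.structure import MissingStructureError

        raise MissingStructureError(
            f"position {position} has no structural annotation"
        )
    return np.concatenate(
        [annotation.ss_onehot(position), [annotation.rsa(position, residue)]]
    )


@lru_cache(maxsize=None)
def feature_names(
    aaindex_names: tuple[str, ...] | None = None,
) -> tuple[str, ...]:
    """The full ordered feature-name list."""
    if aaindex_names is None:
        aaindex_names = tuple(load_default_table().feature_names)
    names = list(aaindex_names)
    names += list(CONSERVATION_NAMES)
    names += [f"{wt}_{var}" for wt in AMINO_ACIDS for var in AMINO_ACIDS]
    names += [f"{gi}_{gj}" for gi in GROUP_NAMES for gj in GROUP_NAMES]
    names += [f"window_{aa}" for aa in AMINO_ACIDS]
    names += [f"window_{g}" for g in WINDOW_GROUP_ORDER]
    names += ["rp"]
    names += [f"ss_{s}" for s in SS7_STATES]
    names += ["rsa"]
    return tuple(names)


def _family_ranges() -> dict[str, tuple[int, int]]:
    ranges = {}
    start = 0
    for fam in FAMILY_ORDER:
        ranges[fam] = (start, start + FAMILY_SIZES[fam])
        start += FAMILY_SIZES[fam]
    return ranges


def featurize(
    record: VariantRecord,
    sequence: str,
    structure: StructuralAnnotation,
    conservation: ConservationAnnotation,
    aaindex_table: AAIndexTable | None = None,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> FeatureVector:
    """Compute all six feature families for one variant.

    A pure function of its inputs: repeated calls return identical
    vectors.  Family-level failures are re-raised with the family named.
    """
    aaindex_table = aaindex_table or load_default_table()
    parts = []
    stages = (
        ("amino_acid",
         lambda: aaindex_features(record.wt_aa, record.var_aa, aaindex_table)),
        ("conservation", lambda: conservation.features(record.position)),
        ("variation_type",
         lambda: variation_type_features(record.wt_aa, record.var_aa)),
        ("neighborhood",
         lambda: neighborhood_features(
             sequence, record.position, window_halfwidth)),
        ("protein_type",
         lambda: np.array([relative_position(record.position, len(sequence))])),
        ("structural",
         lambda: structural_features(structure, record.position, record.wt_aa)),
    )
    for family, fn in stages:
        try:
            part = np.asarray(fn(), dtype=float)
        except Exception as exc:
            raise FeatureError(
                f"{family} features failed for {record.protein_id} "
                f"{record.mutation}: {exc}"
            ) from exc
        if len(part) != FAMILY_SIZES[family]:
            raise FeatureError(
                f"{family} produced {len(part)} values, expected "
                f"{FAMILY_SIZES[family]}"
            )
        parts.append(part)
    return FeatureVector(
        values=np.concatenate(parts),
        names=feature_names(tuple(aaindex_table.feature_names)),
        families=_family_ranges(),
    )


def featurize_dataset(
    dataset,
    structures: Mapping[str, StructuralAnnotation],
    conservations: Mapping[str, ConservationAnnotation],
    aaindex_table: AAIndexTable | None = None,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> pd.DataFrame:
    """Feature matrix for every record of a dataset (rows align with
    ``dataset.records``)."""
    aaindex_table = aaindex_table or load_default_table()
    vectors = []
    for rec in dataset.records:
        fv = featurize(
            rec,
            dataset.sequences[rec.protein_id],
            structures[rec.protein_id],
            conservations[rec.protein_id],
            aaindex_table,
            window_halfwidth,
        )
        vectors.append(fv.values)
    names = feature_names(tuple(aaindex_table.feature_names))
    return pd.DataFrame(np.vstack(vectors), columns=list(names))


def select_named_subset(
    vector: FeatureVector, names: Iterable[str]
) -> FeatureVector:
    """Project a vector onto an ordered list of feature names."""
    names = tuple(names)
    index = {n: i for i, n in enumerate(vector.names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise FeatureError(f"unknown feature names: {missing}")
    values = vector.values[[index[n] for n in names]]
    return FeatureVector(
        values=values, names=names, families={"selected": (0, len(names))}
    )


def load_feature_subset(name_or_path: str) -> tuple[str, ...]:
    """Resolve a feature-subset name to its ordered feature list.

    ``classifier31`` and ``regressor21`` are bundled (the published
    selected sets for the two tasks); any other value is read as a path
    to a newline-separated list.
    """
    bundled = {"classifier31", "regressor21"}
    if name_or_path in bundled:
        path = resources.files("foldrate.features") / "data" / (
            name_or_path + ".txt"
        )
    else:
        path = Path(name_or_path)
    lines = Path(str(path)).read_text().splitlines()
    return tuple(
        ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")
    )
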