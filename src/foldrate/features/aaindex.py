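"""Reader for AAindex-style flat files and the bundled index tables.

The flat-file format is the one used by the AAindex database: records
are separated by ``//``; an ``H`` line carries the accession, an ``I``
line starts a single-residue index (two rows of ten values in
A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V order) and an ``M`` line starts
a residue-pair matrix (``M rows = ..., cols = ...`` followed by either a
lower-triangular or a full matrix).  Indices containing missing values
(``NA``) are excluded, mirroring the published feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from foldrate.constants import AMINO_ACIDS

#: residue order of the two value rows of an ``I`` block
_I_ORDER = ("ARNDCQEGHI", "LKMFPSTWYV")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class AAIndexError(ValueError):
    pass


def _parse_values(tokens: list[str]) -> list[float]:
    vals = []
    for tok in tokens:
        if tok in ("NA", "-", "NA.") or tok.startswith("NA"):
            vals.append(math.nan)
        else:
            vals.append(float(tok))
    return vals


def parse_aaindex_flat(text: str) -> list[dict]:
    """Parse one flat file into raw entry dicts.

    Each entry has ``id``, ``description`` and either ``single`` (map
    residue -> value) or ``matrix`` (20x20 array in alphabetical residue
    order) plus ``symmetric`` for matrices.
    """
    entries = []
    for chunk in text.split("\n//"):
        lines = [ln for ln in chunk.splitlines() if ln.strip()]
        if not lines:
            continue
        entry: dict = {"id": None, "description": ""}
        i = 0
        while i < len(lines):
            line = lines[i]
            tag = line[:1]
            if tag == "H":
                entry["id"] = line[1:].strip()
            elif tag == "D":
                entry["description"] = line[1:].strip()
            elif tag == "I" and "=" not in line:
                row1 = _parse_values(lines[i + 1].split())
                row2 = _parse_values(lines[i + 2].split())
                i += 2
                single = {}
                for aa, v in zip(_I_ORDER[0], row1):
                    single[aa] = v
                for aa, v in zip(_I_ORDER[1], row2):
                    single[aa] = v
                entry["single"] = single
            elif tag == "M" and "rows" in line:
                spec = line[1:].replace(",", " ").split()
                rows_aa = spec[spec.index("rows") + 2]
                cols_aa = spec[spec.index("cols") + 2]
                nrows = len(rows_aa)
                value_rows = [
                    _parse_values(ln.split())
                    for ln in lines[i + 1 : i + 1 + nrows]
                ]
                i += nrows
                entry.update(
                    _build_matrix(entry["id"], rows_aa, cols_aa, value_rows)
                )
            i += 1
        if entry["id"] and ("single" in entry or "matrix" in entry):
            entries.append(entry)
    return entries


def _build_matrix(
    entry_id: str, rows_aa: str, cols_aa: str, value_rows: list[list[float]]
) -> dict:
    nrows, ncols = len(rows_aa), len(cols_aa)
    if len(value_rows) < nrows:
        raise AAIndexError(f"{entry_id}: expected {nrows} matrix rows")
    value_rows = value_rows[:nrows]
    lower = all(len(r) == i + 1 for i, r in enumerate(value_rows))
    mat = np.full((20, 20), math.nan)
    if lower and nrows == ncols:
        symmetric = True
        for i, row in enumerate(value_rows):
            for j, v in enumerate(row):
                a, b = rows_aa[i], cols_aa[j]
                if a in _AA_INDEX and b in _AA_INDEX:
                    mat[_AA_INDEX[a], _AA_INDEX[b]] = v
                    mat[_AA_INDEX[b], _AA_INDEX[a]] = v
    else:
        symmetric = False
        for i, row in enumerate(value_rows):
            if len(row) != ncols:
                raise AAIndexError(
                    f"{entry_id}: row {i} has {len(row)} values, "
                    f"expected {ncols}"
                )
            for j, v in enumerate(row):
                a, b = rows_aa[i], cols_aa[j]
                if a in _AA_INDEX and b in _AA_INDEX:
                    mat[_AA_INDEX[a], _AA_INDEX[b]] = v
        symmetric = bool(
            np.allclose(mat, mat.T, equal_nan=True)
        )
    return {"matrix": mat, "symmetric": symmetric}


@dataclass
class AAIndexTable:
    """Complete single-residue and residue-pair index tables.

    ``single_indices`` maps index id -> {residue -> value} and
    ``pair_indices`` maps index id -> 20x20 array (alphabetical residue
    order on both axes).  Only complete indices (all 20 residues / all
    400 cells) are kept.
    """

    single_indices: dict[str, dict[str, float]]
    pair_indices: dict[str, np.ndarray]
    symmetric: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iid, vals in self.single_indices.items():
            if set(vals) != set(AMINO_ACIDS) or any(
                not math.isfinite(v) for v in vals.values()
            ):
                raise AAIndexError(f"single index {iid} is incomplete")
        for iid, mat in self.pair_indices.items():
            if mat.shape != (20, 20) or not np.isfinite(mat).all():
                raise AAIndexError(f"pair index {iid} is incomplete")

    @property
    def single_ids(self) -> list[str]:
        return sorted(self.single_indices)

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.pair_indices)

    @property
    def feature_names(self) -> list[str]:
        return self.single_ids + self.pair_ids

    def is_symmetric(self, pair_id: str) -> bool:
        return self.symmetric[pair_id]

    @classmethod
    def from_files(cls, paths: Iterable[str | Path]) -> "AAIndexTable":
        singles: dict[str, dict[str, float]] = {}
        pairs: dict[str, np.ndarray] = {}
        symmetric: dict[str, bool] = {}
        for path in paths:
            for entry in parse_aaindex_flat(Path(path).read_text()):
                if "single" in entry:
                    vals = entry["single"]
                    if len(vals) == 20 and all(
                        math.isfinite(v) for v in vals.values()
                    ):
                        singles[entry["id"]] = vals
                elif "matrix" in entry:
                    if np.isfinite(entry["matrix"]).all():
                        pairs[entry["id"]] = entry["matrix"]
                        symmetric[entry["id"]] = entry["symmetric"]
        return cls(
            single_indices=singles, pair_indices=pairs, symmetric=symmetric
        )

    def features(self, wt_aa: str, var_aa: str) -> np.ndarray:
        """688 amino-acid features for one substitution.

        Single indices contribute ``value(var) - value(wt)``; pair
        indices contribute the (wt, var) matrix cell.
        """
        for aa in (wt_aa, var_aa):
            if aa not in _AA_INDEX:
                raise AAIndexError(f"unknown residue {aa!r}")
        out = np.empty(len(self.single_indices) + len(self.pair_indices))
        k = 0
        for iid in self.single_ids:
            vals = self.single_indices[iid]
            out[k] = vals[var_aa] - vals[wt_aa]
            k += 1
        wi, vi = _AA_INDEX[wt_aa], _AA_INDEX[var_aa]
        for iid in self.pair_ids:
            out[k] = self.pair_indices[iid][wi, vi]
            k += 1
        return out


def _data_dir() -> Path:
    return Path(resources.files("foldrate.features") / "data")


@lru_cache(maxsize=1)
def load_default_table() -> AAIndexTable:
    """Load the bundled index tables (553 single + 135 pair indices)."""
    d = _data_dir()
    return AAIndexTable.from_files(
        [d / "aaindex_single.txt", d / "aaindex_pair.txt"]
    )
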