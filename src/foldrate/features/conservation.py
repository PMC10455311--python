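"""Per-position conservation and coevolution annotation.

The three conservation features per variant position are a ConSurf-style
conservation score plus two coevolution summaries derived from a
precomputed residue-coupling table: the maximum coupling strength of the
position and the number of coupling partners above a strength quantile.
These stand in for the original pipeline's external tools, whose exact
feature composition is not published; the tables are consumed as TSV.

A fallback computes the conservation score from a user-supplied multiple
sequence alignment as 1 minus the column's normalised Shannon entropy.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

FEATURE_NAMES = ("C-score", "coev_max", "coev_partners")


class ConservationError(ValueError):
    pass


@dataclass
class ConservationAnnotation:
    """Maps 1-based position -> (c_score, coev_max, coev_partners)."""

    scores: dict[int, tuple[float, float, float]]

    def covers(self, position: int) -> bool:
        return position in self.scores

    def features(self, position: int) -> np.ndarray:
        if position not in self.scores:
            raise ConservationError(
                f"no conservation annotation for position {position}"
            )
        return np.asarray(self.scores[position], dtype=float)

    @classmethod
    def from_tsv(
        cls, path: str | Path, protein_id: str | None = None
    ) -> "ConservationAnnotation":
        """Columns: (protein_id,) position, c_score, coev_max,
        coev_partners."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if protein_id is not None and "protein_id" in df.columns:
            df = df[df["protein_id"] == protein_id]
        scores = {
            int(row.position): (
                float(row.c_score),
                float(row.coev_max),
                float(row.coev_partners),
            )
            for row in df.itertuples(index=False)
        }
        return cls(scores=scores)

    @classmethod
    def from_alignment(
        cls, path: str | Path, fmt: str = "fasta"
    ) -> "ConservationAnnotation":
        """Entropy-based fallback when no precomputed scores exist.

        c_score is ``1 - H/ln(20)`` per ungapped column of the first
        sequence; the two coevolution features are set to 0 (no coupling
        information available from an alignment alone).
        """
        aln = AlignIO.read(str(path), fmt)
        ref = str(aln[0].seq)
        scores: dict[int, tuple[float, float, float]] = {}
        pos = 0
        for col in range(aln.get_alignment_length()):
            if ref[col] == "-":
                continue
            pos += 1
            column = [
                rec.seq[col] for rec in aln if rec.seq[col] not in "-.X"
            ]
            if not column:
                scores[pos] = (0.0, 0.0, 0.0)
                continue
            counts = Counter(column)
            total = sum(counts.values())
            h = -sum(
                (c / total) * math.log(c / total) for c in counts.values()
            )
            scores[pos] = (1.0 - h / math.log(20), 0.0, 0.0)
        return cls(scores=scores)


def coupling_summaries(
    coupling: pd.DataFrame, n_positions: int, quantile: float = 0.9
) -> pd.DataFrame:
    """Summarise a pairwise coupling table into the two per-position
    coevolution features.

    ``coupling`` needs columns pos_i, pos_j, strength.  Returns a frame
    with position, coev_max and coev_partners (count of partners whose
    coupling exceeds the table-wide strength quantile).
    """
    if coupling.empty:
        raise ConservationError("empty coupling table")
    cut = float(coupling["strength"].quantile(quantile))
    best: dict[int, float] = {p: 0.0 for p in range(1, n_positions + 1)}
    npart: dict[int, int] = {p: 0 for p in range(1, n_positions + 1)}
    for row in coupling.itertuples(index=False):
        for p in (int(row.pos_i), int(row.pos_j)):
            if p in best:
                best[p] = max(best[p], float(row.strength))
                if row.strength > cut:
                    npart[p] += 1
    return pd.DataFrame(
        {
            "position": list(best),
            "coev_max": [best[p] for p in best],
            "coev_partners": [npart[p] for p in best],
        }
    )
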