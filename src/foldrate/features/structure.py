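"""Structural annotation: secondary structure, solvent accessibility.

Per-residue annotation is normally consumed from a TSV produced by an
external assignment tool (7-state secondary structure + ASA).  A
reference accessible-surface-area computation is also provided: the
Shrake-Rupley algorithm with a 1.4 A probe on deterministic sphere
points, applied to PDB coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from foldrate.constants import (
    AA3_TO_1,
    DEFAULT_VDW_RADIUS,
    MAX_ASA,
    PROBE_RADIUS,
    SS7_STATES,
    VDW_RADII,
)


class StructureError(ValueError):
    pass


class MissingStructureError(StructureError):
    """A required position has no structural annotation."""


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent accessible surface area (A^2).

    Each atom's expanded sphere (vdW + probe) is sampled at ``n_points``
    fixed points; the accessible area is the unoccluded fraction times
    the sphere area.  Deterministic for a fixed point count.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n_atoms = len(coords)
    unit = sphere_points(n_points)
    areas = np.empty(n_atoms)
    # pairwise neighbor lists: only atoms whose expanded spheres overlap
    # can occlude sample points
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cutoff = radii[:, None] + radii[None, :]
    for i in range(n_atoms):
        neighbors = np.where((dist[i] < cutoff[i]) & (np.arange(n_atoms) != i))[0]
        pts = coords[i] + radii[i] * unit
        if neighbors.size:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(
                axis=-1
            )
            buried = (d2 < radii[neighbors][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * radii[i] ** 2
    return areas


def _atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def compute_asa(
    pdb_path: str | Path,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-residue accessible surface area from a PDB file.

    Reads ATOM records of the first model (altloc 'A' preferred,
    hydrogens and waters skipped), runs Shrake-Rupley over all retained
    atoms and sums per residue.  Residues missing any backbone atom
    (N, CA, C) are flagged unannotated with NaN area.

    Returns a frame with columns chain, resnum, resname, aa, asa,
    annotated.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())

    rows = []  # (chain, resnum, resname)
    coords, radii, owner = [], [], []
    backbone_seen: dict[tuple, set] = {}
    for chain in model:
        for res in chain:
            hetflag, resnum, _ = res.id
            if hetflag.strip():
                continue
            key = (chain.id, resnum, res.resname)
            if key not in backbone_seen:
                backbone_seen[key] = set()
                rows.append(key)
            for atom in res:
                if atom.element == "H":
                    continue
                altloc = atom.get_altloc()
                if altloc not in (" ", "", "A"):
                    continue
                if atom.get_name() in ("N", "CA", "C"):
                    backbone_seen[key].add(atom.get_name())
                coords.append(atom.get_coord())
                radii.append(_atom_radius(atom.element or "C"))
                owner.append(key)
    if not coords:
        raise StructureError(f"no ATOM coordinates found in {pdb_path}")

    areas = shrake_rupley(
        np.array(coords), np.array(radii), probe_radius, n_points
    )
    per_res = {key: 0.0 for key in rows}
    for key, a in zip(owner, areas):
        per_res[key] += a

    out = []
    for chain_id, resnum, resname in rows:
        key = (chain_id, resnum, resname)
        ok = backbone_seen[key] >= {"N", "CA", "C"}
        if not ok:
            warnings.warn(
                f"residue {chain_id}:{resnum} {resname} lacks backbone "
                "atoms; flagged unannotated",
                stacklevel=2,
            )
        out.append(
            {
                "chain": chain_id,
                "resnum": resnum,
                "resname": resname,
                "aa": AA3_TO_1.get(resname, "X"),
                "asa": per_res[key] if ok else math.nan,
                "annotated": ok,
            }
        )
    return pd.DataFrame(out)


@dataclass
class StructuralAnnotation:
    """Per-residue 7-state secondary structure and solvent accessibility
    for one protein.  Positions are 1-based sequence indices."""

    ss: dict[int, str]
    asa: dict[int, float]

    def __post_init__(self) -> None:
        bad = {p: s for p, s in self.ss.items() if s not in SS7_STATES}
        if bad:
            raise StructureError(
                f"unknown secondary structure classes: {bad}"
            )

    def covers(self, position: int) -> bool:
        return position in self.ss and position in self.asa

    def rsa(self, position: int, residue: str) -> float:
        """Relative solvent accessibility ASA / maxASA of the residue."""
        if position not in self.asa:
            raise MissingStructureError(
                f"no ASA annotation for position {position}"
            )
        if residue not in MAX_ASA:
            raise StructureError(f"no maxASA for residue {residue!r}")
        return self.asa[position] / MAX_ASA[residue]

    def ss_onehot(self, position: int) -> np.ndarray:
        if position not in self.ss:
            raise MissingStructureError(
                f"no secondary structure annotation for position {position}"
            )
        vec = np.zeros(len(SS7_STATES))
        vec[SS7_STATES.index(self.ss[position])] = 1.0
        return vec

    @classmethod
    def from_tsv(
        cls, path: str | Path, protein_id: str | None = None
    ) -> "StructuralAnnotation":
        """Read a per-residue annotation table with columns
        (protein_id,) position, ss_class, asa."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if protein_id is not None and "protein_id" in df.columns:
            df = df[df["protein_id"] == protein_id]
        return cls(
            ss=dict(zip(df["position"].astype(int), df["ss_class"])),
            asa=dict(zip(df["position"].astype(int), df["asa"].astype(float))),
        )

    @classmethod
    def from_pdb(
        cls,
        pdb_path: str | Path,
        ss: dict[int, str] | None = None,
        chain: str | None = None,
    ) -> "StructuralAnnotation":
        """Build an annotation from coordinates via :func:`compute_asa`.

        Secondary structure cannot be derived here; positions default to
        coil unless ``ss`` overrides them.  Residue numbers are taken as
        sequence positions.
        """
        table = compute_asa(pdb_path)
        if chain is not None:
            table = table[table["chain"] == chain]
        table = table[table["annotated"]]
        asa = dict(zip(table["resnum"].astype(int), table["asa"]))
        ss = ss or {}
        return cls(ss={p: ss.get(p, "C") for p in asa}, asa=asa)
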