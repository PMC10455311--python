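"""Self-contained synthetic proteins, annotations and variant sets.

The generator plants a statistical (not biophysical) signal: the log
folding-rate change is a linear function of a chosen feature subset
plus Gaussian noise, optionally calibrated through a rank-based normal
transform so that the three class proportions match a target (default
mimics the real data's 653:175:124 split).  Everything is deterministic
per seed, and the emitted TSV/FASTA/PDB files are exactly the formats
the pipeline consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from foldrate.constants import AMINO_ACIDS, MAX_ASA, SS7_STATES
from foldrate.features.conservation import ConservationAnnotation
from foldrate.features.featurize import (
    DEFAULT_WINDOW_HALFWIDTH,
    neighborhood_features,
    relative_position,
)
from foldrate.features.structure import StructuralAnnotation
from foldrate.variant_data import (
    DEFAULT_THRESHOLD,
    VariantDataset,
    VariantRecord,
    write_dataset,
)

#: class proportions of the full real data (decrease, no effect, increase)
DEFAULT_PROPORTIONS = (653, 175, 124)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_proteins: int = 6
    length_range: tuple[int, int] = (60, 120)
    n_variants: int = 300
    class_proportions: tuple[int, int, int] = DEFAULT_PROPORTIONS
    signal_weights: dict = field(
        default_factory=lambda: {"rsa": 1.0, "rp": 0.6, "C-score": 0.8}
    )
    noise_sigma: float = 0.1
    threshold: float = DEFAULT_THRESHOLD
    alanine_bias: float = 0.0  # probability that the variant residue is A
    calibrate: bool = True
    seed: int = 0


@dataclass
class SyntheticData:
    """A generated dataset with its annotations and ground truth."""

    dataset: VariantDataset
    structures: dict[str, StructuralAnnotation]
    conservations: dict[str, ConservationAnnotation]
    weights: dict[str, float]
    spec: SyntheticSpec

    def write_files(self, directory: str | Path) -> dict[str, Path]:
        """Emit variants.tsv / sequences.fasta / structure.tsv /
        conservation.tsv under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": directory / "variants.tsv",
            "fasta": directory / "sequences.fasta",
            "structure": directory / "structure.tsv",
            "conservation": directory / "conservation.tsv",
        }
        write_dataset(self.dataset, paths["variants"], paths["fasta"])
        with open(paths["structure"], "w") as fh:
            fh.write("protein_id\tposition\tss_class\tasa\n")
            for pid in sorted(self.structures):
                ann = self.structures[pid]
                for pos in sorted(ann.ss):
                    fh.write(
                        f"{pid}\t{pos}\t{ann.ss[pos]}\t{ann.asa[pos]:.4f}\n"
                    )
        with open(paths["conservation"], "w") as fh:
            fh.write("protein_id\tposition\tc_score\tcoev_max\tcoev_partners\n")
            for pid in sorted(self.conservations):
                ann = self.conservations[pid]
                for pos in sorted(ann.scores):
                    c, m, p = ann.scores[pos]
                    fh.write(f"{pid}\t{pos}\t{c:.6f}\t{m:.6f}\t{p:.6f}\n")
        return paths


def _planted_feature_value(
    name: str,
    sequence: str,
    position: int,
    structure: StructuralAnnotation,
    conservation: ConservationAnnotation,
) -> float:
    """Value of one generator-supported feature for a variant site."""
    if name == "rsa":
        return structure.rsa(position, sequence[position - 1])
    if name == "rp":
        return relative_position(position, len(sequence))
    if name in ("C-score", "coev_max", "coev_partners"):
        idx = ("C-score", "coev_max", "coev_partners").index(name)
        return float(conservation.features(position)[idx])
    if name.startswith("window_"):
        vec = neighborhood_features(sequence, position, DEFAULT_WINDOW_HALFWIDTH)
        from foldrate.features.featurize import feature_names as _  # noqa: F401
        from foldrate.features.featurize import WINDOW_GROUP_ORDER

        key = name[len("window_") :]
        if key in AMINO_ACIDS:
            return float(vec[AMINO_ACIDS.index(key)])
        if key in WINDOW_GROUP_ORDER:
            return float(vec[20 + WINDOW_GROUP_ORDER.index(key)])
    raise SyntheticError(
        f"signal weight on {name!r}: the generator only supports rsa, rp, "
        "conservation and window_* features"
    )


def _random_structure(
    rng: np.random.Generator, sequence: str
) -> StructuralAnnotation:
    ss: dict[int, str] = {}
    asa: dict[int, float] = {}
    state = rng.choice(SS7_STATES)
    for pos, aa in enumerate(sequence, start=1):
        if rng.random() > 0.8:
            state = rng.choice(SS7_STATES)
        ss[pos] = str(state)
        asa[pos] = float(rng.uniform(0.0, MAX_ASA[aa]))
    return StructuralAnnotation(ss=ss, asa=asa)


def _random_conservation(
    rng: np.random.Generator, length: int
) -> ConservationAnnotation:
    return ConservationAnnotation(
        scores={
            pos: (
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 2)),
                float(rng.integers(0, 8)),
            )
            for pos in range(1, length + 1)
        }
    )


def _calibration(proportions, threshold: float) -> tuple[float, float]:
    """Affine map placing normal scores so that the class proportions
    land at the threshold band edges."""
    dec, no, inc = proportions
    total = dec + no + inc
    z_lo = norm.ppf(dec / total)
    z_hi = norm.ppf(1 - inc / total)
    scale = 2 * threshold / (z_hi - z_lo)
    loc = -threshold - scale * z_lo
    return loc, scale


def generate_dataset(spec: SyntheticSpec) -> SyntheticData:
    """Generate a full synthetic dataset per ``spec``.

    With ``calibrate=True`` the linear signal is passed through a
    rank-based normal transform and an affine map so that class counts
    match the requested proportions up to sampling error while the
    feature ordering (and hence the learnable signal) is preserved.
    With ``calibrate=False`` the raw linear model
    ``delta = w . features + N(0, sigma)`` is used unchanged.
    """
    if spec.n_variants < 1 or spec.n_proteins < 1:
        raise SyntheticError("need at least one protein and one variant")
    lo, hi = spec.length_range
    if lo < 2 * DEFAULT_WINDOW_HALFWIDTH + 1:
        raise SyntheticError(
            f"minimum protein length {lo} shorter than the feature window"
        )
    rng = np.random.default_rng(spec.seed)
    aas = list(AMINO_ACIDS)

    sequences: dict[str, str] = {}
    structures: dict[str, StructuralAnnotation] = {}
    conservations: dict[str, ConservationAnnotation] = {}
    for i in range(spec.n_proteins):
        pid = f"SYN{i+1:03d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length))
        sequences[pid] = seq
        structures[pid] = _random_structure(rng, seq)
        conservations[pid] = _random_conservation(rng, length)

    pids = sorted(sequences)
    sites = []
    for _ in range(spec.n_variants):
        pid = pids[int(rng.integers(len(pids)))]
        seq = sequences[pid]
        position = int(rng.integers(1, len(seq) + 1))
        wt = seq[position - 1]
        if spec.alanine_bias > 0 and wt != "A" and rng.random() < spec.alanine_bias:
            var = "A"
        else:
            var = wt
            while var == wt:
                var = str(rng.choice(aas))
        sites.append((pid, position, wt, var))

    # planted linear signal over standardised feature columns
    signal = np.zeros(spec.n_variants)
    for name, weight in spec.signal_weights.items():
        col = np.array(
            [
                _planted_feature_value(
                    name, sequences[pid], pos, structures[pid],
                    conservations[pid],
                )
                for pid, pos, _, _ in sites
            ]
        )
        sd = col.std()
        if spec.calibrate and sd > 0:
            col = (col - col.mean()) / sd
        signal += weight * col
    noise = rng.normal(0.0, spec.noise_sigma, spec.n_variants)
    raw = signal + noise

    if spec.calibrate:
        loc, scale = _calibration(spec.class_proportions, spec.threshold)
        order = np.argsort(np.argsort(raw, kind="stable"), kind="stable")
        normal_scores = norm.ppf((order + 0.5) / spec.n_variants)
        deltas = loc + scale * normal_scores
    else:
        deltas = raw

    records = [
        VariantRecord(
            protein_id=pid,
            wt_aa=wt,
            position=pos,
            var_aa=var,
            delta_lnkf=float(d),
            threshold=spec.threshold,
        )
        for (pid, pos, wt, var), d in zip(sites, deltas)
    ]
    dataset = VariantDataset(records=records, sequences=sequences)
    return SyntheticData(
        dataset=dataset,
        structures=structures,
        conservations=conservations,
        weights=dict(spec.signal_weights),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# toy structure generation

_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_CA_RADIUS = 2.3


def generate_toy_structure(length: int, path: str | Path) -> Path:
    """Write an idealised poly-alanine helix as a PDB file.

    Backbone N/CA/C/O plus a CB pseudo side-chain atom per residue;
    coordinates follow a canonical alpha-helical spiral, so terminal
    residues are more exposed than core ones.
    """
    if length < 3:
        raise SyntheticError("need at least 3 residues")
    lines = []
    serial = 1
    offsets = {
        # (radius, twist offset, rise offset) per atom
        "N": (1.75, -0.45, -0.60),
        "CA": (_CA_RADIUS, 0.0, 0.0),
        "C": (1.95, 0.40, 0.55),
        "O": (2.10, 0.55, 1.35),
        "CB": (3.55, -0.25, -0.25),
    }
    for res in range(1, length + 1):
        theta = res * _HELIX_TWIST
        z = res * _HELIX_RISE
        for name, (radius, dtheta, dz) in offsets.items():
            x = radius * math.cos(theta + dtheta)
            y = radius * math.sin(theta + dtheta)
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}ALA A{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z + dz:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
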