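"""Cα-only solvent-exposure scoring.

A deliberately lightweight proxy for solvent accessibility that needs
nothing beyond the Cα trace of a predicted structure: for residue *i*,
``N_i`` counts the Cα atoms of other residues within a fixed radius
(local packing density, 8 Å by default) and ``D_i`` is the distance to the
nearest other Cα regardless of the radius. The raw exposure score

    ASA_i = max(0, 20 - N_i) + 2 * D_i

is large for residues that are loosely packed and far from their nearest
neighbour, and the set of raw scores is linearly rescaled to [0, 100] for
comparison across residues. This is a screening statistic, not a
probe-based accessible-surface area.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import squareform, pdist

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 8.0


@dataclass(frozen=True)
class CaStructure:
    """Ordered Cα records of one chain."""

    residue_numbers: tuple[int, ...]
    residue_names: tuple[str, ...]
    coordinates: np.ndarray  # (n, 3) in Å
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        n = len(self.residue_numbers)
        if coords.shape != (n, 3):
            raise ValidationError("coordinates must be (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        if len(set(self.residue_numbers)) != n:
            raise FormatError("duplicate residue numbers in chain")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "residue_numbers", tuple(self.residue_numbers))
        object.__setattr__(self, "residue_names", tuple(self.residue_names))

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass(frozen=True)
class AsaScore:
    residue_number: int
    n_neighbors: int
    min_distance: float
    raw: float
    normalized: float | None = None


def read_ca(
    source: str | Path | io.TextIOBase, chain: str | None = None
) -> CaStructure:
    """Extract the Cα trace of one chain from PDB-format content.

    Only ATOM records from the first model are used; HETATM is ignored.
    Alternate locations resolve to the highest-occupancy conformer (Bio.PDB's
    default selection). ``chain=None`` takes the first chain in the file.
    """
    parser = PDBParser(QUIET=True)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            structure = parser.get_structure("s", fh)
        label = str(source)
    else:
        structure = parser.get_structure("s", source)
        label = "<stream>"
    models = list(structure)
    if not models:
        raise FormatError(f"no coordinates found in {label}")
    if len(models) > 1:
        logger.info("%s: using model 1 of %d", label, len(models))
    model = models[0]
    chains = {c.id: c for c in model}
    if chain is None:
        selected = next(iter(model))
    elif chain in chains:
        selected = chains[chain]
    else:
        raise FormatError(
            f"chain {chain!r} not in {label} (have {sorted(chains)})"
        )
    numbers, names, coords = [], [], []
    for residue in selected:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue  # HETATM / water
        if "CA" not in residue:
            continue
        atom = residue["CA"]  # disordered atoms resolve by occupancy
        numbers.append(int(resseq))
        names.append(residue.get_resname())
        coords.append(atom.get_coord())
    if not numbers:
        raise FormatError(f"no CA atoms in chain {selected.id!r} of {label}")
    return CaStructure(
        residue_numbers=tuple(numbers),
        residue_names=tuple(names),
        coordinates=np.array(coords, dtype=float),
        chain_id=selected.id,
        source=label,
    )


def write_ca_pdb(
    structure: CaStructure, destination: str | Path | io.TextIOBase
) -> None:
    """Write a Cα-only PDB file (one ATOM record per residue)."""
    lines = []
    for i, (num, name) in enumerate(
        zip(structure.residue_numbers, structure.residue_names), start=1
    ):
        x, y, z = structure.coordinates[i - 1]
        lines.append(
            f"ATOM  {i:5d}  CA  {name:>3s} {structure.chain_id:1s}{num:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"           C"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def neighbor_stats(
    structure: CaStructure, radius: float = DEFAULT_RADIUS
) -> list[tuple[int, float]]:
    """Per residue: ``(N_i, D_i)``.

    ``N_i`` counts other Cα atoms at distance <= radius (boundary
    inclusive); ``D_i`` is the minimum distance to any other Cα and is not
    constrained by the radius.
    """
    if len(structure) < 2:
        raise ValidationError("neighbor statistics need at least 2 residues")
    if radius <= 0:
        raise ValidationError("radius must be positive")
    dists = squareform(pdist(structure.coordinates))
    np.fill_diagonal(dists, np.inf)
    ni = (dists <= radius).sum(axis=1)
    di = dists.min(axis=1)
    return [(int(n), float(d)) for n, d in zip(ni, di)]


def asa_raw(n_neighbors: int, min_distance: float) -> float:
    """Raw exposure score ``max(0, 20 - N_i) + 2 * D_i``."""
    if n_neighbors < 0:
        raise ValidationError("neighbor count must be >= 0")
    if min_distance <= 0:
        raise ValidationError("nearest-neighbor distance must be positive")
    return max(0.0, 20.0 - n_neighbors) + 2.0 * min_distance


def normalize_scores(raws: list[float]) -> list[float]:
    """Linear rescale of raw scores onto [0, 100].

    If every raw score is identical the rescale is undefined; all scores are
    set to 0 (never 100, so no residue is spuriously reported as maximally
    exposed) and a warning is emitted.
    """
    if not raws:
        raise ValidationError("cannot normalize an empty score list")
    lo, hi = min(raws), max(raws)
    if hi == lo:
        message = (
            "all raw exposure scores are equal; normalized scores set to 0"
        )
        logger.warning(message)
        warnings.warn(message, stacklevel=2)
        return [0.0 for _ in raws]
    return [(x - lo) / (hi - lo) * 100.0 for x in raws]


def exposure_profile(
    structure: CaStructure,
    radius: float = DEFAULT_RADIUS,
    normalize: bool = True,
) -> list[AsaScore]:
    """Full per-residue exposure table for one chain."""
    stats = neighbor_stats(structure, radius)
    raws = [asa_raw(n, d) for n, d in stats]
    norms = normalize_scores(raws) if normalize else [None] * len(raws)
    return [
        AsaScore(
            residue_number=num,
            n_neighbors=n,
            min_distance=d,
            raw=raw,
            normalized=norm,
        )
        for num, (n, d), raw, norm in zip(
            structure.residue_numbers, stats, raws, norms
        )
    ]
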