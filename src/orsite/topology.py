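"""Membrane topology bookkeeping for 7TM-type receptors.

Topology prediction itself happens upstream (e.g. TOPCONS); this module
consumes the predicted transmembrane segment ranges plus the membrane side
of the N-terminus and derives the full per-residue annotation: tails,
numbered transmembrane helices, and extracellular/intracellular loops whose
sides alternate with each membrane crossing. Insect odorant receptors have
an inverted topology relative to GPCRs — cytoplasmic N-terminus — so the
sidedness is an input, never an assumption.

The candidate-region mask marks the part of the chain searched for
functional residues. Two modes are provided:

``loops_plus_full_tms``
    all extracellular-loop residues plus every residue of transmembrane
    helices numbered >= ``tm_min_index`` (default 3) — the regions a 7TM
    odorant-binding pocket is drawn from;
``loops_plus_tm_termini``
    all extracellular-loop residues plus a window of ``w`` residues at the
    extracellular-facing end of every helix — a stricter reading of
    "TM termini" that keeps only the junction residues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .errors import ValidationError

Side = Literal["cytoplasmic", "extracellular"]

_OPPOSITE: dict[str, str] = {
    "cytoplasmic": "extracellular",
    "extracellular": "cytoplasmic",
}


@dataclass(frozen=True)
class TopologySpec:
    """Ordered TM segment ranges (1-based inclusive) plus N-terminal side."""

    protein_length: int
    tm_segments: tuple[tuple[int, int], ...]
    n_term_side: Side = "cytoplasmic"

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValidationError("protein_length must be positive")
        if self.n_term_side not in _OPPOSITE:
            raise ValidationError(
                f"n_term_side must be cytoplasmic or extracellular, "
                f"got {self.n_term_side!r}"
            )
        segs = tuple((int(s), int(e)) for s, e in self.tm_segments)
        if not segs:
            raise ValidationError("at least one TM segment is required")
        prev_end = 0
        for k, (s, e) in enumerate(segs, start=1):
            if not 1 <= s <= e <= self.protein_length:
                raise ValidationError(
                    f"TM{k} range {s}-{e} outside 1..{self.protein_length}"
                )
            if s <= prev_end:
                raise ValidationError(
                    f"TM{k} ({s}-{e}) overlaps or is out of order"
                )
            prev_end = e
        object.__setattr__(self, "tm_segments", segs)


@dataclass(frozen=True)
class Region:
    label: str
    start: int  # 1-based inclusive; start > end encodes an empty region
    end: int
    side: str  # membrane side for loops/tails, "membrane" for TMs

    @property
    def empty(self) -> bool:
        return self.start > self.end

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class RegionAnnotation:
    """Per-residue partition of the chain into tails, TMs and loops."""

    protein_length: int
    regions: tuple[Region, ...]

    def region_of(self, position: int) -> Region:
        if not 1 <= position <= self.protein_length:
            raise ValidationError(
                f"position {position} outside 1..{self.protein_length}"
            )
        for region in self.regions:
            if position in region:
                return region
        raise AssertionError("regions do not partition the chain")

    def by_label(self, label: str) -> Region:
        for region in self.regions:
            if region.label == label:
                return region
        raise ValidationError(f"no region labelled {label!r}")

    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def to_tsv(self, destination: str | Path | io.TextIOBase) -> None:
        lines = ["region\tstart\tend\tside"]
        for r in self.regions:
            start, end = ("", "") if r.empty else (str(r.start), str(r.end))
            lines.append(f"{r.label}\t{start}\t{end}\t{r.side}")
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)

    def to_bed(self, destination: str | Path | io.TextIOBase,
               name: str = "protein") -> None:
        """BED-style export: 0-based half-open intervals on the chain.

        A 1-based inclusive range (s, e) becomes (s-1, e); empty regions are
        skipped since BED cannot represent them.
        """
        lines = []
        for r in self.regions:
            if not r.empty:
                lines.append(f"{name}\t{r.start - 1}\t{r.end}\t{r.label}")
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)


def derive_regions(spec: TopologySpec) -> RegionAnnotation:
    """Expand TM segment ranges into the full labelled partition.

    The side alternates at every membrane crossing starting from
    ``n_term_side``; each inter-TM gap becomes an EL or IL (numbered
    independently along the chain) according to the side the preceding helix
    exits to. Zero-length loops and tails are kept as explicit empty regions
    so the alternation bookkeeping stays intact.
    """
    regions: list[Region] = []
    side = spec.n_term_side
    first_start = spec.tm_segments[0][0]
    n_tail = Region("N_tail", 1, first_start - 1, side)
    regions.append(n_tail)
    el = il = 0
    for k, (s, e) in enumerate(spec.tm_segments, start=1):
        regions.append(Region(f"TM{k}", s, e, "membrane"))
        side = _OPPOSITE[side]
        if k < len(spec.tm_segments):
            nxt = spec.tm_segments[k][0]
            if side == "extracellular":
                el += 1
                label = f"EL{el}"
            else:
                il += 1
                label = f"IL{il}"
            regions.append(Region(label, e + 1, nxt - 1, side))
    last_end = spec.tm_segments[-1][1]
    regions.append(Region("C_tail", last_end + 1, spec.protein_length, side))
    return RegionAnnotation(
        protein_length=spec.protein_length, regions=tuple(regions)
    )


def classify_residue(
    annotation: RegionAnnotation, position: int
) -> tuple[str, str]:
    """Label and membrane side of one residue position."""
    region = annotation.region_of(position)
    return region.label, region.side


MaskMode = Literal["loops_plus_full_tms", "loops_plus_tm_termini"]


@dataclass(frozen=True)
class CandidateRegionMask:
    """The residue positions searched for candidate functional residues."""

    positions: frozenset[int]
    mode: str
    tm_min_index: int
    terminal_window: int

    def __contains__(self, position: int) -> bool:
        return position in self.positions


def candidate_mask(
    annotation: RegionAnnotation,
    mode: MaskMode = "loops_plus_full_tms",
    tm_min_index: int = 3,
    terminal_window: int = 4,
) -> CandidateRegionMask:
    """Build the candidate-region mask (see module docstring for modes)."""
    tm_regions = [r for r in annotation.regions if r.label.startswith("TM")]
    if not 1 <= tm_min_index <= len(tm_regions):
        raise ValidationError(
            f"tm_min_index {tm_min_index} outside 1..{len(tm_regions)}"
        )
    if terminal_window < 0:
        raise ValidationError("terminal window w must be >= 0")
    positions: set[int] = set()
    for region in annotation.regions:
        if region.label.startswith("EL") and not region.empty:
            positions.update(range(region.start, region.end + 1))
    if mode == "loops_plus_full_tms":
        for k, region in enumerate(tm_regions, start=1):
            if k >= tm_min_index:
                positions.update(range(region.start, region.end + 1))
    elif mode == "loops_plus_tm_termini":
        for region in tm_regions:
            end_side_start = _extracellular_end(annotation, region)
            if end_side_start is None:
                continue
            lo, hi = end_side_start
            w = min(terminal_window, hi - lo + 1)
            if _faces_extracellular_after(annotation, region):
                positions.update(range(hi - w + 1, hi + 1))
            else:
                positions.update(range(lo, lo + w))
    else:
        raise ValidationError(f"unknown candidate mask mode {mode!r}")
    return CandidateRegionMask(
        positions=frozenset(positions),
        mode=mode,
        tm_min_index=tm_min_index,
        terminal_window=terminal_window,
    )


def _faces_extracellular_after(
    annotation: RegionAnnotation, tm: Region
) -> bool:
    """True if the chain exits this helix on the extracellular side."""
    idx = annotation.regions.index(tm)
    after = annotation.regions[idx + 1]
    return after.side == "extracellular"


def _extracellular_end(
    annotation: RegionAnnotation, tm: Region
) -> tuple[int, int] | None:
    """The helix range, or None if neither flank is extracellular."""
    idx = annotation.regions.index(tm)
    before = annotation.regions[idx - 1]
    after = annotation.regions[idx + 1]
    if "extracellular" not in (before.side, after.side):
        return None
    return tm.start, tm.end


def read_topology_config(
    source: str | Path | io.TextIOBase,
) -> TopologySpec:
    """Parse a minimal two-column topology file.

    Format: a header line ``length <N> <n_term_side>`` followed by one
    ``<start> <end>`` pair per TM segment; blank lines and ``#`` comments
    ignored.
    """
    text = (
        Path(source).read_text()
        if isinstance(source, (str, Path))
        else source.read()
    )
    length = None
    side: str = "cytoplasmic"
    segments: list[tuple[int, int]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0].lower() == "length":
            length = int(parts[1])
            if len(parts) > 2:
                side = parts[2]
        else:
            if len(parts) != 2:
                raise ValidationError(
                    f"expected '<start> <end>', got {raw!r}"
                )
            segments.append((int(parts[0]), int(parts[1])))
    if length is None:
        raise ValidationError("topology file is missing the 'length' line")
    return TopologySpec(
        protein_length=length,
        tm_segments=tuple(segments),
        n_term_side=side,  # type: ignore[arg-type]
    )


def write_topology_config(
    spec: TopologySpec, destination: str | Path | io.TextIOBase
) -> None:
    lines = [f"length {spec.protein_length} {spec.n_term_side}"]
    lines += [f"{s} {e}" for s, e in spec.tm_segments]
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)
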