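"""Synthetic inputs with the statistical and geometric structure the
pipeline assumes.

Two generators cover the two input families:

* :func:`simulate_family` evolves a protein family down a (random or
  supplied) tree under the packaged substitution model, with three column
  classes — invariant, moderate and fast — whose default mix mirrors the
  conservation-class proportions typical of an odorant-receptor ortholog
  set (~20% near-invariant, ~54% variable). Selected columns can be planted
  as invariant (or forced fast) to provide ground truth for
  parameter-recovery tests. Ragged sequence ends are emulated by terminal
  deletions only, so internal column indexing stays aligned with the
  reference.

* :func:`simulate_bundle` builds an ideal α-helical Cα bundle — standard
  helix geometry (1.5 Å rise and 100° twist per residue on a 2.3 Å helical
  radius), helix axes on a circle, alternating up/down — with smooth loop
  arcs bulging outward, optional Gaussian coordinate jitter, and the
  matching membrane-topology specification. Outward-facing residues are
  labelled as the exposed class in the emitted ground truth.

Both generators are deterministic under their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .conservation import AlignedFamily, SequenceRecord, write_fasta
from .errors import ValidationError
from .exposure import CaStructure, asa_raw, neighbor_stats, write_ca_pdb
from .substitution import SubstitutionModel, jtt
from .topology import TopologySpec, derive_regions, write_topology_config


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels for planted residues.

    Classes: ``key`` (conserved + exposed — should be recovered),
    ``decoy_buried`` (conserved but buried), ``decoy_variable`` (exposed but
    variable), ``exposed``/``buried`` (geometric labels from the bundle).
    """

    entries: tuple[tuple[int, str], ...] = ()

    def positions(self, cls: str) -> list[int]:
        return sorted(p for p, c in self.entries if c == cls)

    def merged(self, other: "PlantedTruth") -> "PlantedTruth":
        return PlantedTruth(entries=self.entries + other.entries)


@dataclass(frozen=True)
class FamilySimSpec:
    """Study conditions for the family simulator."""

    n_taxa: int = 11
    length: int = 400
    tree: dendropy.Tree | None = None
    fraction_invariant: float = 0.20
    fraction_fast: float = 0.54
    rate_multipliers: tuple[float, float, float] = (0.0, 1.0, 2.2)
    edge_length_mean: float = 0.2
    max_terminal_trim: int = 44
    planted_invariant: tuple[int, ...] = ()
    planted_fast: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValidationError("need at least 2 taxa")
        if self.length < 1:
            raise ValidationError("alignment length must be positive")
        f_inv, f_fast = self.fraction_invariant, self.fraction_fast
        if not (0 <= f_inv <= 1 and 0 <= f_fast <= 1 and f_inv + f_fast <= 1):
            raise ValidationError(
                "column-class fractions must lie in [0,1] and sum to <= 1"
            )
        for p in self.planted_invariant + self.planted_fast:
            if not 1 <= p <= self.length:
                raise ValidationError(f"planted position {p} outside 1..{self.length}")
        if set(self.planted_invariant) & set(self.planted_fast):
            raise ValidationError("planted position sets must be disjoint")


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    edge_length_mean: float = 0.12,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Random bifurcating tree by sequential random joins, exponential
    branch lengths."""
    if labels is None:
        labels = [f"sp{i:02d}" for i in range(1, n_taxa + 1)]
    clusters = [f"{lab}:{rng.exponential(edge_length_mean):.6f}"
                for lab in labels]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        bl = rng.exponential(edge_length_mean)
        clusters.append(f"({a},{b}):{bl:.6f}")
    newick = clusters[0].rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return tree


def _evolve_states(
    parent: np.ndarray,
    t: float,
    rates: np.ndarray,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample child residue states given parent states and per-column rates."""
    child = parent.copy()
    for rate in np.unique(rates):
        cols = np.nonzero(rates == rate)[0]
        if rate <= 0 or t <= 0 or len(cols) == 0:
            continue
        p = model.transition_matrix(t * rate)
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(cols))
        child[cols] = (u[:, None] > cum[parent[cols], :]).sum(axis=1)
    return child


def simulate_family(
    spec: FamilySimSpec,
    model: SubstitutionModel | None = None,
    reference_id: str = "focal",
) -> tuple[AlignedFamily, PlantedTruth]:
    """Evolve an aligned family down a tree under the substitution model.

    The ancestral sequence is drawn from the model's stationary frequencies
    and evolved along each branch with per-class rate multipliers via the
    model's transition matrices. Invariant-class columns (including planted
    ones) are copied unchanged everywhere. The reference (focal) sequence is
    never trimmed, so reference positions coincide with alignment columns.
    """
    model = model or jtt()
    rng = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
    tree = spec.tree
    if tree is None:
        tree = random_tree(spec.n_taxa, rng, spec.edge_length_mean)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != spec.n_taxa:
        raise ValidationError(
            f"tree has {len(leaves)} leaves but spec.n_taxa={spec.n_taxa}"
        )

    L = spec.length
    r_inv, r_mod, r_fast = spec.rate_multipliers
    u = rng.random(L)
    rates = np.where(
        u < spec.fraction_invariant,
        r_inv,
        np.where(u < spec.fraction_invariant + spec.fraction_fast, r_fast, r_mod),
    )
    for p in spec.planted_invariant:
        rates[p - 1] = r_inv
    for p in spec.planted_fast:
        rates[p - 1] = r_fast

    root_states = rng.choice(20, size=L, p=model.frequencies)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = root_states
        else:
            t = float(node.edge.length or 0.0)
            current = _evolve_states(
                states[id(node.parent_node)], t, rates, model, rng
            )
        states[id(node)] = current
        if node.is_leaf():
            leaf_states[node.taxon.label] = current

    alphabet = model.alphabet
    # the focal sequence takes the ancestral-most leaf's place: relabel the
    # first leaf as the reference and never trim it
    ordered = [reference_id] + [lab for lab in leaves][1:]
    leaf_states[reference_id] = leaf_states.pop(leaves[0])

    members = []
    for lab in ordered:
        seq = "".join(alphabet[s] for s in leaf_states[lab])
        if lab != reference_id and spec.max_terminal_trim > 0:
            head = int(rng.integers(0, spec.max_terminal_trim + 1))
            tail = int(rng.integers(0, spec.max_terminal_trim + 1))
            body = seq[head: L - tail if tail else L]
            seq = "-" * head + body + "-" * tail
        members.append(SequenceRecord(id=lab, residues=seq))
    family = AlignedFamily(members=tuple(members), reference_id=reference_id)
    truth = PlantedTruth(
        entries=tuple((p, "invariant") for p in spec.planted_invariant)
        + tuple((p, "fast") for p in spec.planted_fast)
    )
    return family, truth


@dataclass(frozen=True)
class BundleSimSpec:
    """Study conditions for the Cα helix-bundle simulator.

    The default layout — seven 21-residue helices, a 10-residue N-tail,
    loops of 10/40/33/56/10/50 residues and no C-tail — is the canonical
    insect-OR chain of 356 residues.
    """

    n_helices: int = 7
    residues_per_helix: int = 21
    n_tail: int = 10
    c_tail: int = 0
    loop_lengths: tuple[int, ...] = (10, 40, 33, 56, 10, 50)
    rise: float = 1.5  # Å per residue along the helix axis
    twist_deg: float = 100.0  # rotation per residue
    helix_radius: float = 2.3  # Å, Cα distance from the helix axis
    bundle_radius: float = 8.5  # Å, helix axes on this circle
    jitter: float = 0.2  # Å, Gaussian coordinate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 2:
            raise ValidationError("need >= 1 helix with >= 2 residues each")
        if len(self.loop_lengths) != self.n_helices - 1:
            raise ValidationError(
                f"need {self.n_helices - 1} loop lengths, "
                f"got {len(self.loop_lengths)}"
            )
        if min((self.n_tail, self.c_tail) + self.loop_lengths) < 0:
            raise ValidationError("tail and loop lengths must be >= 0")
        if min(self.rise, self.helix_radius, self.bundle_radius) <= 0:
            raise ValidationError("geometry lengths must be positive")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")

    @property
    def total_residues(self) -> int:
        return (
            self.n_tail
            + self.n_helices * self.residues_per_helix
            + sum(self.loop_lengths)
            + self.c_tail
        )


def _helix_trace(
    axis_xy: np.ndarray,
    z_start: float,
    direction: float,
    n: int,
    spec: BundleSimSpec,
    phase: float,
) -> np.ndarray:
    """Ideal α-helical Cα trace around a vertical axis."""
    i = np.arange(n)
    phi = phase + np.deg2rad(spec.twist_deg) * i
    x = axis_xy[0] + spec.helix_radius * np.cos(phi)
    y = axis_xy[1] + spec.helix_radius * np.sin(phi)
    z = z_start + direction * spec.rise * i
    return np.column_stack([x, y, z])


def _loop_walk(
    p: np.ndarray,
    q: np.ndarray,
    n: int,
    rng: np.random.Generator,
    obstacles: np.ndarray,
    step: float = 3.8,
    clash: float = 3.4,
) -> np.ndarray:
    """n loop points from p toward q as a guided walk with ~3.8 Å steps.

    Early steps wander away from the membrane plane and radially outward
    (loops sit on the bundle surface); later steps are pulled increasingly
    hard toward q so the walk lands within one step of the next helix. The
    fixed step keeps consecutive Cα spacing physical, and candidate steps
    that land within the clash distance of already-placed atoms are
    deflected away, so loop residues are genuinely less packed than helix
    residues without unphysical contacts.
    """
    if n == 0:
        return np.empty((0, 3))
    pts: list[np.ndarray] = []
    cur = p.astype(float).copy()
    z_sign = 1.0 if p[2] + q[2] >= 0 else -1.0

    def min_dist(x: np.ndarray) -> tuple[float, np.ndarray]:
        placed = (
            np.vstack([obstacles] + [np.array(pts)])
            if pts
            else obstacles
        )
        d = np.linalg.norm(placed - x[None, :], axis=1)
        j = int(np.argmin(d))
        return float(d[j]), placed[j]

    for i in range(n):
        remaining = n + 1 - i
        to_q = q - cur
        dist_q = float(np.linalg.norm(to_q))
        pull = to_q / max(dist_q, 1e-9)
        out = np.array([cur[0], cur[1], 0.0])
        nrm = float(np.linalg.norm(out))
        out = out / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        out = out + np.array([0.0, 0.0, 0.35 * z_sign])
        # urgency -> 1 when the remaining budget barely covers the distance
        urgency = min(1.0, dist_q / (remaining * step))
        w = i / max(n - 1, 1)
        noise = rng.normal(0.0, 0.25, size=3)
        direction = (
            (0.25 + 0.75 * max(urgency, w)) * pull
            + (1.0 - urgency) * (1.0 - w) * (out + noise)
        )
        direction = direction / max(float(np.linalg.norm(direction)), 1e-9)
        cand = cur + step * direction
        for _ in range(6):
            d_min, nearest = min_dist(cand)
            if d_min >= clash or urgency > 0.95:
                break
            away = cand - nearest
            away = away / max(float(np.linalg.norm(away)), 1e-9)
            direction = direction + 0.8 * away
            direction = direction / max(
                float(np.linalg.norm(direction)), 1e-9
            )
            cand = cur + step * direction
        cur = cand
        pts.append(cur.copy())
    return np.array(pts)


def _tail(p: np.ndarray, direction: np.ndarray, n: int) -> np.ndarray:
    """n points marching away from p at 3.8 Å spacing (nearest first)."""
    if n == 0:
        return np.empty((0, 3))
    d = direction / np.linalg.norm(direction)
    steps = 3.8 * (np.arange(n) + 1)
    return p[None, :] + steps[:, None] * d[None, :]


def simulate_bundle(
    spec: BundleSimSpec,
) -> tuple[CaStructure, PlantedTruth, TopologySpec]:
    """Ideal α-helix bundle Cα trace plus matching topology and truth labels.

    Helix axes sit on a circle of the bundle radius with alternating
    up/down orientation; loops are smooth outward arcs; tails extend away
    from the bundle. Residues whose Cα lies outside the axis circle (all
    loop and tail residues, and the outward face of each helix) are labelled
    ``exposed``; inward helix-facing residues are ``buried``.
    """
    rng = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
    m = spec.residues_per_helix
    height = (m - 1) * spec.rise
    coords_parts: list[np.ndarray] = []
    helix_ranges: list[tuple[int, int]] = []
    pos = 1

    helix_traces = []
    for k in range(spec.n_helices):
        theta = 2.0 * math.pi * k / spec.n_helices
        axis = spec.bundle_radius * np.array([math.cos(theta), math.sin(theta)])
        direction = 1.0 if k % 2 == 0 else -1.0
        z0 = -height / 2.0 if direction > 0 else height / 2.0
        helix_traces.append(
            _helix_trace(axis, z0, direction, m, spec, phase=theta)
        )

    # N tail: march away from the first helix start, outward and down
    first = helix_traces[0][0]
    tail_dir = np.array([first[0], first[1], 0.0])
    tail_dir = tail_dir / np.linalg.norm(tail_dir) + np.array([0, 0, -0.5])
    n_tail_pts = _tail(first, tail_dir, spec.n_tail)[::-1]
    coords_parts.append(n_tail_pts)
    pos += spec.n_tail

    for k in range(spec.n_helices):
        coords_parts.append(helix_traces[k])
        helix_ranges.append((pos, pos + m - 1))
        pos += m
        if k < spec.n_helices - 1:
            n_loop = spec.loop_lengths[k]
            obstacles = np.vstack(
                [np.vstack(helix_traces)]
                + ([np.vstack([c for c in coords_parts if len(c)])]
                   if any(len(c) for c in coords_parts) else [])
            )
            arc = _loop_walk(
                helix_traces[k][-1],
                helix_traces[k + 1][0],
                n_loop,
                rng,
                obstacles,
            )
            coords_parts.append(arc)
            pos += n_loop

    last = helix_traces[-1][-1]
    ctail_dir = np.array([last[0], last[1], 0.0])
    nrm = np.linalg.norm(ctail_dir)
    ctail_dir = (
        ctail_dir / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    ) + np.array([0, 0, 0.5 if last[2] > 0 else -0.5])
    coords_parts.append(_tail(last, ctail_dir, spec.c_tail))

    coords = np.vstack(coords_parts)
    if spec.jitter > 0:
        coords = coords + rng.normal(0.0, spec.jitter, size=coords.shape)
    n = spec.total_residues
    assert coords.shape == (n, 3)

    structure = CaStructure(
        residue_numbers=tuple(range(1, n + 1)),
        residue_names=("ALA",) * n,
        coordinates=coords,
        chain_id="A",
        source=f"synthetic-bundle-seed{spec.seed}",
    )
    topology = TopologySpec(
        protein_length=n,
        tm_segments=tuple(helix_ranges),
        n_term_side="cytoplasmic",
    )

    helix_positions = {
        p for s, e in helix_ranges for p in range(s, e + 1)
    }
    radial = np.linalg.norm(coords[:, :2], axis=1)
    entries = []
    margin = spec.helix_radius / 2.0
    for p in range(1, n + 1):
        if p in helix_positions:
            r = radial[p - 1]
            if r > spec.bundle_radius + margin:
                cls = "exposed"
            elif r < spec.bundle_radius - margin:
                cls = "buried"
            else:
                cls = "lateral"
        else:
            cls = "exposed"
        entries.append((p, cls))
    return structure, PlantedTruth(entries=tuple(entries)), topology


@dataclass(frozen=True)
class FixtureSpec:
    """A joined family + bundle fixture with planted key residues."""

    bundle: BundleSimSpec = BundleSimSpec()
    n_taxa: int = 11
    n_keys: int = 3
    n_decoys: int = 2
    background: str = "calibrated"  # or "variable": all background fast
    seed: int = 42


def build_fixture(spec: FixtureSpec):
    """Generate a consistent (family, structure, topology, truth) quadruple.

    Key residues are planted invariant at the apexes of the largest
    extracellular loops (maximally exposed by construction); buried decoys
    are planted invariant at inward-facing residues of the later helices;
    variable decoys are forced fast at other exposed loop positions. With
    ``background="variable"`` every non-planted column evolves fast, giving
    the clean conserved-vs-background contrast used for parameter-recovery
    checks.
    """
    structure, geom_truth, topology = simulate_bundle(
        replace(spec.bundle, seed=spec.seed)
    )
    annotation = derive_regions(topology)
    els = sorted(
        (
            r
            for r in annotation.regions
            if r.label.startswith("EL") and not r.empty
        ),
        key=lambda r: r.end - r.start,
        reverse=True,
    )
    if len(els) < 1:
        raise ValidationError("fixture bundle produced no extracellular loop")
    el_all = [p for r in els for p in range(r.start, r.end + 1)]
    if len(el_all) < spec.n_keys:
        raise ValidationError("not enough EL residues to plant keys")
    # plant keys at the measurably most exposed EL positions of this very
    # structure, so "surface placement" holds by construction
    stats = neighbor_stats(structure)
    raw = {p: asa_raw(*stats[p - 1]) for p in el_all}
    keys = sorted(sorted(el_all, key=lambda p: -raw[p])[: spec.n_keys])

    buried = [
        p
        for p, c in geom_truth.entries
        if c == "buried" and annotation.region_of(p).label in
        {f"TM{k}" for k in range(3, spec.bundle.n_helices + 1)}
    ]
    decoys_buried = buried[: spec.n_decoys]
    el_positions = [
        p
        for r in els
        for p in range(r.start, r.end + 1)
        if p not in keys
    ]
    decoys_variable = el_positions[: spec.n_decoys]

    variable = spec.background == "variable"
    fam_spec = FamilySimSpec(
        n_taxa=spec.n_taxa,
        length=topology.protein_length,
        fraction_invariant=0.0 if variable else 0.20,
        fraction_fast=1.0 if variable else 0.54,
        # the recovery contrast needs background columns that are genuinely
        # variable: deep divergence and no ragged ends, so planted
        # conservation is the only conservation signal
        edge_length_mean=0.35 if variable else 0.2,
        max_terminal_trim=0 if variable else 44,
        planted_invariant=tuple(sorted(keys + decoys_buried)),
        planted_fast=tuple(decoys_variable),
        seed=spec.seed,
    )
    family, _ = simulate_family(fam_spec)
    truth = PlantedTruth(
        entries=tuple((p, "key") for p in keys)
        + tuple((p, "decoy_buried") for p in decoys_buried)
        + tuple((p, "decoy_variable") for p in decoys_variable)
    )
    return family, structure, topology, truth


def write_fixture(
    directory: str | Path,
    spec: FixtureSpec = FixtureSpec(),
) -> dict[str, Path]:
    """Write a complete demo dataset (FASTA, PDB, topology, truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    family, structure, topology, truth = build_fixture(spec)
    paths = {
        "alignment": directory / "family.fasta",
        "structure": directory / "structure.pdb",
        "topology": directory / "topology.txt",
        "truth": directory / "truth.json",
    }
    write_fasta(family, paths["alignment"])
    write_ca_pdb(structure, paths["structure"])
    write_topology_config(topology, paths["topology"])
    paths["truth"].write_text(
        json.dumps(
            {
                "seed": spec.seed,
                "planted": [
                    {"position": p, "class": c} for p, c in truth.entries
                ],
            },
            indent=2,
        )
        + "\n"
    )
    return paths
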