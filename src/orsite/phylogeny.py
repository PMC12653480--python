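"""Distance-based phylogenetics: ML pairwise distances under an empirical
amino-acid model, Neighbor-Joining, and bootstrap bipartition support.

Pairwise distances maximize the likelihood of the observed residue pairs
under the reversible model, ``sum_i log(pi_a P_ab(t))`` over shared valid
columns, by bracketed scalar optimization on ``t`` in ``[0, cap]``; pairs
whose optimum sits at the cap are flagged as saturated rather than dropped.
Trees are built with the Saitou-Nei Neighbor-Joining agglomeration, which is
exact on additive distance matrices, and support for each internal
bipartition of the NJ tree is the percentage of column-resampled replicate
trees that contain the same bipartition.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .conservation import AlignedFamily
from .errors import OrsiteError, ValidationError
from .substitution import SubstitutionModel, jtt

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_CAP = 10.0


class UndefinedDistanceError(OrsiteError):
    """Two sequences share no column where both residues are valid."""

    exit_code = 3


def _pair_counts(a: str, b: str, model: SubstitutionModel) -> np.ndarray:
    """20x20 table of co-occurring valid residue pairs in two aligned rows."""
    if len(a) != len(b):
        raise ValidationError(
            f"aligned rows differ in length ({len(a)} vs {len(b)})"
        )
    idx = {ch: i for i, ch in enumerate(model.alphabet)}
    counts = np.zeros((20, 20))
    for x, y in zip(a.upper(), b.upper()):
        i = idx.get(x)
        j = idx.get(y)
        if i is not None and j is not None:
            counts[i, j] += 1
    return counts


def pair_log_likelihood(
    counts: np.ndarray, t: float, model: SubstitutionModel
) -> float:
    """Log-likelihood of the pair-count table at divergence time *t*."""
    p = model.frequencies[:, None] * model.transition_matrix(t)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    logp[np.isneginf(logp)] = -1e10  # impossible pairs at t=0
    return float((counts * logp).sum())


def jtt_distance(
    a: str,
    b: str,
    model: SubstitutionModel | None = None,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> tuple[float, bool]:
    """ML distance between two aligned residue strings.

    Returns ``(distance, saturated)`` in expected substitutions per site.
    Identical sequences return 0 exactly; an optimum within optimizer
    tolerance of the cap is reported at the cap with ``saturated=True``.
    """
    model = model or jtt()
    counts = _pair_counts(a, b, model)
    n_shared = counts.sum()
    if n_shared == 0:
        raise UndefinedDistanceError(
            "no shared valid column between the two sequences"
        )
    if counts.sum() == np.trace(counts):
        return 0.0, False
    res = minimize_scalar(
        lambda t: -pair_log_likelihood(counts, t, model),
        bounds=(0.0, cap),
        method="bounded",
        options={"xatol": 1e-6},
    )
    t_hat = float(res.x)
    saturated = t_hat >= cap - 1e-4
    return (cap if saturated else t_hat), saturated


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with saturation flags."""

    labels: tuple[str, ...]
    values: np.ndarray
    saturated: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValidationError(
                "distance matrix must be symmetric with a zero diagonal"
            )
        if np.any(v < 0):
            raise ValidationError("distances must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def mean_pairwise(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        return float(self.values[iu].mean())

    def max_pairwise(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        return float(self.values[iu].max())

    def to_tsv(self, destination: str | Path | io.TextIOBase) -> None:
        lines = ["\t".join(("taxon",) + self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append(
                "\t".join(
                    [lab] + [f"{x:.4f}" for x in self.values[i]]
                )
            )
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)

    def to_phylip(self, destination: str | Path | io.TextIOBase) -> None:
        """PHYLIP square (lower+upper) distance matrix."""
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.values[i])
            lines.append(f"{lab:<10s} {row}")
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)


def distance_matrix(
    family: AlignedFamily,
    model: SubstitutionModel | None = None,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> DistanceMatrix:
    """All pairwise ML distances for an aligned family.

    A pair with no shared valid column is flagged saturated and set to the
    cap instead of aborting the whole matrix.
    """
    model = model or jtt()
    labels = tuple(m.id for m in family.members)
    rows = [m.residues for m in family.members]
    n = len(labels)
    values = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, sat = jtt_distance(rows[i], rows[j], model, cap)
            except UndefinedDistanceError:
                d, sat = cap, True
            values[i, j] = values[j, i] = d
            if sat:
                saturated.add(tuple(sorted((labels[i], labels[j]))))
    return DistanceMatrix(labels, values, frozenset(saturated))


@dataclass
class PhyloTree:
    """An unrooted tree plus optional bootstrap support per bipartition.

    ``support`` maps normalized split bitmasks (dendropy encoding over
    ``taxon_namespace``) to percentages in [0, 100].
    """

    tree: dendropy.Tree
    support: dict[int, float] = field(default_factory=dict)

    @property
    def taxon_namespace(self) -> dendropy.TaxonNamespace:
        return self.tree.taxon_namespace

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def bipartitions(self) -> set[int]:
        """Nontrivial (internal-edge) split bitmasks of the unrooted tree."""
        self.tree.encode_bipartitions()
        out = set()
        for edge in self.tree.preorder_edge_iter():
            bp = edge.bipartition
            if bp is not None and not bp.is_trivial():
                out.add(bp.split_bitmask)
        return out

    def branch_length(self, label: str) -> float:
        node = next(
            lf
            for lf in self.tree.leaf_node_iter()
            if lf.taxon.label == label
        )
        return float(node.edge.length or 0.0)


def nj_tree(
    dm: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> PhyloTree:
    """Neighbor-Joining tree from a distance matrix.

    Agglomerates on the Saitou-Nei Q-criterion; ties are broken by the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest leaf label) so output is reproducible. Negative branch
    length estimates are clamped to zero with a warning.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValidationError("Neighbor-Joining needs at least 2 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(list(dm.labels))
    taxa = {lab: tns.get_taxon(lab) for lab in dm.labels}
    if None in taxa.values():
        missing = [k for k, v in taxa.items() if v is None]
        raise ValidationError(f"taxa missing from namespace: {missing}")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.warning(
                "negative NJ branch length %.4g (%s) clamped to 0", x, context
            )
            return 0.0
        return x

    nodes: dict[str, dendropy.Node] = {}
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa[lab])
        nodes[lab] = node
    # working copy of distances keyed by cluster label (= smallest leaf label)
    d = {
        (a, b): dm.get(a, b)
        for i, a in enumerate(dm.labels)
        for b in dm.labels[i + 1 :]
    }

    def dist(a: str, b: str) -> float:
        if a == b:
            return 0.0
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    active = sorted(dm.labels)

    if n == 2:
        a, b = active
        half = dist(a, b) / 2.0
        root = dendropy.Node()
        for lab in (a, b):
            nodes[lab].edge.length = half
            root.add_child(nodes[lab])
        tree.seed_node = root
        tree.update_bipartitions(suppress_unifurcations=False)
        return PhyloTree(tree=tree)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        va_raw = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        va = clamp(va_raw, f"{a}-{b}")
        vb = clamp(dab - va_raw, f"{b}-{a}")
        parent = dendropy.Node()
        nodes[a].edge.length = va
        nodes[b].edge.length = vb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        new_label = min(a, b)
        # distances from the new cluster to everything still active
        updates = {}
        for c in active:
            if c in (a, b):
                continue
            updates[c] = max(0.0, (dist(a, c) + dist(b, c) - dab) / 2.0)
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
        d = {
            (x, y): (updates[y] if x == new_label else
                     updates[x] if y == new_label else dist(x, y))
            for i, x in enumerate(active)
            for y in active[i + 1 :]
        }
        nodes[new_label] = parent

    # final trifurcation: closed-form three-point branch lengths
    a, b, c = active
    la = clamp((dist(a, b) + dist(a, c) - dist(b, c)) / 2.0, a)
    lb = clamp((dist(a, b) + dist(b, c) - dist(a, c)) / 2.0, b)
    lc = clamp((dist(a, c) + dist(b, c) - dist(a, b)) / 2.0, c)
    root = dendropy.Node()
    for lab, length in ((a, la), (b, lb), (c, lc)):
        nodes[lab].edge.length = length
        root.add_child(nodes[lab])
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return PhyloTree(tree=tree)


def _resample_columns(
    family: AlignedFamily, rng: np.random.Generator
) -> AlignedFamily:
    cols = rng.integers(0, family.length, size=family.length)
    members = tuple(
        type(m)(id=m.id, residues="".join(m.residues[c] for c in cols))
        for m in family.members
    )
    return AlignedFamily(members=members, reference_id=family.reference_id)


def bootstrap_support(
    family: AlignedFamily,
    model: SubstitutionModel | None = None,
    replicates: int = 100,
    seed: int = 0,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> PhyloTree:
    """NJ tree of the family with bootstrap support on its internal edges.

    Columns are resampled with replacement to the original length for each
    replicate; distances and the NJ tree are recomputed, and the support of
    each internal bipartition of the original tree is
    ``100 * (replicates containing it) / (replicates kept)``. Replicate
    random streams are derived from the master seed by replicate index, so
    any single replicate is reproducible in isolation.
    """
    if replicates < 1:
        raise ValidationError("need at least 1 bootstrap replicate")
    model = model or jtt()
    dm = distance_matrix(family, model, cap)
    main = nj_tree(dm)
    target = main.bipartitions()
    counts = dict.fromkeys(target, 0)
    kept = 0
    for r in range(replicates):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, r])
        try:
            fam_r = _resample_columns(family, rng)
            dm_r = distance_matrix(fam_r, model, cap)
            tree_r = nj_tree(dm_r, taxon_namespace=main.taxon_namespace)
        except OrsiteError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", r, exc)
            continue
        kept += 1
        found = tree_r.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    if kept < replicates / 2.0:
        raise OrsiteError(
            f"only {kept}/{replicates} bootstrap replicates usable"
        )
    support = {bp: 100.0 * c / kept for bp, c in counts.items()}
    main.support = support
    _annotate_support(main)
    return main


def _annotate_support(ptree: PhyloTree) -> None:
    """Write integer support percentages as internal node labels."""
    ptree.tree.encode_bipartitions()
    for node in ptree.tree.preorder_node_iter():
        if node.is_leaf() or node is ptree.tree.seed_node:
            continue
        bp = node.edge.bipartition
        if bp is not None and bp.split_bitmask in ptree.support:
            node.label = str(int(round(ptree.support[bp.split_bitmask])))


def write_newick(
    ptree: PhyloTree,
    outgroup: str | None = None,
    destination: str | Path | io.TextIOBase | None = None,
) -> str:
    """Serialize to Newick with support values as internal node labels.

    If *outgroup* names a leaf, the tree is rerooted at the midpoint of the
    outgroup's edge for display; the unrooted bipartition set is unchanged.
    """
    tree = ptree.tree.clone(depth=1)
    if outgroup is not None:
        node = next(
            (
                lf
                for lf in tree.leaf_node_iter()
                if lf.taxon.label == outgroup
            ),
            None,
        )
        if node is None:
            raise ValidationError(f"outgroup {outgroup!r} is not a leaf")
        length = node.edge.length or 0.0
        tree.reroot_at_edge(
            node.edge, length1=length / 2.0, length2=length / 2.0
        )
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)
    return text


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string back into a tree (round-trip support)."""
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return PhyloTree(tree=tree)
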