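"""End-to-end candidate-residue selection and ranking.

The selection rule is the intersection of two per-residue filters expressed
in the same 1-based reference coordinate system: column conservation at or
above the candidate threshold (0.9 by default), and membership in the
candidate-region mask derived from the membrane topology. Selected
candidates are then ranked by their normalized Cα exposure score, with
deterministic tie-breaking (fewer neighbors, then larger nearest-neighbor
distance, then smaller position) and truncation to the top *k*.

The phylogeny stage (distances, NJ tree, bootstrap support) contextualizes
the family but never gates selection; it can be disabled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .conservation import (
    conservation_profile,
    profile_to_tsv,
    read_fasta,
    reference_residues,
    residue_conservation,
    summarize,
)
from .errors import ConsistencyError, OrsiteError, ValidationError
from .exposure import AsaScore, exposure_profile, neighbor_stats, asa_raw, normalize_scores, read_ca
from .phylogeny import bootstrap_support, distance_matrix, write_newick
from .topology import (
    CandidateRegionMask,
    candidate_mask,
    derive_regions,
    read_topology_config,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateResidue:
    """One selected residue with everything that justified its selection."""

    position: int
    residue: str
    conservation: float
    region: str
    n_neighbors: int
    min_distance: float
    raw: float
    normalized: float
    rank: int | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a pipeline run; mirrors the CLI flags and config file."""

    alignment: str
    structure: str
    topology: str
    reference_id: str | None = None
    chain: str | None = None
    candidate_threshold: float = 0.9
    t_var: float = 0.7
    t_high: float = 0.9
    mask_mode: str = "loops_plus_full_tms"
    tm_min_index: int = 3
    terminal_window: int = 4
    asa_radius: float = 8.0
    normalization_scope: str = "candidates"  # or "all"
    top_k: int = 5
    run_phylogeny: bool = True
    bootstrap_replicates: int = 100
    distance_cap: float = 10.0
    outgroup: str | None = None
    structure_offset: int = 0  # added to PDB residue numbers
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("candidate_threshold", "t_var", "t_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.normalization_scope not in ("candidates", "all"):
            raise ValidationError(
                "normalization_scope must be 'candidates' or 'all'"
            )
        if self.bootstrap_replicates < 1:
            raise ValidationError("bootstrap_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def select_candidates(
    res_conservation: Mapping[int, float],
    residue_letters: Mapping[int, str],
    mask: CandidateRegionMask,
    threshold: float = 0.9,
) -> list[CandidateResidue]:
    """Positions with conservation >= threshold that lie inside the mask.

    Returns unranked records with exposure fields zeroed; order-independent
    (output sorted by position).
    """
    out = []
    for pos in sorted(res_conservation):
        ci = res_conservation[pos]
        if ci >= threshold and pos in mask:
            out.append(
                CandidateResidue(
                    position=pos,
                    residue=residue_letters.get(pos, "X"),
                    conservation=ci,
                    region="",
                    n_neighbors=0,
                    min_distance=0.0,
                    raw=0.0,
                    normalized=0.0,
                )
            )
    return out


def rank_candidates(
    candidates: list[CandidateResidue],
    asa: Mapping[int, AsaScore],
    top_k: int = 5,
) -> list[CandidateResidue]:
    """Attach exposure scores, sort, and truncate to the top *k*.

    Descending by normalized score; ties broken by smaller neighbor count,
    then larger nearest-neighbor distance, then smaller position.
    """
    missing = [c.position for c in candidates if c.position not in asa]
    if missing:
        raise ConsistencyError(
            f"candidate positions missing from the structure: {missing}"
        )
    scored = [
        dataclasses.replace(
            c,
            n_neighbors=asa[c.position].n_neighbors,
            min_distance=asa[c.position].min_distance,
            raw=asa[c.position].raw,
            normalized=float(asa[c.position].normalized or 0.0),
        )
        for c in candidates
    ]
    scored.sort(
        key=lambda c: (-c.normalized, c.n_neighbors, -c.min_distance, c.position)
    )
    return [
        dataclasses.replace(c, rank=i + 1)
        for i, c in enumerate(scored[:top_k])
    ]


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    candidates: list[CandidateResidue]
    all_candidates: list[CandidateResidue]
    summary: object
    annotation: object
    tree_newick: str | None
    manifest: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _candidates_tsv(candidates: list[CandidateResidue], path: Path) -> None:
    header = (
        "rank\tposition\tresidue\tregion\tCi\tNi\tDi\traw_asa\tnorm_asa"
    )
    lines = [header]
    for c in candidates:
        lines.append(
            "\t".join(
                [
                    str(c.rank or ""),
                    str(c.position),
                    c.residue,
                    c.region,
                    f"{c.conservation:.4f}",
                    str(c.n_neighbors),
                    f"{c.min_distance:.4f}",
                    f"{c.raw:.4f}",
                    f"{c.normalized:.4f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: PipelineConfig, outdir: str | Path
) -> ReportBundle:
    """Execute conservation -> (optional) phylogeny -> topology -> exposure
    -> selection -> ranking and write the report bundle to *outdir*.

    Identical config and inputs produce byte-identical reports; any stage
    failure removes partial outputs and re-raises with the stage name.
    """
    outdir = Path(outdir)
    written: list[Path] = []
    stage = "validate"
    try:
        for name in ("alignment", "structure", "topology"):
            p = Path(getattr(config, name))
            if not p.exists():
                raise ValidationError(f"{name} file does not exist: {p}")
        outdir.mkdir(parents=True, exist_ok=True)

        stage = "conservation"
        family = read_fasta(
            config.alignment, aligned=True, reference_id=config.reference_id
        )
        profile = conservation_profile(family)
        summary = summarize(profile, config.t_var, config.t_high)
        res_cons = residue_conservation(profile)
        letters = reference_residues(family)

        stage = "topology"
        topo = read_topology_config(config.topology)
        annotation = derive_regions(topo)
        mask = candidate_mask(
            annotation,
            mode=config.mask_mode,
            tm_min_index=config.tm_min_index,
            terminal_window=config.terminal_window,
        )

        stage = "exposure"
        structure = read_ca(config.structure, chain=config.chain)
        numbers = [
            n + config.structure_offset for n in structure.residue_numbers
        ]
        ref_len = family.reference.ungapped_length
        if not (ref_len == topo.protein_length == len(numbers)):
            raise ConsistencyError(
                "length mismatch: reference sequence has "
                f"{ref_len} residues, topology declares "
                f"{topo.protein_length}, structure has {len(numbers)} "
                "CA atoms"
            )
        stats = neighbor_stats(structure, config.asa_radius)
        raws = [asa_raw(n, d) for n, d in stats]

        stage = "selection"
        candidates = select_candidates(
            res_cons, letters, mask, config.candidate_threshold
        )
        if config.normalization_scope == "all":
            norms = normalize_scores(raws)
        else:
            cand_set = {c.position for c in candidates}
            cand_raws = [
                raw for num, raw in zip(numbers, raws) if num in cand_set
            ]
            norm_by_pos = dict(
                zip(
                    [n for n in numbers if n in cand_set],
                    normalize_scores(cand_raws) if cand_raws else [],
                )
            )
            norms = [norm_by_pos.get(num) for num in numbers]
        asa = {
            num: AsaScore(
                residue_number=num,
                n_neighbors=stats[i][0],
                min_distance=stats[i][1],
                raw=raws[i],
                normalized=norms[i],
            )
            for i, num in enumerate(numbers)
        }

        stage = "ranking"
        candidates = [
            dataclasses.replace(
                c, region=annotation.region_of(c.position).label
            )
            for c in candidates
        ]
        ranked_all = rank_candidates(candidates, asa, top_k=len(candidates) or 1) \
            if candidates else []
        ranked = ranked_all[: config.top_k]

        stage = "phylogeny"
        tree_text = None
        if config.run_phylogeny:
            dm = distance_matrix(family, cap=config.distance_cap)
            ptree = bootstrap_support(
                family,
                replicates=config.bootstrap_replicates,
                seed=config.seed,
                cap=config.distance_cap,
            )
            tree_text = write_newick(ptree, outgroup=config.outgroup)
            p = outdir / "distances.tsv"
            dm.to_tsv(p)
            written.append(p)
            p = outdir / "tree.nwk"
            p.write_text(tree_text)
            written.append(p)

        stage = "report"
        p = outdir / "conservation.tsv"
        profile_to_tsv(profile, p)
        written.append(p)
        p = outdir / "regions.tsv"
        annotation.to_tsv(p)
        written.append(p)
        p = outdir / "candidates.tsv"
        _candidates_tsv(ranked, p)
        written.append(p)
        p = outdir / "all_candidates.tsv"
        _candidates_tsv(ranked_all, p)
        written.append(p)

        manifest = {
            "package": "orsite",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "inputs": {
                name: {
                    "path": str(getattr(config, name)),
                    "sha256": _sha256(getattr(config, name)),
                }
                for name in ("alignment", "structure", "topology")
            },
            "summary": {
                "n_columns": family.length,
                "mean_conservation": round(summary.mean, 4),
                "median_conservation": round(summary.median, 4),
                "n_high": summary.n_high,
                "n_variable": summary.n_variable,
                "n_candidates": len(ranked_all),
                "top_k": config.top_k,
            },
        }
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(p)

        return ReportBundle(
            candidates=ranked,
            all_candidates=ranked_all,
            summary=summary,
            annotation=annotation,
            tree_newick=tree_text,
            manifest=manifest,
            outputs={pp.name: pp for pp in written},
        )
    except OrsiteError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise type(exc)(f"[stage={stage}] {exc}") from exc
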