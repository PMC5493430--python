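"""Synthetic fixtures with the statistical structure the method assumes.

Generates scored interaction networks (Erdős–Rényi pair inclusion with
uniform confidence scores), pathway collections with guaranteed nested
member sets (to exercise the integration step), and expression profiles in
which the members of a designated target pathway carry a coherent log2
shift above a sub-qualification background.  Also provides exact
multivariate-normal sampling for the χ² calibration demonstration: 10000
draws against a 20×20 equicorrelation matrix (diagonal 1, off-diagonal
0.5).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .io import (
    InteractionScores,
    PathwayCollection,
    PathwayDefinition,
    RawRatioRecord,
    write_gene_sets_gmt,
)

__all__ = [
    "SimulationDesign",
    "generate_interaction_network",
    "generate_pathway_collection",
    "generate_expression_records",
    "sample_profiles",
    "make_psd_rulebook_sigma",
    "fig8_preset",
    "simulate_bundle",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic study.

    Defaults describe a small-but-realistic proteomic screen: a couple of
    hundred quantified proteins, a sparse experimentally-supported PPI
    network with scores above the 0.4 medium-confidence floor, pathways of
    5–30 members with a third of them nested inside another pathway, and a
    2-fold (1.0 log2 unit) coherent shift on the perturbed pathway over a
    background whose spread (SD 0.5 log2 units) leaves most unperturbed
    proteins below the 1.5-fold qualification threshold.
    """

    n_proteins: int = 200
    edge_density: float = 0.05
    score_range: tuple[float, float] = (0.4, 1.0)
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 30)
    nested_fraction: float = 0.3
    effect_size: float = 1.0
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.edge_density <= 1):
            raise ValueError("edge_density must be in [0, 1]")
        lo, hi = self.score_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("score_range must lie within (0, 1]")
        if not (0 <= self.nested_fraction <= 1):
            raise ValueError("nested_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    def protein_names(self) -> list[str]:
        width = len(str(self.n_proteins - 1))
        return [f"P{i:0{width}d}" for i in range(self.n_proteins)]


def generate_interaction_network(design: SimulationDesign) -> InteractionScores:
    """Include each of the C(n,2) pairs with probability edge_density;
    scores uniform on score_range."""
    if design.n_proteins < 2:
        raise ValueError("need at least two proteins")
    rng = np.random.default_rng(design.seed)
    names = design.protein_names()
    lo, hi = design.score_range
    edges = []
    for a, b in itertools.combinations(names, 2):
        if rng.random() < design.edge_density:
            edges.append((a, b, float(rng.uniform(lo, hi))))
    return InteractionScores.from_edges(edges)


def generate_pathway_collection(design: SimulationDesign) -> PathwayCollection:
    """Random member sets; a nested_fraction of pathways are strict subsets
    of an earlier pathway, guaranteeing integration test cases."""
    if design.n_pathways < 1:
        raise ValueError("need at least one pathway")
    rng = np.random.default_rng(design.seed + 1)
    names = design.protein_names()
    lo, hi = design.pathway_size_range
    width = len(str(design.n_pathways - 1))
    pathways: list[PathwayDefinition] = []
    for k in range(design.n_pathways):
        pid = f"pw{k:0{width}d}"
        # nesting needs a parent with >=2 members so the subset can be strict
        parents = [p for p in pathways if len(p.members) >= 2]
        if parents and rng.random() < design.nested_fraction:
            parent = parents[rng.integers(len(parents))]
            pool = sorted(parent.members)
            size = int(rng.integers(1, len(pool)))
            members = rng.choice(pool, size=size, replace=False)
        else:
            size = int(rng.integers(lo, min(hi, design.n_proteins) + 1))
            members = rng.choice(names, size=size, replace=False)
        pathways.append(
            PathwayDefinition(pid, f"synthetic pathway {k}", frozenset(map(str, members)))
        )
    return PathwayCollection(pathways)


def generate_expression_records(
    design: SimulationDesign, collection: PathwayCollection | None = None
) -> list[RawRatioRecord]:
    """Fold-scale expression records: background log2 ratios N(0, sd²) with
    the first pathway's members shifted up by effect_size log2 units."""
    rng = np.random.default_rng(design.seed + 2)
    names = design.protein_names()
    log2 = rng.normal(0.0, design.background_sd, size=len(names))
    if collection is not None and len(collection) and design.effect_size > 0:
        target = next(iter(collection))
        hit = {n for n in target.members}
        for i, n in enumerate(names):
            if n in hit:
                log2[i] += design.effect_size
    return [RawRatioRecord((n,), float(2.0 ** v)) for n, v in zip(names, log2)]


def sample_profiles(
    Sigma: np.ndarray, mean: np.ndarray, n_samples: int, seed: int
) -> np.ndarray:
    """Draw n_samples i.i.d. vectors from MVN(mean, Sigma).

    Sigma must be symmetric positive definite; sampling goes through its
    Cholesky factor so a non-PD matrix fails immediately with the smallest
    eigenvalue in the message.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    mean = np.asarray(mean, dtype=float)
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        lam_min = float(linalg.eigvalsh(Sigma).min())
        raise ValueError(
            f"Sigma is not positive definite (smallest eigenvalue {lam_min:.3e})"
        ) from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, len(mean)))
    return mean + Z @ L.T


def make_psd_rulebook_sigma(
    order: tuple[str, ...],
    scores: InteractionScores,
    x_signs: np.ndarray,
    diag_constant: float = 0.4,
) -> tuple[np.ndarray, float]:
    """Build S by the four covariance rules, then shift the diagonal just
    enough to make it positive definite.

    The rule-built S can be indefinite (scores may exceed the diagonal
    constant); calibration sampling needs a PD matrix.  Returns
    (Sigma, shift) where shift = |λmin| + 1e-6 if λmin ≤ 0, else 0.
    """
    from .statistic import build_covariance

    cov = build_covariance(order, np.asarray(x_signs, float), scores, diag_constant)
    S = cov.S.copy()
    lam_min = float(linalg.eigvalsh(S).min())
    shift = 0.0
    if lam_min <= 0:
        shift = abs(lam_min) + 1e-6
        S = S + shift * np.eye(len(order))
    return S, shift


def fig8_preset() -> tuple[SimulationDesign, np.ndarray]:
    """The calibration demonstration preset: 10000 samples against a 20×20
    equicorrelation matrix with diagonal 1 and off-diagonal 0.5.

    Eigenvalues are 1+19·0.5 = 10.5 (once) and 0.5 (nineteen-fold), so the
    matrix is positive definite.
    """
    design = SimulationDesign(n_proteins=20, seed=0)
    Sigma = np.full((20, 20), 0.5)
    np.fill_diagonal(Sigma, 1.0)
    return design, Sigma


def simulate_bundle(design: SimulationDesign, outdir: str | Path) -> dict[str, str]:
    """Write a full fixture bundle: expression TSV, GMT, PPI TSV, manifest.

    Returns a map from artifact name to file path.  Everything is a pure
    function of the design (including its seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores = generate_interaction_network(design)
    collection = generate_pathway_collection(design)
    records = generate_expression_records(design, collection)

    expr_path = outdir / "expression.tsv"
    with expr_path.open("w") as fh:
        for rec in records:
            fh.write(f"{';'.join(rec.identifiers)}\t{rec.ratio:.6g}\n")
    gmt_path = outdir / "pathways.gmt"
    write_gene_sets_gmt(collection, gmt_path)
    ppi_path = outdir / "ppi.tsv"
    with ppi_path.open("w") as fh:
        for a, b, c in scores.pairs():
            fh.write(f"{a}\t{b}\t{c:.6g}\n")
    manifest_path = outdir / "manifest.json"
    manifest = {"design": asdict(design), "artifacts": ["expression.tsv", "pathways.gmt", "ppi.tsv"]}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "expression": str(expr_path),
        "gene_sets": str(gmt_path),
        "ppi": str(ppi_path),
        "manifest": str(manifest_path),
    }
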