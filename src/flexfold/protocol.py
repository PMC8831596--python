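"""Iterative ensemble-folding protocol: pool generation, ranking, clustering,
template reseeding, convergence, refinement.

Each iteration generates a pool of independently annealed models, ranks them
by total score, clusters the top fraction by greedy leader clustering on a
Cα-RMSD cutoff and reseeds the next iteration from the cluster
representatives. The incumbent best subunit is carried over (elitism), making
the best score non-increasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sampler import AnnealSchedule, FoldResult, SSAnnotation, init_conformation, mc_fold, minimize
from .scoring import CGParams, ScoreWeights, SymmetricScorer
from .structio import Ensemble, Structure, SymmetryFrame, ca_rmsd, structure_from_ca, symmetrize_c5

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolConfig",
    "ClusterResult",
    "IterationRecord",
    "ProtocolResult",
    "generate_pool",
    "rank_and_select",
    "cluster",
    "run_protocol",
]


@dataclass
class ProtocolConfig:
    """Loop control. Defaults are desk-scale; production-scale values
    (n_pool=1000, top_m=100) are plain flags on the same fields."""

    n_pool: int = 40
    top_m: int = 10
    rmsd_cutoff: float = 3.0  # Å
    max_iterations: int = 6
    convergence_window: int = 2
    # plateau threshold: improvements below ~the score scatter of the top
    # pool no longer change the selected fold
    convergence_tolerance: float = 10.0  # score units
    master_seed: int = 0
    moves_per_temperature: int = 300
    template_perturb_sigma: float = 1.0
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.top_m > self.n_pool:
            raise ValueError("top_m must be <= n_pool")
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")


@dataclass
class ClusterResult:
    assignments: dict[int, int]  # model index -> cluster id
    representatives: list[int]  # best-scoring member per cluster, by cluster id
    populations: list[int]


@dataclass
class IterationRecord:
    iteration: int
    best_s_total: float
    n_clusters: int
    top_cluster_population: int
    representative_rmsd_to_previous: float | None


@dataclass
class ProtocolResult:
    final: Ensemble
    final_subunits: list[np.ndarray]
    records: list[IterationRecord]
    converged: bool
    scores: list


def _run_seed(master_seed: int, iteration: int, run: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration, run))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_pool(
    templates: list[np.ndarray] | None,
    n: int,
    restraints: list,
    ss: SSAnnotation,
    residue_numbers: list[int],
    master_seed: int = 0,
    iteration: int = 0,
    moves_per_temperature: int = 200,
    template_perturb_sigma: float = 1.5,
    frame: SymmetryFrame | None = None,
    weights: ScoreWeights | None = None,
    params: CGParams | None = None,
    scorer: SymmetricScorer | None = None,
    ladder: list[float] | None = None,
) -> list[FoldResult]:
    """n independent annealing runs with per-run seeds derived from the
    master seed and run index; fully reproducible."""
    if n < 1:
        raise ValueError("pool size must be >= 1")
    frame = frame or SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    if scorer is None:
        scorer = SymmetricScorer(residue_numbers, restraints, ss.as_dict(),
                                 weights, params, frame)
    # template-seeded rounds refine: they anneal from a cooler ladder so the
    # inherited fold survives the hot stage
    if ladder is None:
        ladder = ([8.0, 3.0, 1.2, 0.5, 0.2, 0.08] if not templates
                  else [0.4, 0.15, 0.05])
    results = []
    for run in range(n):
        seed = _run_seed(master_seed, iteration, run)
        start = init_conformation(residue_numbers, ss, templates, seed=seed,
                                  perturb_sigma=template_perturb_sigma)
        schedule = AnnealSchedule(temperatures=list(ladder),
                                  moves_per_temperature=moves_per_temperature,
                                  seed=seed)
        results.append(
            mc_fold(start, ss, restraints, schedule,
                    residue_numbers=residue_numbers, frame=frame, scorer=scorer)
        )
    return results


def rank_and_select(pool: list[FoldResult], top_m: int) -> list[FoldResult]:
    """Ascending total score; ties broken by pool position (stable sort)."""
    for r in pool:
        if r.score is None:
            raise ValueError("model without a score in pool")
    ranked = sorted(range(len(pool)), key=lambda i: (pool[i].score.s_total, i))
    return [pool[i] for i in ranked[:top_m]]


def cluster(selected: list[FoldResult], cutoff: float) -> ClusterResult:
    """Greedy leader clustering on score-sorted order.

    The best-scoring unassigned model founds a cluster; every unassigned
    model within ``cutoff`` Cα RMSD (after superposition) joins it. Every
    member is therefore within the cutoff of its representative, and the
    representative has the minimal score in its cluster.
    """
    if len(selected) == 0:
        raise ValueError("nothing to cluster")
    order = sorted(range(len(selected)),
                   key=lambda i: (selected[i].score.s_total, i))
    assignments: dict[int, int] = {}
    representatives: list[int] = []
    populations: list[int] = []
    for leader in order:
        if leader in assignments:
            continue
        cid = len(representatives)
        representatives.append(leader)
        assignments[leader] = cid
        pop = 1
        for other in order:
            if other in assignments:
                continue
            if ca_rmsd(selected[other].model, selected[leader].model) <= cutoff:
                assignments[other] = cid
                pop += 1
        populations.append(pop)
    return ClusterResult(assignments=assignments, representatives=representatives,
                         populations=populations)


def run_protocol(
    config: ProtocolConfig,
    restraints: list,
    ss: SSAnnotation,
    residue_numbers: list[int],
    templates0: list[np.ndarray] | None = None,
    frame: SymmetryFrame | None = None,
    weights: ScoreWeights | None = None,
    params: CGParams | None = None,
) -> ProtocolResult:
    """Generate → rank → cluster → reseed until convergence, then refine.

    Initial templates (if any) are used only in the first round. Convergence
    is declared when the best total score improves by less than the tolerance
    over the convergence window AND the top representative moves by less than
    half the clustering cutoff between consecutive iterations. The final top
    models pass through local minimization.
    """
    frame = frame or SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    scorer = SymmetricScorer(residue_numbers, restraints, ss.as_dict(),
                             weights, params, frame)
    templates = templates0
    records: list[IterationRecord] = []
    best_history: list[float] = []
    prev_rep_model: Structure | None = None
    incumbent: FoldResult | None = None
    converged = False
    selected: list[FoldResult] = []

    for it in range(config.max_iterations):
        # first-round homolog templates still need a warm exploration stage;
        # reseeded representatives in later rounds only need refinement
        ladder = None
        if it == 0 and templates:
            ladder = [2.0, 0.8, 0.3, 0.12, 0.05]
        pool = generate_pool(
            templates, config.n_pool, restraints, ss, residue_numbers,
            master_seed=config.master_seed, iteration=it,
            moves_per_temperature=config.moves_per_temperature,
            template_perturb_sigma=config.template_perturb_sigma,
            frame=frame, scorer=scorer, ladder=ladder,
        )
        if config.elitism and incumbent is not None:
            pool = pool + [incumbent]
        selected = rank_and_select(pool, config.top_m)
        clusters = cluster(selected, config.rmsd_cutoff)
        incumbent = selected[0]
        best = incumbent.score.s_total
        best_history.append(best)

        rep = selected[clusters.representatives[0]]
        rep_rmsd = (ca_rmsd(rep.model, prev_rep_model)
                    if prev_rep_model is not None else None)
        prev_rep_model = rep.model
        records.append(IterationRecord(
            iteration=it, best_s_total=best, n_clusters=len(clusters.representatives),
            top_cluster_population=clusters.populations[0],
            representative_rmsd_to_previous=rep_rmsd,
        ))
        logger.info("iteration %d: best=%.3f clusters=%d", it, best,
                    len(clusters.representatives))

        templates = [selected[i].subunit_coords for i in clusters.representatives]

        if _has_converged(records, config):
            converged = True
            break

    # refinement: cold annealing then local minimization of the selected models
    final_subunits, final_models, final_scores = [], [], []
    for i, fr in enumerate(selected):
        seed = _run_seed(config.master_seed, 10_000, i)
        cold = AnnealSchedule(temperatures=[0.12, 0.05, 0.02],
                              moves_per_temperature=config.moves_per_temperature,
                              seed=seed)
        refined = mc_fold(fr.subunit_coords, ss, restraints, cold,
                          residue_numbers=residue_numbers, frame=frame,
                          scorer=scorer)
        x, score = minimize(refined.subunit_coords, ss, restraints,
                            residue_numbers=residue_numbers, frame=frame,
                            seed=seed + 1, max_steps=800, scorer=scorer)
        final_subunits.append(x)
        final_models.append(symmetrize_c5(
            structure_from_ca(x, first_residue=residue_numbers[0]), frame))
        final_scores.append(score)
    order = sorted(range(len(final_models)),
                   key=lambda i: (final_scores[i].s_total, i))
    return ProtocolResult(
        final=Ensemble(models=[final_models[i] for i in order]),
        final_subunits=[final_subunits[i] for i in order],
        records=records,
        converged=converged,
        scores=[final_scores[i] for i in order],
    )


def _has_converged(records: list[IterationRecord], config: ProtocolConfig) -> bool:
    """Pure function of the iteration log implementing the plateau rule."""
    w = config.convergence_window
    if len(records) < w + 1:
        return False
    improvement = records[-1 - w].best_s_total - records[-1].best_s_total
    if improvement >= config.convergence_tolerance:
        return False
    rep_move = records[-1].representative_rmsd_to_previous
    return rep_move is not None and rep_move < config.rmsd_cutoff / 2.0
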