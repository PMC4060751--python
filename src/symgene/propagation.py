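"""Label propagation over the PPI network (PRINCE-style update).

Starting from the prior Y, the update

    F_t = alpha * W' F_{t-1} + (1 - alpha) * Y,      F_1 = Y,

is iterated to its fixed point (1 - alpha)(I - alpha W')^{-1} Y, which exists
whenever the spectral radius of alpha W' is below 1 — guaranteed by the
degree-symmetric normalization for alpha < 1.  alpha weighs network smoothing
against the prior; 0.9 is the default.  Converged scores are ranked and genes
scoring strictly above ``score_cutoff`` (default 0.01) are reported as
potential symptom genes.  Output files label the score column "correlation",
following the field's customary table heading for these propagation scores;
they are not statistical correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import NormalizedAdjacency
from .prior import PriorVector

__all__ = [
    "PropagationConfig",
    "ScoreVector",
    "propagate",
    "rank_genes",
    "potential_genes",
    "write_ranking",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationConfig:
    """alpha in (0,1), L1 convergence tolerance, iteration cap, score cutoff."""

    alpha: float = 0.9
    tolerance: float = 1e-9
    max_iterations: int = 1000
    score_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ScoreVector:
    """Converged propagation scores F over the network node order."""

    symptom: str
    scores: np.ndarray
    nodes: tuple[str, ...]
    iterations_used: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, map(float, self.scores)))


def propagate(
    Wn: NormalizedAdjacency, Y: PriorVector, cfg: PropagationConfig = PropagationConfig()
) -> ScoreVector:
    """Iterate the propagation update until the L1 change falls below tolerance.

    Non-convergence within ``max_iterations`` returns the last iterate with
    ``converged=False`` and a warning; it never fails silently.
    """
    if Wn.nodes != Y.nodes:
        raise ValueError("node order of normalized adjacency and prior differ")
    y = np.asarray(Y.values, dtype=float)
    if not y.any():
        raise ValueError("prior has no nonzero entry")
    W = Wn.matrix
    alpha = cfg.alpha
    f = y.copy()
    iterations = 0
    converged = False
    for iterations in range(1, cfg.max_iterations + 1):
        f_next = alpha * (W @ f) + (1.0 - alpha) * y
        if np.abs(f_next - f).sum() < cfg.tolerance:
            f = f_next
            converged = True
            break
        f = f_next
    if not converged:
        logger.warning(
            "propagation for %r did not converge in %d iterations",
            Y.symptom,
            cfg.max_iterations,
        )
    return ScoreVector(Y.symptom, f, Y.nodes, iterations, converged)


def rank_genes(F: ScoreVector) -> list[tuple[str, float, int]]:
    """Rank genes by score descending, ties broken by gene id ascending.

    Ranks are 1-based and consecutive (tied genes get successive ranks in
    lexicographic order), so output is bit-reproducible across runs.
    """
    if not np.all(np.isfinite(F.scores)):
        raise ValueError("scores must be finite")
    order = sorted(zip(F.nodes, F.scores), key=lambda gs: (-gs[1], gs[0]))
    return [(g, float(s), r) for r, (g, s) in enumerate(order, start=1)]


def potential_genes(
    ranked: list[tuple[str, float, int]], cfg: PropagationConfig = PropagationConfig()
) -> list[tuple[str, float, int]]:
    """Genes scoring strictly above the cutoff, order preserved."""
    return [(g, s, r) for g, s, r in ranked if s > cfg.score_cutoff]


def write_ranking(ranked: list[tuple[str, float, int]], path: str | Path) -> None:
    """Write TSV rank / gene / correlation with 14-decimal scores."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene\tcorrelation\n")
        for g, s, r in ranked:
            fh.write(f"{r}\t{g}\t{s:.14f}\n")
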