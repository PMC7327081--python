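"""Pearson co-expression with t-based significance and stage networks.

A gene pair is co-expressed over a sample set when |rho| > tau (default
0.7) with a two-sided p-value below 0.05, where

    t = rho * sqrt(n - 2) / sqrt(1 - rho^2)

is referred to Student's t with n - 2 degrees of freedom.  A stage's
reference network has the stage's selected DEGs as nodes and its
co-expressed pairs as edges, held in a canonical (lexicographic) edge
order that downstream perturbation vectors index into positionally.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffexpr import DEGRecord
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.7
DEFAULT_P_CUT = 0.05


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant expression vector."""


def pearson_pcc(x, y) -> float:
    """Pearson correlation rho = (E[XY] - E[X]E[Y]) / (sd(X) sd(Y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sx = np.sqrt(np.mean(x * x) - np.mean(x) ** 2)
    sy = np.sqrt(np.mean(y * y) - np.mean(y) ** 2)
    if sx == 0.0 or sy == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    rho = (np.mean(x * y) - np.mean(x) * np.mean(y)) / (sx * sy)
    return float(np.clip(rho, -1.0, 1.0))


def pcc_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a correlation via the t transform, df = n - 2."""
    if n < 3:
        raise ValueError("p-value needs n >= 3 samples")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho {rho} outside [-1, 1]")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho * rho)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CoexpressionEdge:
    """One co-expressed gene pair; ``gene_a < gene_b`` canonically."""

    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError(f"edge genes not in canonical order: "
                             f"{self.gene_a!r} !< {self.gene_b!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class StageNetwork:
    """Reference co-expression network for one group (control or stage 1-4).

    ``edges`` is immutable once built and lexicographically ordered by
    gene pair; that order is the positional contract for perturbation
    vectors.
    """

    stage: int | str
    reference_samples: list[str]
    node_genes: list[str]
    edges: tuple[CoexpressionEdge, ...]
    threshold_tau: float = DEFAULT_TAU
    p_cut: float = DEFAULT_P_CUT
    dropped_constant_genes: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> list[tuple[str, str]]:
        return [e.pair for e in self.edges]

    def checksum(self) -> str:
        """Digest of the full network state (non-mutation assertions)."""
        h = hashlib.sha256()
        h.update(repr(self.stage).encode())
        h.update("\x1f".join(self.reference_samples).encode())
        h.update("\x1f".join(self.node_genes).encode())
        h.update(f"{self.threshold_tau!r}|{self.p_cut!r}".encode())
        for e in self.edges:
            h.update(f"{e.gene_a}|{e.gene_b}|{e.rho!r}|{e.p_value!r}|{e.n_samples}".encode())
        return h.hexdigest()


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between rows of ``values``."""
    centered = values - values.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = centered / sd[:, None]
        corr = norm @ norm.T / values.shape[1]
    return np.clip(corr, -1.0, 1.0)


def build_stage_network(expr: ExpressionMatrix, samples: list[str],
                        genes: list[str], *, stage: int | str = 0,
                        tau: float = DEFAULT_TAU, p_cut: float = DEFAULT_P_CUT,
                        assume_counts: bool | None = None) -> StageNetwork:
    """Build the reference network over ``samples`` restricted to ``genes``.

    Edges are exactly the canonical gene pairs with |rho| > tau (strict)
    and p < p_cut over the reference samples, on log2-scale expression.
    Genes constant over the reference samples have undefined correlations
    and are dropped from the node set with a log notice.
    """
    from .diffexpr import log2_scale

    if len(samples) < 3:
        raise ValueError("need at least 3 reference samples")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    logv = log2_scale(expr, assume_counts=assume_counts)
    sub = logv[np.ix_(expr.gene_rows(list(genes)), expr.sample_cols(list(samples)))]

    constant = sub.std(axis=1) == 0
    dropped = [g for g, c in zip(genes, constant) if c]
    if dropped:
        logger.info("stage %s network: dropped %d constant gene(s): %s",
                    stage, len(dropped), dropped[:5])
    kept = [g for g, c in zip(genes, constant) if not c]
    sub = sub[~constant]

    n = len(samples)
    corr = correlation_matrix(sub)
    edges: list[CoexpressionEdge] = []
    order = sorted(range(len(kept)), key=lambda i: kept[i])
    for ii, i in enumerate(order):
        for j in order[ii + 1:]:
            rho = float(corr[i, j])
            if abs(rho) > tau:
                p = pcc_pvalue(rho, n)
                if p < p_cut:
                    a, b = kept[i], kept[j]
                    edges.append(CoexpressionEdge(a, b, rho, p, n))
    return StageNetwork(stage=stage, reference_samples=list(samples),
                        node_genes=sorted(kept), edges=tuple(edges),
                        threshold_tau=tau, p_cut=p_cut,
                        dropped_constant_genes=dropped)


def ceg_pairs_by_direction(
    network: StageNetwork, deg_records: list[DEGRecord],
) -> tuple[set[tuple[str, str]], set[tuple[str, str]], set[tuple[str, str]]]:
    """Split network edges into up/up, down/down and mixed-direction pairs.

    Only concordant pairs enter the Up and Down universes used for
    enrichment; mixed pairs are returned separately for reporting.
    """
    direction = {r.gene_id: r.direction for r in deg_records}
    missing = [g for g in network.node_genes if g not in direction]
    if missing:
        raise ValueError(f"network genes without a DEG direction: {missing[:5]}")
    up, down, mixed = set(), set(), set()
    for e in network.edges:
        da, db = direction[e.gene_a], direction[e.gene_b]
        if da == db == "up":
            up.add(e.pair)
        elif da == db == "down":
            down.add(e.pair)
        else:
            mixed.add(e.pair)
    return up, down, mixed
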