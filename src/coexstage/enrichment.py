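"""Gene-pair hypergeometric pathway enrichment and stage-evolution analysis.

Enrichment here is over *pairs* of genes rather than genes: within one
regulation direction, the universe holds all N = C(d, 2) unordered pairs
of the d DEGs, of which K pairs are co-expressed.  A pathway whose
intersection with the DEG set spans n pairs, k of them co-expressed, is
scored by the upper-tail hypergeometric probability P(X >= k) of drawing
at least k co-expressed pairs in n draws from the (N, K) urn.  The
point mass P(X = k) is available as a compatibility mode.

Comparing which pathways are enriched in control tissue and at each
stage yields the evolution summary: functions that persist through all
stages, disappear at a given stage (and never return), recur
intermittently, or emerge in early (1-2) or advanced (3-4) disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import canonical_pair
from .diffexpr import DEGRecord
from .io import STAGES, PathwayCollection

DEFAULT_ALPHA = 0.05


@dataclass
class PairUniverse:
    """The (N, K) urn for one regulation direction.

    N = number of DEG pairs, K = co-expressed pairs among them.
    """

    direction: str
    deg_genes: frozenset[str]
    ceg_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.ceg_pairs:
            if a not in self.deg_genes or b not in self.deg_genes:
                raise ValueError(
                    f"co-expressed pair ({a!r}, {b!r}) uses a gene outside "
                    f"the {self.direction}-regulated DEG set"
                )

    @property
    def N(self) -> int:
        return comb(len(self.deg_genes), 2)

    @property
    def K(self) -> int:
        return len(self.ceg_pairs)


def build_pair_universe(deg_records: list[DEGRecord],
                        ceg_pairs: set[tuple[str, str]],
                        direction: str) -> PairUniverse:
    """Universe of one direction's DEG pairs and its co-expressed subset."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    genes = frozenset(r.gene_id for r in deg_records if r.direction == direction)
    pairs = frozenset(canonical_pair(a, b) for a, b in ceg_pairs)
    return PairUniverse(direction, genes, pairs)


@dataclass
class PairEnrichmentResult:
    pathway_id: str
    n: int  # pathway DEG pairs
    k: int  # co-expressed pairs among them
    N: int
    K: int
    p_value: float
    adjusted_p: float = float("nan")
    enriched: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n <= self.N and self.k <= self.K):
            raise ValueError(
                f"inconsistent pair counts for {self.pathway_id!r}: "
                f"k={self.k}, n={self.n}, N={self.N}, K={self.K}"
            )


def hypergeom_pair_pvalue(N: int, K: int, n: int, k: int,
                          *, point_mass: bool = False) -> float:
    """P(X >= k) (or P(X = k)) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    if n == 0:
        return 1.0
    dist = stats.hypergeom(N, K, n)
    if point_mass:
        return float(dist.pmf(k))
    return float(dist.sf(k - 1))


def enrich_pathway(universe: PairUniverse, pathway_genes: frozenset[str] | set[str],
                   pathway_id: str = "", *, point_mass: bool = False) -> PairEnrichmentResult:
    """Score one pathway's gene set against the pair universe.

    The pathway contributes its intersection with the universe's DEG set;
    n is the number of pairs within that intersection and k the number of
    those pairs that are co-expressed.  A pathway spanning no DEG pair
    (n = 0) gets p = 1 by convention.
    """
    effective = frozenset(pathway_genes) & universe.deg_genes
    n = comb(len(effective), 2)
    k = sum(1 for a, b in universe.ceg_pairs if a in effective and b in effective)
    p = hypergeom_pair_pvalue(universe.N, universe.K, n, k, point_mass=point_mass)
    return PairEnrichmentResult(pathway_id, n, k, universe.N, universe.K, float(p))


def enrich_all(universe: PairUniverse, pathways: PathwayCollection,
               alpha: float = DEFAULT_ALPHA, *, point_mass: bool = False,
               adjust: bool = True) -> list[PairEnrichmentResult]:
    """Score every pathway; flag enrichment at Benjamini-Hochberg FDR alpha.

    ``adjust=False`` switches the enrichment call to the raw p-value.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway collection")
    results = [enrich_pathway(universe, genes, pid, point_mass=point_mass)
               for pid, genes in pathways.items()]
    pvals = [r.p_value for r in results]
    if adjust:
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        adj = pvals
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
        r.enriched = bool(a < alpha)
    return results


def enriched_set(results: list[PairEnrichmentResult]) -> set[str]:
    return {r.pathway_id for r in results if r.enriched}


# ---------------------------------------------------------------------------
# evolution across stages

@dataclass
class EvolutionSummary:
    """How control-tissue functions persist, vanish or newly arise with stage.

    ``disappeared_at[s]`` holds pathways enriched in control and in every
    stage before s but in no stage at or after s; pathways whose pattern
    is non-monotone land in ``intermittent``.  Emergent pathways are
    absent in control and enriched somewhere early (stages 1-2) or
    advanced (stages 3-4); a pathway straddling both windows appears in
    both emergent sets.
    """

    persistent: set[str] = field(default_factory=set)
    disappeared_at: dict[int, set[str]] = field(default_factory=dict)
    intermittent: set[str] = field(default_factory=set)
    emergent_early: set[str] = field(default_factory=set)
    emergent_advanced: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "persistent": sorted(self.persistent),
            "disappeared_at": {str(s): sorted(v) for s, v in self.disappeared_at.items()},
            "disappeared_total": len(set().union(*self.disappeared_at.values())
                                     if self.disappeared_at else set()),
            "intermittent": sorted(self.intermittent),
            "emergent_early": sorted(self.emergent_early),
            "emergent_advanced": sorted(self.emergent_advanced),
            "counts": {
                "persistent": len(self.persistent),
                **{f"disappeared_stage{s}": len(v)
                   for s, v in self.disappeared_at.items()},
                "intermittent": len(self.intermittent),
                "emergent_early": len(self.emergent_early),
                "emergent_advanced": len(self.emergent_advanced),
            },
        }


def evolution_summary(control_enriched: set[str],
                      stage_enriched: dict[int, set[str]]) -> EvolutionSummary:
    """Partition control-enriched pathways and collect emergent ones."""
    missing = [s for s in STAGES if s not in stage_enriched]
    if missing:
        raise ValueError(f"stage enrichment sets missing for stages {missing}")
    summary = EvolutionSummary(disappeared_at={s: set() for s in STAGES})
    for pw in control_enriched:
        present = [pw in stage_enriched[s] for s in STAGES]
        if all(present):
            summary.persistent.add(pw)
            continue
        # disappearance stage: enriched at every stage before s, absent from s on
        placed = False
        for s in STAGES:
            if all(present[: s - 1]) and not any(present[s - 1:]):
                summary.disappeared_at[s].add(pw)
                placed = True
                break
        if not placed:
            summary.intermittent.add(pw)
    early = stage_enriched[1] | stage_enriched[2]
    advanced = stage_enriched[3] | stage_enriched[4]
    summary.emergent_early = early - control_enriched
    summary.emergent_advanced = advanced - control_enriched
    return summary
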