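"""Synthetic stage-stratified expression with planted co-expression modules.

The generator emulates the structure the staging method relies on: each
tumor stage carries its own modules of mutually co-expressed,
differentially expressed genes, while control tissue carries none.  Genes
inside a module load on a shared per-sample latent factor, which gives
exact control over the population pairwise Pearson correlation; module
genes are additionally mean-shifted against control so they are
recoverable as DEGs.  Each module gene's shift direction is drawn at
random (real stage modules mix up- and down-regulated genes), which is
also what makes the planted signal perturbable: a sample lacking the
module lands off the module's correlation axis for discordant gene
pairs, so single-sample network perturbation can see it.  Everything
outside the planted modules is independent Gaussian noise around a
common baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CONTROL, STAGES, ExpressionMatrix


@dataclass
class SimulationConfig:
    """Parameters of the staged-expression generator.

    Defaults describe a desk-scale dataset with a strong, cleanly
    recoverable signal: four stages of 60 samples plus 60 controls over
    300 genes, two 15-gene modules per stage with within-module
    correlation 0.9 and a log2 fold change of magnitude 3 against
    control.  ``noise_sd`` is the residual SD of a gene on log2 scale
    within its group; 0.3 is typical of well-expressed genes in
    homogeneous tissue, and keeps the DE shift at several within-group
    SDs -- the regime in which one added sample can visibly perturb a
    reference correlation.
    """

    n_genes: int = 300
    samples_per_group: int = 60
    modules_per_stage: int = 2
    module_size: int = 15
    within_module_correlation: float = 0.9
    de_effect_logfc: float = 3.0
    noise_sd: float = 0.3
    baseline_mean: float = 5.0
    #: plant the *same* modules in all four stages (stage-uninformative null)
    shared_modules: bool = False
    #: exponentiate the log-scale values into pseudo-counts
    as_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must lie in (0, 1)")
        n_module_genes = self._n_module_sets * self.modules_per_stage * self.module_size
        if n_module_genes > self.n_genes:
            raise ValueError(
                f"planted modules need {n_module_genes} genes but only "
                f"{self.n_genes} are available"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")

    @property
    def _n_module_sets(self) -> int:
        return 1 if self.shared_modules else len(STAGES)


@dataclass
class GroundTruth:
    """Registry of what was planted, keyed by stage."""

    modules: dict[int, list[list[str]]] = field(default_factory=dict)
    degs: dict[int, list[str]] = field(default_factory=dict)
    #: per-stage planted DEG directions, gene -> "up" | "down"
    deg_direction: dict[int, dict[str, str]] = field(default_factory=dict)

    def module_pairs(self, stage: int) -> set[tuple[str, str]]:
        """All within-module gene pairs of ``stage`` in canonical order."""
        pairs: set[tuple[str, str]] = set()
        for module in self.modules[stage]:
            for i, a in enumerate(module):
                for b in module[i + 1:]:
                    pairs.add((a, b) if a < b else (b, a))
        return pairs

    def to_dict(self) -> dict:
        return {"modules": {str(s): m for s, m in self.modules.items()},
                "degs": {str(s): d for s, d in self.degs.items()},
                "deg_direction": {str(s): d for s, d in self.deg_direction.items()}}


def simulate_staged_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, int | str], GroundTruth]:
    """Generate expression, stage labels and the planted ground truth.

    Module genes of stage *s* are, in stage-*s* samples only,

        x = mu + d_g * delta + lam * f + sigma * eps,

    with one latent factor ``f ~ N(0,1)`` per module per sample, a
    per-gene shift direction ``d_g`` drawn uniformly from {-1, +1}, and
    ``lam`` chosen so the population correlation between any two genes of
    the module equals ``within_module_correlation``
    (rho = lam^2 / (lam^2 + sigma^2)).  In every other group those genes
    are baseline noise, so they are differentially expressed and
    co-expressed exclusively in their own stage.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rho, sigma = cfg.within_module_correlation, cfg.noise_sd
    # rho = lam^2/(lam^2 + sigma^2)  =>  lam = sigma * sqrt(rho/(1-rho))
    lam = sigma * np.sqrt(rho / (1.0 - rho))

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    groups: list[int | str] = [CONTROL, *STAGES]
    sample_ids: list[str] = []
    labels: dict[str, int | str] = {}
    for grp in groups:
        tag = "C" if grp == CONTROL else f"S{grp}"
        for i in range(cfg.samples_per_group):
            sid = f"{tag}_{i:03d}"
            sample_ids.append(sid)
            labels[sid] = grp

    n_total = len(sample_ids)
    values = cfg.baseline_mean + sigma * rng.standard_normal((cfg.n_genes, n_total))

    # assign disjoint gene blocks to modules
    truth = GroundTruth()
    cursor = 0
    module_genes: dict[int, list[list[int]]] = {}
    module_sets = 1 if cfg.shared_modules else len(STAGES)
    planted: list[list[list[int]]] = []
    for _ in range(module_sets):
        mods = []
        for _ in range(cfg.modules_per_stage):
            idx = list(range(cursor, cursor + cfg.module_size))
            cursor += cfg.module_size
            mods.append(idx)
        planted.append(mods)
    # one shift direction per gene of each planted block, shared across
    # stages when the blocks are shared
    sign_of: dict[int, int] = {}
    for mods in planted:
        for idx in mods:
            for i in idx:
                sign_of[i] = int(rng.choice((-1, 1)))

    for stage in STAGES:
        module_genes[stage] = planted[0] if cfg.shared_modules else planted[stage - 1]
        truth.modules[stage] = [[gene_ids[i] for i in m] for m in module_genes[stage]]
        truth.degs[stage] = sorted({gene_ids[i] for m in module_genes[stage] for i in m})
        truth.deg_direction[stage] = {
            gene_ids[i]: ("up" if sign_of[i] > 0 else "down")
            for m in module_genes[stage] for i in m}

    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    for stage in STAGES:
        cols = np.array([col_of[s] for s, g in labels.items() if g == stage])
        for idx in module_genes[stage]:
            factor = rng.standard_normal(len(cols))
            rows = np.asarray(idx)
            shift = cfg.de_effect_logfc * np.array([sign_of[i] for i in idx])
            values[np.ix_(rows, cols)] += shift[:, None] + lam * factor[None, :]

    if cfg.as_counts:
        values = np.rint(np.exp2(values)).clip(min=0)

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    return expr, labels, truth
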