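"""Per-stage differential expression against control and DEG-set balancing.

Stage networks are built over stage-specific DEG sets.  The built-in test
is Welch's two-sample t on log2-scale expression with strict cutoffs
|log2 FC| > 2.5 and p < 0.05; a pluggable import path accepts an external
DE table (e.g. an edgeR export) so an upstream count model can replace
the built-in test without touching the rest of the pipeline.

Because DEG counts differ across stages, the selected sets are balanced:
n is the smallest per-stage DEG count and each stage keeps its n DEGs of
largest expression variance, so no stage network is bigger merely because
its contrast yielded more genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL, STAGES, ExpressionMatrix, samples_by_group

logger = logging.getLogger(__name__)

DEFAULT_LOGFC_CUT = 2.5
DEFAULT_P_CUT = 0.05


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log_fc: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.log_fc > 0 else "down"


@dataclass
class StageDEGSet:
    stage: int
    records: list[DEGRecord]
    selected_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def directions(self) -> dict[str, str]:
        return {r.gene_id: r.direction for r in self.records}


def log2_scale(expr: ExpressionMatrix, *, assume_counts: bool | None = None) -> np.ndarray:
    """Expression on log2 scale.

    Integer-valued matrices are treated as raw counts and converted to
    log2(CPM + 1); anything else is assumed to be on a log-like scale
    already.  Override the auto-detection with ``assume_counts``.
    """
    v = expr.values
    if assume_counts is None:
        assume_counts = bool(np.all(v >= 0) and np.all(np.equal(np.mod(v, 1), 0)) and v.max() > 50)
    if assume_counts:
        libsize = v.sum(axis=0)
        libsize = np.where(libsize == 0, 1.0, libsize)
        return np.log2(v / libsize * 1e6 + 1.0)
    return v


def identify_degs(expr: ExpressionMatrix, labels: Mapping[str, int | str],
                  stage: int, *, logfc_cut: float = DEFAULT_LOGFC_CUT,
                  p_cut: float = DEFAULT_P_CUT,
                  samples: list[str] | None = None,
                  assume_counts: bool | None = None) -> list[DEGRecord]:
    """Genes differentially expressed between one tumor stage and control.

    Welch's t on log2-scale values, gene by gene; a gene is a DEG iff
    |log2 FC| > ``logfc_cut`` and p < ``p_cut``, both strict.  Genes that
    are constant in both groups carry no testable signal and are dropped
    with a log notice.  ``samples`` optionally restricts the stage/control
    sample pool (used by the leakage-guarded protocol variant).
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    groups = samples_by_group(labels)
    stage_samples = groups[stage]
    control_samples = groups[CONTROL]
    if samples is not None:
        pool = set(samples)
        stage_samples = [s for s in stage_samples if s in pool]
        control_samples = [s for s in control_samples if s in pool]
    if len(stage_samples) < 2 or len(control_samples) < 2:
        raise ValueError(
            f"stage {stage} needs >=2 stage and >=2 control samples "
            f"(got {len(stage_samples)} and {len(control_samples)})"
        )

    logv = log2_scale(expr, assume_counts=assume_counts)
    a = logv[:, expr.sample_cols(stage_samples)]
    b = logv[:, expr.sample_cols(control_samples)]

    log_fc = a.mean(axis=1) - b.mean(axis=1)
    both_constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue)
    # equal constant groups -> zero FC and no evidence; flag and drop
    n_const = int(both_constant.sum())
    if n_const:
        logger.info("identify_degs stage %s: skipped %d constant gene(s)", stage, n_const)
    p = np.where(both_constant, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)

    keep = (~both_constant) & (np.abs(log_fc) > logfc_cut) & (p < p_cut)
    return [DEGRecord(expr.gene_ids[i], float(log_fc[i]), float(p[i]))
            for i in np.flatnonzero(keep)]


def degs_from_table(table: pd.DataFrame | str, *,
                    logfc_cut: float = DEFAULT_LOGFC_CUT,
                    p_cut: float = DEFAULT_P_CUT) -> list[DEGRecord]:
    """Import an external DE table (gene, logFC, p-value) through the same cutoffs.

    Accepts edgeR-style column names (``logFC``/``PValue``) as well as
    plain ``log_fc``/``p_value``.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    cols = {c.lower().replace("-", "").replace("_", "").replace(".", ""): c
            for c in table.columns}
    try:
        gene_c = next(cols[k] for k in ("gene", "geneid", "genes") if k in cols)
        fc_c = next(cols[k] for k in ("logfc", "log2fc", "log2foldchange") if k in cols)
        p_c = next(cols[k] for k in ("pvalue", "p", "pval") if k in cols)
    except StopIteration:
        raise ValueError(
            f"DE table needs gene, logFC and p-value columns; got {list(table.columns)}"
        ) from None
    records = []
    for _, row in table.iterrows():
        fc, p = float(row[fc_c]), float(row[p_c])
        if abs(fc) > logfc_cut and p < p_cut:
            records.append(DEGRecord(str(row[gene_c]), fc, p))
    return records


def balance_deg_sets(per_stage: dict[int, StageDEGSet], expr: ExpressionMatrix,
                     labels: Mapping[str, int | str], *,
                     variance_samples: Mapping[int, list[str]] | None = None,
                     assume_counts: bool | None = None) -> dict[int, StageDEGSet]:
    """Equalize DEG-set sizes across stages by top-variance selection.

    n is the minimum DEG count over the four stages; each stage keeps its
    n DEGs of largest log2-expression variance, computed over that
    stage's own tumor samples (``variance_samples`` can restrict the pool,
    e.g. to reference+training under a strict split).  Variance ties break
    by gene identifier so the selection is deterministic.
    """
    missing = [s for s in STAGES if s not in per_stage]
    if missing:
        raise ValueError(f"DEG sets missing for stages {missing}")
    counts = {s: len(per_stage[s].records) for s in STAGES}
    empty = [s for s, c in counts.items() if c == 0]
    if empty:
        raise ValueError(
            f"stage(s) {empty} have no DEGs; relax --logfc-cut / --p-cut"
        )
    n = min(counts.values())

    logv = log2_scale(expr, assume_counts=assume_counts)
    groups = samples_by_group(labels)
    out: dict[int, StageDEGSet] = {}
    for stage in STAGES:
        degset = per_stage[stage]
        pool = (variance_samples[stage] if variance_samples is not None
                else groups[stage])
        if not pool:
            raise ValueError(f"no samples available to rank variance for stage {stage}")
        cols = expr.sample_cols(pool)
        rows = expr.gene_rows(degset.genes)
        var = logv[np.ix_(rows, cols)].var(axis=1, ddof=1)
        order = sorted(range(len(rows)), key=lambda i: (-var[i], degset.genes[i]))
        selected = sorted(degset.genes[i] for i in order[:n])
        out[stage] = StageDEGSet(stage, list(degset.records), selected)
    sizes = {len(s.selected_genes) for s in out.values()}
    assert sizes == {n}, "balanced DEG sets must have equal size"
    return out
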