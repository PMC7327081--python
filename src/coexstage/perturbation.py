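"""Single-sample network perturbation and fixed-layout feature vectors.

A sample is scored against a stage's reference network by re-computing
every edge's Pearson correlation over the reference samples *plus* the
sample.  An edge whose expanded-set |rho| stays above the network's
threshold keeps its (recomputed) correlation at its fixed vector
position; an edge pulled to or below the threshold is recorded as 0.0.
The four per-stage vectors, concatenated in stage order, are the feature
vector a stage classifier consumes.

The per-edge update is O(1) thanks to precomputed reference sums, so a
whole sample costs O(edges).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .coexpression import StageNetwork, build_stage_network
from .diffexpr import log2_scale
from .io import STAGES, ExpressionMatrix


@dataclass
class PerturbationVector:
    sample_id: str
    stage_of_network: int | str
    values: np.ndarray  # aligned with the network's canonical edge order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class FeatureLayout:
    """Positional contract: which (stage, gene pair) each feature index means."""

    positions: list[tuple[int | str, str, str]]

    def __len__(self) -> int:
        return len(self.positions)

    def checksum(self) -> str:
        payload = json.dumps([[str(s), a, b] for s, a, b in self.positions])
        return hashlib.sha256(payload.encode()).hexdigest()

    def block_slices(self) -> dict[int | str, slice]:
        slices: dict[int | str, slice] = {}
        start = 0
        current = None
        for i, (s, _, _) in enumerate(self.positions):
            if s != current:
                if current is not None:
                    slices[current] = slice(start, i)
                current, start = s, i
        if current is not None:
            slices[current] = slice(start, len(self.positions))
        return slices

    def to_dict(self) -> dict:
        return {"checksum": self.checksum(),
                "positions": [[str(s), a, b] for s, a, b in self.positions]}


@dataclass
class FeatureVector:
    sample_id: str
    values: np.ndarray
    layout: FeatureLayout

    def block(self, stage: int | str) -> np.ndarray:
        return self.values[self.layout.block_slices()[stage]]


class _EdgeState:
    """Reference-set sufficient statistics for O(1) expanded-set PCC."""

    def __init__(self, network: StageNetwork, expr: ExpressionMatrix,
                 assume_counts: bool | None = None):
        self.network = network
        logv = log2_scale(expr, assume_counts=assume_counts)
        genes = network.node_genes
        rows = expr.gene_rows(genes)
        cols = expr.sample_cols(network.reference_samples)
        ref = logv[np.ix_(rows, cols)]
        gidx = {g: i for i, g in enumerate(genes)}
        self.ia = np.array([gidx[e.gene_a] for e in network.edges], dtype=int)
        self.ib = np.array([gidx[e.gene_b] for e in network.edges], dtype=int)
        self.n_ref = ref.shape[1]
        self.s1 = ref.sum(axis=1)            # per-gene sum
        self.s2 = (ref * ref).sum(axis=1)    # per-gene sum of squares
        self.sxy = (ref[self.ia] * ref[self.ib]).sum(axis=1)  # per-edge cross sum
        self._gene_rows = rows
        self._logv = logv
        self._expr = expr

    def expanded_rho(self, sample_id: str) -> np.ndarray:
        """Edge correlations over reference samples plus ``sample_id``."""
        col = self._expr.sample_cols([sample_id])[0]
        v = self._logv[self._gene_rows, col]
        n = self.n_ref + 1
        s1 = self.s1 + v
        s2 = self.s2 + v * v
        sxy = self.sxy + v[self.ia] * v[self.ib]
        num = n * sxy - s1[self.ia] * s1[self.ib]
        var_a = n * s2[self.ia] - s1[self.ia] ** 2
        var_b = n * s2[self.ib] - s1[self.ib] ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = num / np.sqrt(var_a * var_b)
        # a constant expanded profile has undefined correlation: treat as lost
        rho = np.nan_to_num(rho, nan=0.0)
        return np.clip(rho, -1.0, 1.0)


def perturb_network(network: StageNetwork, expr: ExpressionMatrix,
                    new_sample: str, *, assume_counts: bool | None = None,
                    _state: _EdgeState | None = None) -> PerturbationVector:
    """Perturbation entries of ``new_sample`` against one stage network.

    Entry i is the expanded-set correlation of edge i when its magnitude
    stays above the network threshold, else exactly 0.0.  The reference
    network is never mutated.
    """
    if new_sample in set(network.reference_samples):
        raise ValueError(f"sample {new_sample!r} is part of the reference set")
    state = _state or _EdgeState(network, expr, assume_counts=assume_counts)
    rho = state.expanded_rho(new_sample)
    values = np.where(np.abs(rho) > network.threshold_tau, rho, 0.0)
    return PerturbationVector(new_sample, network.stage, values)


def build_feature_vector(networks: dict[int, StageNetwork], expr: ExpressionMatrix,
                         sample: str, *, assume_counts: bool | None = None) -> FeatureVector:
    """Concatenate the four per-stage perturbation vectors in stage order."""
    _require_stage_networks(networks)
    parts, positions = [], []
    for stage in STAGES:
        net = networks[stage]
        pv = perturb_network(net, expr, sample, assume_counts=assume_counts)
        parts.append(pv.values)
        positions.extend((stage, e.gene_a, e.gene_b) for e in net.edges)
    return FeatureVector(sample, np.concatenate(parts), FeatureLayout(positions))


def build_feature_matrix(networks: dict[int, StageNetwork], expr: ExpressionMatrix,
                         samples: list[str], *,
                         assume_counts: bool | None = None
                         ) -> tuple[pd.DataFrame, FeatureLayout]:
    """Feature vectors for many samples under one shared layout."""
    _require_stage_networks(networks)
    states = {s: _EdgeState(networks[s], expr, assume_counts=assume_counts)
              for s in STAGES}
    positions = [(s, e.gene_a, e.gene_b) for s in STAGES for e in networks[s].edges]
    layout = FeatureLayout(positions)
    rows = []
    for sid in samples:
        parts = []
        for stage in STAGES:
            net = networks[stage]
            pv = perturb_network(net, expr, sid, _state=states[stage])
            parts.append(pv.values)
        rows.append(np.concatenate(parts))
    cols = [f"s{s}:{a}|{b}" for s, a, b in positions]
    df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(cols))),
                      index=samples, columns=cols)
    return df, layout


def _require_stage_networks(networks: dict[int, StageNetwork]) -> None:
    missing = [s for s in STAGES if s not in networks]
    if missing:
        raise ValueError(f"networks missing for stages {missing}")


class PerturbationFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: reference networks in, perturbation features out.

    ``fit(X, y)`` takes a samples-x-genes DataFrame of *reference*
    samples and their stage labels, builds one co-expression network per
    stage over the genes named in ``stage_genes``, and freezes the
    feature layout.  ``transform(X)`` then maps any samples-x-genes
    DataFrame (samples disjoint from the references) onto perturbation
    feature vectors.

    Parameters
    ----------
    stage_genes : dict mapping stage (1-4) to the node gene list
        (typically the balanced DEG selection for that stage).
    tau : correlation magnitude an edge must strictly exceed (default 0.7).
    p_cut : significance cutoff for reference edges (default 0.05).
    assume_counts : force or suppress count detection / log2 CPM transform.
    """

    def __init__(self, stage_genes: dict[int, list[str]] | None = None,
                 tau: float = 0.7, p_cut: float = 0.05,
                 assume_counts: bool | None = None):
        self.stage_genes = stage_genes
        self.tau = tau
        self.p_cut = p_cut
        self.assume_counts = assume_counts

    def fit(self, X: pd.DataFrame, y=None) -> "PerturbationFeaturizer":
        if self.stage_genes is None:
            raise ValueError("stage_genes must be provided")
        if y is None:
            raise ValueError("fit needs the stage label of each reference sample")
        X = self._as_frame(X)
        y = np.asarray(list(y))
        expr = ExpressionMatrix(list(X.columns), list(X.index), X.to_numpy().T)
        self.networks_ = {}
        for stage in STAGES:
            ref = [s for s, lab in zip(X.index, y) if int(lab) == stage]
            self.networks_[stage] = build_stage_network(
                expr, ref, list(self.stage_genes[stage]), stage=stage,
                tau=self.tau, p_cut=self.p_cut, assume_counts=self.assume_counts)
        self.layout_ = FeatureLayout(
            [(s, e.gene_a, e.gene_b) for s in STAGES
             for e in self.networks_[s].edges])
        self.n_features_out_ = len(self.layout_)
        self._reference_expr = expr
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "networks_")
        X = self._as_frame(X)
        ref = self._reference_expr
        combined = ExpressionMatrix(
            ref.gene_ids,
            ref.sample_ids + list(X.index),
            np.hstack([ref.values, X[ref.gene_ids].to_numpy().T]),
        )
        df, _ = build_feature_matrix(self.networks_, combined, list(X.index),
                                     assume_counts=self.assume_counts)
        return df.to_numpy()

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples-x-genes DataFrame with identifiers")
        return X
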