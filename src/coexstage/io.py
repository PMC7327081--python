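"""Readers and writers for the pipeline's on-disk formats.

Expression matrices, stage labels and network edge lists travel as
tab-separated text; pathway collections as standard GMT; reports and
layout manifests as JSON.  Every reader validates the invariants of the
object it builds (unique identifiers, finite values, known stage labels)
and fails loudly rather than repairing input.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONTROL = "control"
STAGES = (1, 2, 3, 4)
#: the five admissible group labels, normal tissue plus four tumor stages
GROUPS = (CONTROL,) + STAGES


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``, in whatever units the source supplied (raw counts,
    CPM, or log scale -- downstream steps detect integer count matrices
    and log-transform where correlation is computed).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value for gene {self.gene_ids[i]!r} "
                f"in sample {self.sample_ids[j]!r}; missing values are not imputed"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_rows(self, genes: list[str]) -> np.ndarray:
        """Row indices for ``genes``, erroring on unknown identifiers."""
        try:
            return np.array([self._gene_index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in expression matrix") from None

    def sample_cols(self, samples: list[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in samples], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in expression matrix") from None

    def subset(self, genes: list[str] | None = None,
               samples: list[str] | None = None) -> "ExpressionMatrix":
        rows = self.gene_rows(genes) if genes is not None else np.arange(self.n_genes)
        cols = self.sample_cols(samples) if samples is not None else np.arange(self.n_samples)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in rows],
            [self.sample_ids[j] for j in cols],
            self.values[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values))


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise FormatError(f"duplicate {kind} identifier {name!r}")
        seen.add(name)


def read_expression_matrix(path: str | Path, *, sep: str = "\t",
                           genes_as_rows: bool = True) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The first column holds gene identifiers and the header row sample
    identifiers (set ``genes_as_rows=False`` for the transposed layout).
    Duplicate identifiers, missing cells and non-numeric cells are hard
    errors that name the offending coordinate.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if not genes_as_rows:
        df = df.T
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric value {cell!r} at gene {df.index[i]!r}, "
                    f"sample {df.columns[j]!r} in {path}"
                ) from None
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)), values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            *, sep: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=sep, index_label="gene")


# ---------------------------------------------------------------------------
# stage labels

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}
_CONTROL_WORDS = {"control", "normal", "ctrl", "healthy", "0"}
# TCGA-style sub-stages (IIA, IIB, 3a ...) collapse onto the main stage
_STAGE_RE = re.compile(r"^(?:stage[\s_]*)?([1-4]|iv|iii|ii|i)[abc]?$")


def normalize_stage_label(label: str) -> int | str:
    """Map a free-form group label onto ``control`` or a stage 1-4.

    Case-insensitive; accepts arabic and roman numerals, an optional
    ``stage`` prefix, and TCGA sub-stage suffixes (``Stage IIA`` -> 2).
    Unknown labels raise :class:`FormatError`.
    """
    text = str(label).strip().lower()
    if text in _CONTROL_WORDS:
        return CONTROL
    m = _STAGE_RE.match(text)
    if m:
        tok = m.group(1)
        return _ROMAN[tok] if tok in _ROMAN else int(tok)
    raise FormatError(f"unknown stage label {label!r}")


def read_stage_labels(path: str | Path, *, sep: str = "\t") -> dict[str, int | str]:
    """Read a two-column (sample_id, stage) table into a sample->group map."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs two columns (sample_id, stage)")
    sample_col, stage_col = df.columns[:2]
    labels: dict[str, int | str] = {}
    for _, row in df.iterrows():
        sid = str(row[sample_col])
        if sid in labels:
            raise FormatError(f"duplicate sample identifier {sid!r} in label file")
        labels[sid] = normalize_stage_label(row[stage_col])
    return labels


def write_stage_labels(labels: Mapping[str, int | str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstage\n")
        for sid, stage in labels.items():
            fh.write(f"{sid}\t{stage}\n")


def check_labels_match(expr: ExpressionMatrix,
                       labels: Mapping[str, int | str]) -> None:
    """Require expression samples and label samples to coincide exactly."""
    expr_samples = set(expr.sample_ids)
    labelled = set(labels)
    unlabelled = sorted(expr_samples - labelled)
    orphans = sorted(labelled - expr_samples)
    problems = []
    if unlabelled:
        problems.append(f"samples without a stage label: {unlabelled}")
    if orphans:
        problems.append(f"labels without an expression column: {orphans}")
    if problems:
        raise FormatError("; ".join(problems))


def samples_by_group(labels: Mapping[str, int | str]) -> dict[int | str, list[str]]:
    """Group sample identifiers by stage/control, preserving insertion order."""
    out: dict[int | str, list[str]] = {g: [] for g in GROUPS}
    for sid, grp in labels.items():
        out[grp].append(sid)
    return out


# ---------------------------------------------------------------------------
# pathway collections (GMT)

@dataclass
class PathwayCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def items(self):
        for pid, (_, genes) in self.pathways.items():
            yield pid, genes


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one gene"
                )
            name, desc = fields[0], fields[1]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = (desc, genes)
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in collection.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# edge lists, feature matrices, JSON reports

def write_edge_list(edges, path: str | Path) -> None:
    """Write co-expression edges as TSV (gene_a, gene_b, pcc, p_value)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpcc\tp_value\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.rho!r}\t{e.p_value!r}\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    expected = {"gene_a", "gene_b", "pcc", "p_value"}
    if not expected.issubset(df.columns):
        raise FormatError(f"edge list {path} missing columns {sorted(expected - set(df.columns))}")
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
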