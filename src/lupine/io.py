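"""Count-table containers, study assembly, and network serialization.

The central objects are :class:`CountMatrix` (one time point's samples-by-taxa
table together with per-sample library sizes) and :class:`TimeSeriesStudy`
(a subject-matched ordered sequence of count matrices for one group).
Inference results are carried by :class:`InferredNetwork` (binary adjacency)
and :class:`EdgeStatistics` (partial correlations, p-values and optional
bootstrap confidence bounds).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSFORMS = ("raw_counts", "clr", "relative_abundance")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class CountMatrix:
    """One time point's samples-by-taxa abundance table.

    Parameters
    ----------
    values : (n, p) array
        Non-negative abundances. Integers for raw counts; reals are allowed
        when the table is pre-transformed (clr or relative abundance).
    sample_ids, taxon_ids : sequences of str
        Unique, ordered identifiers matching the rows / columns of ``values``.
    library_sizes : (n,) array, optional
        Total reads per sample. Computed as row sums for raw counts when
        omitted.
    transformed_flag : {"raw_counts", "clr", "relative_abundance"}
        Pre-transformed tables disable the library-size offset downstream.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    library_sizes: np.ndarray | None = None
    transformed_flag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples-by-taxa matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValidationError("id lists do not match matrix dimensions")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != p:
            raise ValidationError("duplicate taxon ids")
        if self.transformed_flag not in TRANSFORMS:
            raise ValidationError(f"unknown transformed_flag {self.transformed_flag!r}")
        if self.transformed_flag == "raw_counts":
            if np.isnan(self.values).any():
                raise ValidationError("raw-count tables must be complete (no NaN)")
            if (self.values < 0).any():
                raise ValidationError("negative entries in count table")
        if self.library_sizes is None:
            if self.transformed_flag != "raw_counts":
                raise ValidationError(
                    "library_sizes must be supplied for pre-transformed tables "
                    "unless the offset is disabled downstream"
                )
            self.library_sizes = self.values.sum(axis=1)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if self.library_sizes.shape != (n,):
                raise ValidationError("library_sizes length does not match samples")
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def subset_taxa(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        """Subset columns (order-preserving); library sizes are retained."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            values=self.values[:, keep],
            sample_ids=list(self.sample_ids),
            taxon_ids=[self.taxon_ids[k] for k in keep],
            library_sizes=self.library_sizes.copy(),
            transformed_flag=self.transformed_flag,
        )

    def reorder_samples(self, order: Sequence[int]) -> "CountMatrix":
        """Take rows by index; repeated indices (bootstrap resampling) get a
        uniquifying suffix on the sample id."""
        order = list(order)
        ids, seen = [], {}
        for k in order:
            sid = self.sample_ids[k]
            count = seen.get(sid, 0)
            seen[sid] = count + 1
            ids.append(sid if count == 0 else f"{sid}#{count}")
        return CountMatrix(
            values=self.values[order],
            sample_ids=ids,
            taxon_ids=list(self.taxon_ids),
            library_sizes=self.library_sizes[order],
            transformed_flag=self.transformed_flag,
        )


@dataclass
class TimeSeriesStudy:
    """Subject-matched ordered sequence of count matrices for one group.

    Row ``k`` of every table belongs to the same subject, and all tables share
    the same taxa in the same order.
    """

    tables: list[CountMatrix]
    time_labels: list[str]
    group_label: str = ""
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValidationError("a study needs at least one table")
        taxa = self.tables[0].taxon_ids
        for tab in self.tables[1:]:
            if tab.taxon_ids != taxa:
                raise ValidationError("all tables must share taxon_ids in order")
        ns = {tab.n_samples for tab in self.tables}
        if len(ns) != 1:
            raise ValidationError("tables must be subject-matched (equal n)")
        if len(self.time_labels) != len(self.tables):
            raise ValidationError("time_labels length mismatch")
        if not self.subject_ids:
            self.subject_ids = list(self.tables[0].sample_ids)
        if len(self.subject_ids) != self.tables[0].n_samples:
            raise ValidationError("subject_ids length mismatch")

    @property
    def n_times(self) -> int:
        return len(self.tables)

    @property
    def n_subjects(self) -> int:
        return self.tables[0].n_samples

    @property
    def taxon_ids(self) -> list[str]:
        return self.tables[0].taxon_ids

    def subset_taxa(self, keep) -> "TimeSeriesStudy":
        return TimeSeriesStudy(
            tables=[t.subset_taxa(keep) for t in self.tables],
            time_labels=list(self.time_labels),
            group_label=self.group_label,
            subject_ids=list(self.subject_ids),
        )

    def resample_subjects(self, order: Sequence[int]) -> "TimeSeriesStudy":
        """Take subjects by index (with or without replacement), jointly
        across all time points to preserve matching."""
        order = list(order)
        return TimeSeriesStudy(
            tables=[t.reorder_samples(order) for t in self.tables],
            time_labels=list(self.time_labels),
            group_label=self.group_label,
            subject_ids=[self.subject_ids[k] for k in order],
        )


@dataclass
class InferredNetwork:
    """Binary undirected taxa-association network at one (group, time)."""

    adjacency: np.ndarray
    taxon_ids: list[str]
    tested_mask: np.ndarray
    alpha: float = 0.05
    mode: str = "single"
    time_label: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=int)
        p = len(self.taxon_ids)
        if A.shape != (p, p):
            raise ValidationError("adjacency shape mismatch")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValidationError("adjacency must have zero diagonal")
        self.adjacency = A
        self.tested_mask = np.asarray(self.tested_mask, dtype=bool)
        untested = ~self.tested_mask
        if A[untested].any() or A[:, untested].any():
            raise ValidationError("untested taxa must be isolated")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for t, tested in zip(self.taxon_ids, self.tested_mask):
            g.add_node(t, tested=bool(tested))
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        g.add_edges_from((self.taxon_ids[i], self.taxon_ids[j]) for i, j in zip(ii, jj))
        return g


@dataclass
class EdgeStatistics:
    """Per-pair partial correlations and test results backing a network.

    Entries for untested pairs are NaN (missing), not p = 1.
    """

    partial_corr: np.ndarray
    p_values: np.ndarray
    df: int
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.partial_corr = np.asarray(self.partial_corr, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.partial_corr.shape != self.p_values.shape:
            raise ValidationError("statistic matrices must share a shape")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.partial_corr), initial=0.0) > 1 + 1e-9:
                raise ValidationError("partial correlations outside [-1, 1]")
            pv = self.p_values[~np.isnan(self.p_values)]
            if ((pv < 0) | (pv > 1)).any():
                raise ValidationError("p-values outside [0, 1]")


def read_count_table(
    path: str | Path,
    format: str | None = None,
    orientation: str = "samples_by_taxa",
    transformed_flag: str = "raw_counts",
) -> CountMatrix:
    """Read a count table from TSV/CSV (header = taxa, first column = sample
    ids) or BIOM v1 JSON.

    ``orientation="taxa_by_samples"`` transposes the table after reading.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".biom": "biom"}.get(path.suffix.lower(), "tsv")
    if format == "biom":
        df = _read_biom_v1(path)
        # BIOM stores observations (taxa) as rows
        df = df.T if orientation == "samples_by_taxa" else df
        if orientation == "taxa_by_samples":
            df = df  # rows already taxa; transposed below
    else:
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "taxa_by_samples":
        df = df.T
    vals = df.to_numpy(dtype=float)
    if transformed_flag == "raw_counts" and (vals < 0).any():
        raise ValidationError(f"negative entries in {path}")
    lib = None
    if transformed_flag != "raw_counts":
        lib = np.ones(vals.shape[0])
    return CountMatrix(
        values=vals,
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        library_sizes=lib,
        transformed_flag=transformed_flag,
    )


def _read_biom_v1(path: Path) -> pd.DataFrame:
    """Minimal BIOM v1 (JSON) reader returning an observations-by-samples frame."""
    with open(path) as fh:
        doc = json.load(fh)
    obs = [r["id"] for r in doc["rows"]]
    samp = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(obs), len(samp)))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat, index=obs, columns=samp)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, subject_id, time, group."""
    md = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "time", "group"}
    missing = required - set(md.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    return md


def assemble_study(
    tables: Sequence[CountMatrix],
    metadata: pd.DataFrame,
    min_subjects: int = 4,
) -> list[TimeSeriesStudy]:
    """Assemble per-group subject-matched studies from per-sample tables.

    ``metadata`` maps each sample id to (subject_id, time, group). Tables may
    be given in any order and may each hold any subset of samples; samples are
    pooled and regrouped. Subjects missing any time point within their group
    are dropped with a warning. Output is invariant to metadata row order.
    """
    md = metadata.copy()
    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    if md.duplicated(subset=["group", "subject_id", "time"]).any():
        raise ValidationError("duplicated (subject, time) pair within a group")

    # pool all samples into one lookup
    taxa = tables[0].taxon_ids
    rows: dict[str, np.ndarray] = {}
    libs: dict[str, float] = {}
    flag = tables[0].transformed_flag
    for tab in tables:
        if tab.taxon_ids != taxa:
            raise ValidationError("tables must share taxon_ids to assemble a study")
        for k, sid in enumerate(tab.sample_ids):
            rows[sid] = tab.values[k]
            libs[sid] = float(tab.library_sizes[k])
    unknown = set(md["sample_id"]) - set(rows)
    if unknown:
        raise ValidationError(f"metadata samples absent from tables: {sorted(unknown)[:5]}")

    studies = []
    for group in sorted(md["group"].unique()):
        sub = md[md["group"] == group]
        times = sorted(sub["time"].unique(), key=_time_key)
        by_subject = sub.groupby("subject_id")["time"].apply(set)
        complete = sorted(s for s, ts in by_subject.items() if ts >= set(times))
        dropped = sorted(set(by_subject.index) - set(complete))
        if dropped:
            warnings.warn(
                f"group {group!r}: dropping subjects missing time points: {dropped}",
                stacklevel=2,
            )
        if len(complete) < min_subjects:
            raise ValidationError(
                f"group {group!r} has {len(complete)} complete subjects; "
                f"at least {min_subjects} required for a stable correlation test"
            )
        lookup = sub.set_index(["subject_id", "time"])["sample_id"]
        group_tables = []
        for t in times:
            sids = [lookup.loc[(s, t)] for s in complete]
            group_tables.append(
                CountMatrix(
                    values=np.array([rows[s] for s in sids]),
                    sample_ids=sids,
                    taxon_ids=list(taxa),
                    library_sizes=np.array([libs[s] for s in sids]),
                    transformed_flag=flag,
                )
            )
        studies.append(
            TimeSeriesStudy(
                tables=group_tables,
                time_labels=[str(t) for t in times],
                group_label=str(group),
                subject_ids=list(complete),
            )
        )
    return studies


def _time_key(t):
    try:
        return (0, float(t))
    except (TypeError, ValueError):
        return (1, str(t))


def write_network(
    net: InferredNetwork,
    stats: EdgeStatistics,
    path: str | Path,
    format: str = "edge_list_csv",
) -> None:
    """Serialize a network with its statistics.

    Formats: ``adjacency_tsv`` (binary matrix), ``edge_list_csv`` (one row per
    edge, taxa in lexicographic order), ``graphml`` (edge attributes carry the
    partial correlation and p-value; nodes carry the tested flag).
    """
    path = Path(path)
    if format == "adjacency_tsv":
        pd.DataFrame(net.adjacency, index=net.taxon_ids, columns=net.taxon_ids).to_csv(
            path, sep="\t"
        )
    elif format == "edge_list_csv":
        recs = []
        ii, jj = np.nonzero(np.triu(net.adjacency, 1))
        for i, j in zip(ii, jj):
            a, b = sorted((net.taxon_ids[i], net.taxon_ids[j]))
            recs.append(
                {
                    "taxon_i": a,
                    "taxon_j": b,
                    "partial_corr": stats.partial_corr[i, j],
                    "p_value": stats.p_values[i, j],
                }
            )
        recs.sort(key=lambda r: (r["taxon_i"], r["taxon_j"]))
        pd.DataFrame(recs, columns=["taxon_i", "taxon_j", "partial_corr", "p_value"]).to_csv(
            path, index=False
        )
    elif format == "graphml":
        g = net.to_graph()
        for i, j in g.edges():
            a, b = net.taxon_ids.index(i), net.taxon_ids.index(j)
            g.edges[i, j]["partial_corr"] = float(stats.partial_corr[a, b])
            g.edges[i, j]["p_value"] = float(stats.p_values[a, b])
        g.graph.update(
            alpha=net.alpha, mode=net.mode, time_label=net.time_label,
            group_label=net.group_label,
        )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_adjacency_tsv(path: str | Path) -> InferredNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    A = df.to_numpy(dtype=int)
    return InferredNetwork(
        adjacency=A,
        taxon_ids=[str(t) for t in df.columns],
        tested_mask=np.ones(A.shape[1], dtype=bool),
    )


def read_network_graphml(path: str | Path) -> InferredNetwork:
    g = nx.read_graphml(path)
    taxa = sorted(g.nodes())
    idx = {t: k for k, t in enumerate(taxa)}
    A = np.zeros((len(taxa), len(taxa)), dtype=int)
    for a, b in g.edges():
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1
    tested = np.array([bool(g.nodes[t].get("tested", True)) for t in taxa])
    # edges imply tested regardless of a missing attribute
    tested |= A.any(axis=0)
    return InferredNetwork(
        adjacency=A,
        taxon_ids=taxa,
        tested_mask=tested,
        alpha=float(g.graph.get("alpha", 0.05)),
        mode=str(g.graph.get("mode", "single")),
        time_label=str(g.graph.get("time_label", "")),
        group_label=str(g.graph.get("group_label", "")),
    )
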