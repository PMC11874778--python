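"""Model / Results objects wrapping the inference pipeline.

``LupineModel`` is built from a subject-matched longitudinal study (or a
single count table) and holds the modelling choices; ``fit()`` runs the
per-time-point network inference and returns a ``LupineResults`` carrying the
binary networks, the underlying partial correlations and p-values, and
comparison diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import netcompare
from .inference import (
    bootstrap_pvalue_ci,
    infer_network_longitudinal,
    infer_network_single,
)
from .io import CountMatrix, EdgeStatistics, InferredNetwork, TimeSeriesStudy, assemble_study
from .preprocess import per_network_filter


class LupineModel:
    """Latent-component partial-correlation network model.

    Parameters
    ----------
    data : TimeSeriesStudy or CountMatrix
        Subject-matched longitudinal study, or a single time point's table.
    mode : {"longitudinal", "single"}
        ``longitudinal`` controls each pair through a component that shares
        covariance with past time points (PLS / blockPLS); ``single`` treats
        each time point independently (PCA). A bare CountMatrix forces
        ``single``.
    history : "all_past" or int
        Which past blocks the longitudinal component sees (window size k, or
        everything).
    n_components : int
        Number of latent components conditioned on (1 by default).
    network_threshold : float or None
        Per-time tested-taxa filter on mean relative abundance (e.g. 0.001);
        None tests every taxon.
    alpha : float
        Edge significance level.
    offset : {"library", "none"}
        Whether the log library size enters the regressions (ignored for
        pre-transformed tables).
    """

    def __init__(
        self,
        data: TimeSeriesStudy | CountMatrix,
        mode: str = "longitudinal",
        history: str | int = "all_past",
        n_components: int = 1,
        network_threshold: float | None = None,
        alpha: float = 0.05,
        offset: str = "library",
        use_log: bool = True,
        exact_per_pair: bool = False,
        bh_correct: bool = False,
    ) -> None:
        if isinstance(data, CountMatrix):
            mode = "single"
            data = TimeSeriesStudy(tables=[data], time_labels=["0"])
        if mode not in ("single", "longitudinal"):
            raise ValueError("mode must be 'single' or 'longitudinal'")
        if mode == "longitudinal" and data.n_times < 2:
            raise ValueError("longitudinal mode needs at least two time points")
        self.study = data
        self.mode = mode
        self.history = history
        self.n_components = n_components
        self.network_threshold = network_threshold
        self.alpha = alpha
        self.offset = offset
        self.use_log = use_log
        self.exact_per_pair = exact_per_pair
        self.bh_correct = bh_correct

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        group: str | None = None,
        **kwargs,
    ) -> "LupineModel":
        """Build a model from a samples-by-taxa count frame plus a metadata
        frame (sample_id, subject_id, time, group). With several groups
        present, ``group`` selects which study to model."""
        table = CountMatrix(
            values=counts.to_numpy(dtype=float),
            sample_ids=[str(s) for s in counts.index],
            taxon_ids=[str(t) for t in counts.columns],
        )
        studies = assemble_study([table], metadata)
        if group is not None:
            match = [s for s in studies if s.group_label == str(group)]
            if not match:
                raise ValueError(f"group {group!r} not found")
            study = match[0]
        elif len(studies) == 1:
            study = studies[0]
        else:
            raise ValueError(
                f"metadata contains {len(studies)} groups; pass group=..."
            )
        return cls(study, **kwargs)

    def _times(self) -> list[int]:
        first = 1 if self.mode == "longitudinal" else 0
        return list(range(first, self.study.n_times))

    def fit(self, times: list[int] | None = None) -> "LupineResults":
        """Infer the network at each requested time point."""
        times = self._times() if times is None else list(times)
        networks, stats = [], []
        for t in times:
            if self.mode == "longitudinal":
                net, st = infer_network_longitudinal(
                    self.study,
                    t=t,
                    history=self.history,
                    alpha=self.alpha,
                    n_components=self.n_components,
                    use_log=self.use_log,
                    offset=self.offset,
                    network_threshold=self.network_threshold,
                    bh_correct=self.bh_correct,
                )
            else:
                mask = (
                    per_network_filter(self.study, t, self.network_threshold)
                    if self.network_threshold is not None
                    else None
                )
                net, st = infer_network_single(
                    self.study.tables[t],
                    tested_mask=mask,
                    alpha=self.alpha,
                    n_components=self.n_components,
                    use_log=self.use_log,
                    offset=self.offset,
                    exact_per_pair=self.exact_per_pair,
                    bh_correct=self.bh_correct,
                    time_label=self.study.time_labels[t],
                    group_label=self.study.group_label,
                )
            networks.append(net)
            stats.append(st)
        return LupineResults(model=self, times=times, networks=networks, stats=stats)


@dataclass
class LupineResults:
    """Fitted networks with their statistics and comparison diagnostics."""

    model: LupineModel
    times: list[int]
    networks: list[InferredNetwork]
    stats: list[EdgeStatistics]
    _ci: dict = field(default_factory=dict, repr=False)

    def network_at(self, t: int) -> InferredNetwork:
        return self.networks[self.times.index(t)]

    def stats_at(self, t: int) -> EdgeStatistics:
        return self.stats[self.times.index(t)]

    def summary(self) -> pd.DataFrame:
        """Per-time-point overview: tested taxa, edges, density, strongest
        partial correlation."""
        rows = []
        for t, net, st in zip(self.times, self.networks, self.stats):
            q = int(net.tested_mask.sum())
            possible = q * (q - 1) // 2
            with np.errstate(invalid="ignore"):
                max_pi = np.nanmax(np.abs(st.partial_corr)) if possible else np.nan
            rows.append(
                {
                    "time": self.model.study.time_labels[t],
                    "mode": net.mode,
                    "n_subjects": self.model.study.n_subjects,
                    "tested_taxa": q,
                    "edges": net.n_edges,
                    "density": net.n_edges / possible if possible else np.nan,
                    "max_abs_partial_corr": float(max_pi),
                    "df": st.df,
                    "alpha": net.alpha,
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self, t: int | None = None) -> pd.DataFrame:
        """Long-format edge list (taxon_i < taxon_j) with statistics."""
        times = self.times if t is None else [t]
        recs = []
        for tt in times:
            net, st = self.network_at(tt), self.stats_at(tt)
            ii, jj = np.nonzero(np.triu(net.adjacency, 1))
            for i, j in zip(ii, jj):
                a, b = sorted((net.taxon_ids[i], net.taxon_ids[j]))
                recs.append(
                    {
                        "time": self.model.study.time_labels[tt],
                        "taxon_i": a,
                        "taxon_j": b,
                        "partial_corr": st.partial_corr[i, j],
                        "p_value": st.p_values[i, j],
                    }
                )
        cols = ["time", "taxon_i", "taxon_j", "partial_corr", "p_value"]
        return pd.DataFrame(recs, columns=cols).sort_values(
            ["time", "taxon_i", "taxon_j"], ignore_index=True
        )

    def bootstrap_ci(self, t: int, B: int = 1000, level: float = 0.95, seed=None):
        """Bootstrap percentile bounds on every pair's p-value at time t;
        results are cached on the EdgeStatistics."""
        kwargs = dict(
            alpha=self.model.alpha,
            n_components=self.model.n_components,
            use_log=self.model.use_log,
            offset=self.model.offset,
        )
        if self.model.mode == "longitudinal":
            lo, hi = bootstrap_pvalue_ci(
                self.model.study, B=B, level=level, seed=seed, t=t,
                history=self.model.history, **kwargs,
            )
        else:
            lo, hi = bootstrap_pvalue_ci(
                self.model.study.tables[t], B=B, level=level, seed=seed, **kwargs
            )
        st = self.stats_at(t)
        st.ci_lower, st.ci_upper = lo, hi
        return lo, hi

    # -- comparison diagnostics ---------------------------------------------

    def as_series(self) -> netcompare.NetworkSeries:
        return netcompare.NetworkSeries(networks=self.networks)

    def gdd_matrix(self) -> np.ndarray:
        return netcompare.gdd_matrix(self.as_series())

    def ivi_scores(self) -> pd.DataFrame:
        table = netcompare.ivi_table(self.as_series())
        return pd.DataFrame(
            table.scores,
            index=[self.model.study.time_labels[t] for t in self.times],
            columns=self.networks[0].taxon_ids,
        )

    def mantel_matrix(self, n_perm: int = 999, seed=None) -> np.ndarray:
        """Pairwise Mantel p-values between the fitted networks' Hamming
        profiles (diagonal is 0 by convention)."""
        profiles = [
            netcompare.hamming_profile_distance(n.adjacency) for n in self.networks
        ]
        m = len(profiles)
        P = np.zeros((m, m))
        for a in range(m - 1):
            for b in range(a + 1, m):
                _, pval = netcompare.mantel_test(
                    profiles[a], profiles[b], n_perm=n_perm, seed=seed
                )
                P[a, b] = P[b, a] = pval
        return P
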