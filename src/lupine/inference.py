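"""Partial-correlation network inference from latent-component regressions.

For every pair of taxa (i, j) the influence of all other taxa is summarized
by a one-dimensional latent component with the pair's loadings zeroed out.
Each taxon of the pair is then regressed (on the log scale, with the log
library size as an extra covariate for raw counts) on that component, and the
Pearson correlation of the two residual vectors estimates the partial
correlation. A t-test with n - 2 degrees of freedom decides whether the pair
is connected in the binary network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CountMatrix, EdgeStatistics, InferredNetwork, TimeSeriesStudy
from .latent import fit_factors, masked_component
from .preprocess import log_with_zero_offset, per_network_filter, standardized_log

logger = logging.getLogger(__name__)


@dataclass
class PartialCorrelation:
    """One pair's partial correlation with its significance test."""

    pi: float
    t_stat: float
    df: int
    p_value: float


def residualize(
    y_counts: np.ndarray,
    covariates: np.ndarray | list[np.ndarray],
    offset: np.ndarray | None = None,
    y_is_log: bool = False,
) -> np.ndarray:
    """Residuals of an OLS fit of log(y) on an intercept, the latent
    covariate(s), and (optionally) the log library size.

    ``y_counts`` is logged with the zero-offset rule unless ``y_is_log``.
    Constant covariates are dropped with a warning (they are collinear with
    the intercept). Residuals are orthogonal to all retained regressors.
    """
    y = np.asarray(y_counts, dtype=float)
    logy = y if y_is_log else log_with_zero_offset(y)
    cols = covariates if isinstance(covariates, (list, tuple)) else [covariates]
    cols = [np.asarray(c, dtype=float) for c in cols]
    if offset is not None:
        cols = cols + [np.asarray(offset, dtype=float)]
    kept = []
    for c in cols:
        if np.ptp(c) == 0:
            warnings.warn("constant covariate dropped (collinear with intercept)",
                          stacklevel=2)
        else:
            kept.append(c)
    Z = np.column_stack([np.ones_like(logy)] + kept)
    beta, *_ = np.linalg.lstsq(Z, logy, rcond=None)
    return logy - Z @ beta


def partial_correlation(e_i: np.ndarray, e_j: np.ndarray) -> PartialCorrelation:
    """Pearson correlation of two residual vectors, tested against zero with
    t = pi * sqrt((n-2)/(1-pi^2)) on n - 2 degrees of freedom (two-sided)."""
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    n = e_i.size
    df = n - 2
    si, sj = e_i.std(), e_j.std()
    if si == 0 or sj == 0:
        raise ValueError("zero-variance residual: partial correlation undefined")
    pi = float(np.corrcoef(e_i, e_j)[0, 1])
    pi = float(np.clip(pi, -1.0, 1.0))
    if abs(pi) >= 1.0:
        return PartialCorrelation(pi=pi, t_stat=np.inf * np.sign(pi), df=df, p_value=0.0)
    t = pi * np.sqrt(df / (1.0 - pi * pi))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PartialCorrelation(pi=pi, t_stat=float(t), df=df, p_value=float(min(p, 1.0)))


def _pairwise_statistics(
    log_y: np.ndarray,
    factors,
    offset: np.ndarray | None,
    exact_refit=None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partial correlations and p-values for all pairs of the (already
    filtered) q taxa. ``exact_refit(i, j)`` optionally supplies per-pair
    covariates from a full refit instead of the masking shortcut."""
    n, q = log_y.shape
    pis = np.full((q, q), np.nan)
    pvals = np.full((q, q), np.nan)
    ones = np.ones(n)
    for i in range(q - 1):
        for j in range(i + 1, q):
            if exact_refit is not None:
                covs = exact_refit(i, j)
            else:
                covs = [masked_component(f, i=i, j=j) for f in factors]
            cols = [ones]
            for c in covs:
                if np.ptp(c) > 0:
                    cols.append(c)
            if offset is not None and np.ptp(offset) > 0:
                cols.append(offset)
            Z = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(Z, log_y[:, [i, j]], rcond=None)
            E = log_y[:, [i, j]] - Z @ beta
            if E[:, 0].std() == 0 or E[:, 1].std() == 0:
                continue  # untested pair: statistics stay missing
            pc = partial_correlation(E[:, 0], E[:, 1])
            pis[i, j] = pis[j, i] = pc.pi
            pvals[i, j] = pvals[j, i] = pc.p_value
    return pis, pvals, n - 2


def _assemble(
    pis_q, pvals_q, df, mask, taxon_ids, alpha, mode, time_label, group_label,
    bh_correct=False,
):
    p = mask.size
    idx = np.flatnonzero(mask)
    pis = np.full((p, p), np.nan)
    pvals = np.full((p, p), np.nan)
    pis[np.ix_(idx, idx)] = pis_q
    pvals[np.ix_(idx, idx)] = pvals_q
    decide = pvals.copy()
    if bh_correct:
        decide = _bh_adjust_symmetric(pvals)
    with np.errstate(invalid="ignore"):
        A = (decide < alpha).astype(int)
    A[np.isnan(decide)] = 0
    np.fill_diagonal(A, 0)
    net = InferredNetwork(
        adjacency=A,
        taxon_ids=list(taxon_ids),
        tested_mask=mask.copy(),
        alpha=alpha,
        mode=mode,
        time_label=time_label,
        group_label=group_label,
    )
    return net, EdgeStatistics(partial_corr=pis, p_values=pvals, df=df)


def _bh_adjust_symmetric(pvals: np.ndarray) -> np.ndarray:
    out = np.full_like(pvals, np.nan)
    iu = np.triu_indices_from(pvals, k=1)
    flat = pvals[iu]
    ok = ~np.isnan(flat)
    if ok.any():
        adj = stats.false_discovery_control(flat[ok], method="bh")
        vals = flat.copy()
        vals[ok] = adj
        out[iu] = vals
        out.T[iu] = vals
    return out


def infer_network_single(
    table: CountMatrix,
    tested_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    n_components: int = 1,
    use_log: bool = True,
    offset: str = "library",
    exact_per_pair: bool = False,
    bh_correct: bool = False,
    time_label: str = "",
    group_label: str = "",
) -> tuple[InferredNetwork, EdgeStatistics]:
    """Single-time-point network: PCA latent control plus pairwise partial
    correlations.

    The component is fitted once on the full tested set and masked per pair
    (``exact_per_pair=True`` refits it for every pair instead). The log
    library size enters as a covariate for raw counts; it is omitted for
    pre-transformed tables, whose values are used as-is on the left-hand side.
    """
    p = table.n_taxa
    if tested_mask is None:
        tested_mask = np.ones(p, dtype=bool)
    tested_mask = np.asarray(tested_mask, dtype=bool).copy()
    # zero-variance taxa cannot be tested
    tested_mask &= np.asarray(table.values).std(axis=0, ddof=1) > 0
    if tested_mask.sum() < 3:
        raise ValueError("need at least 3 tested taxa for a controlling set")
    sub = table.subset_taxa(tested_mask)
    raw = sub.transformed_flag == "raw_counts"
    X_std = standardized_log(sub, use_log=use_log)
    log_y = log_with_zero_offset(sub.values) if raw else np.asarray(sub.values, float)
    off = np.log(sub.library_sizes) if (raw and offset == "library") else None

    factors = fit_factors([X_std], method="pca", n_components=n_components)

    exact = None
    if exact_per_pair:
        def exact(i, j, X_std=X_std, n_components=n_components):
            keep = np.ones(X_std.shape[1], dtype=bool)
            keep[[i, j]] = False
            fs = fit_factors([X_std[:, keep]], method="pca", n_components=n_components)
            return [f.u for f in fs]

    pis_q, pvals_q, df = _pairwise_statistics(log_y, factors, off, exact_refit=exact)
    return _assemble(
        pis_q, pvals_q, df, tested_mask, table.taxon_ids, alpha, "single",
        time_label, group_label, bh_correct=bh_correct,
    )


def infer_network_longitudinal(
    study: TimeSeriesStudy,
    t: int,
    history: str | int = "all_past",
    tested_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    n_components: int = 1,
    use_log: bool = True,
    offset: str = "library",
    strict_intersection: bool = False,
    network_threshold: float | None = None,
    bh_correct: bool = False,
) -> tuple[InferredNetwork, EdgeStatistics]:
    """Longitudinal network at time index ``t`` (0-based, ``t >= 1``).

    The latent control component at time t maximizes covariance with the
    preceding block (PLS, when one past block is included) or with all
    included past blocks jointly (blockPLS). ``history`` is either
    ``"all_past"`` or an integer window k restricting the past to the k
    blocks immediately before t. The tested-taxa mask is computed at the
    current time point and applied to every included block
    (``strict_intersection=True`` additionally requires taxa to pass the
    filter at every included time point).
    """
    if t < 1:
        raise ValueError("longitudinal inference requires at least one prior time point")
    if t >= study.n_times:
        raise ValueError(f"time index {t} out of range")
    if isinstance(history, int):
        if history < 1:
            raise ValueError("history window must be >= 1")
        start = max(0, t - history)
    else:
        if history != "all_past":
            raise ValueError("history must be 'all_past' or a window size")
        start = 0
    included = list(range(start, t + 1))

    table = study.tables[t]
    p = table.n_taxa
    if tested_mask is None:
        if network_threshold is not None:
            tested_mask = per_network_filter(study, t, network_threshold)
        else:
            tested_mask = np.ones(p, dtype=bool)
    tested_mask = np.asarray(tested_mask, dtype=bool).copy()
    for k in included:
        tab = study.tables[k]
        if strict_intersection and network_threshold is not None:
            tested_mask &= per_network_filter(study, k, network_threshold)
        # every included block must be scalable for the retained taxa
        tested_mask &= np.asarray(tab.values).std(axis=0, ddof=1) > 0
    if tested_mask.sum() < 3:
        raise ValueError("need at least 3 tested taxa for a controlling set")

    blocks = []
    for k in included:
        sub = study.tables[k].subset_taxa(tested_mask)
        blocks.append(standardized_log(sub, use_log=use_log))
    sub_t = study.tables[t].subset_taxa(tested_mask)
    raw = sub_t.transformed_flag == "raw_counts"
    log_y = log_with_zero_offset(sub_t.values) if raw else np.asarray(sub_t.values, float)
    off = np.log(sub_t.library_sizes) if (raw and offset == "library") else None

    method = "pls" if len(blocks) == 2 else "blockpls"
    factors = fit_factors(blocks, method=method, n_components=n_components)

    pis_q, pvals_q, df = _pairwise_statistics(log_y, factors, off)
    return _assemble(
        pis_q, pvals_q, df, tested_mask, study.taxon_ids, alpha, "longitudinal",
        study.time_labels[t], study.group_label, bh_correct=bh_correct,
    )


def bootstrap_pvalue_ci(
    data: CountMatrix | TimeSeriesStudy,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    t: int | None = None,
    max_skip_fraction: float = 0.10,
    **infer_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile confidence bounds for every pair's p-value, from resampling
    subjects with replacement and re-running the full inference pipeline.

    For a study, subjects are resampled jointly across all time points so the
    matched structure is preserved. Replicates that degenerate (e.g. a
    resample makes a taxon constant) are skipped and logged; more than
    ``max_skip_fraction`` of skips raises.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a stable percentile interval")
    rng = np.random.default_rng(seed)
    longitudinal = isinstance(data, TimeSeriesStudy)
    n = data.n_subjects if longitudinal else data.n_samples
    samples = []
    skipped = 0
    while len(samples) < B:
        idx = rng.integers(0, n, size=n)
        try:
            if longitudinal:
                res = data.resample_subjects(idx)
                _, st = infer_network_longitudinal(res, t=t, **infer_kwargs)
            else:
                res = data.reorder_samples(idx)
                _, st = infer_network_single(res, **infer_kwargs)
        except (ValueError, np.linalg.LinAlgError) as exc:
            skipped += 1
            logger.info("bootstrap replicate skipped: %s", exc)
            if skipped > max_skip_fraction * B:
                raise RuntimeError(
                    f"more than {max_skip_fraction:.0%} of bootstrap replicates degenerate"
                ) from exc
            continue
        samples.append(st.p_values)
    stackd = np.stack(samples)  # (B, p, p)
    lo = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN untested pairs
        ci_lower = np.nanquantile(stackd, lo, axis=0)
        ci_upper = np.nanquantile(stackd, 1.0 - lo, axis=0)
    return ci_lower, ci_upper


def permutation_pvalue(
    e_i: np.ndarray,
    e_j: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for corr(e_i, e_j):
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)."""
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    if e_i.size < 5:
        raise ValueError("permutation test needs n >= 5")
    rng = np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(e_i, e_j)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = np.corrcoef(e_i, rng.permutation(e_j))[0, 1]
        if abs(r) >= r_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
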