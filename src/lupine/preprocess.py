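"""Filtering, transformation, and imputation rules applied before inference.

Filtering is two-stage: a global abundance filter defines the common taxa set
for a whole study collection, then a per-network mask restricts which taxa are
tested at a given (group, time). Counts enter the regressions as natural logs
with zero cells offset to 1, and latent fitters consume centred/scaled
columns.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .io import CountMatrix, TimeSeriesStudy, ValidationError


def log_with_zero_offset(values: np.ndarray) -> np.ndarray:
    """Natural log with zero counts offset to 1 (so log(0 count) -> 0).

    Positive non-integer entries pass through the plain log unchanged.
    """
    values = np.asarray(values, dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValidationError("negative entries are not log-transformable counts")
    out = np.where(values > 0, values, 1.0)
    return np.log(out)


def center_scale(values: np.ndarray, return_flags: bool = False):
    """Column-wise centring to mean 0 and scaling to unit sample sd (ddof=1).

    Zero-variance columns are left at 0 and flagged; they carry no information
    for the latent component and would otherwise break scaling.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to centre and scale")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    out = (X - mu) / sd_safe
    out[:, constant] = 0.0
    if return_flags:
        return out, constant
    return out


def clr_transform(values: np.ndarray) -> np.ndarray:
    """Centred log-ratio per sample, with zero cells offset to 1.

    Each row of the output sums to 0.
    """
    logs = log_with_zero_offset(values)
    return logs - logs.mean(axis=1, keepdims=True)


def relative_abundance(table: CountMatrix) -> np.ndarray:
    return table.values / table.library_sizes[:, None]


def global_abundance_filter(
    studies: Sequence[TimeSeriesStudy], threshold: float = 0.001
) -> list[TimeSeriesStudy]:
    """Drop taxa whose mean relative abundance is below ``threshold`` in every
    (group, time) cell.

    A taxon survives if its mean relative abundance reaches the threshold in
    at least one group at one time point. Library sizes are computed before
    filtering and retained, so downstream offsets reflect the original
    sequencing depth. Idempotent.
    """
    taxa = studies[0].taxon_ids
    keep = np.zeros(len(taxa), dtype=bool)
    for study in studies:
        if study.taxon_ids != taxa:
            raise ValidationError("studies must share taxa for the global filter")
        for table in study.tables:
            keep |= relative_abundance(table).mean(axis=0) >= threshold
    if threshold <= 0:
        keep[:] = True
    if not keep.any():
        raise ValidationError("global filter removed every taxon")
    return [s.subset_taxa(keep) for s in studies]


def per_network_filter(
    study: TimeSeriesStudy, t: int, threshold: float = 0.001
) -> np.ndarray:
    """Boolean tested-mask at time index ``t``: mean relative abundance must
    exceed ``threshold`` in this group at this time.

    Zero-variance taxa at this time point are also excluded — they cannot be
    centred/scaled and carry no association signal. Untested taxa receive no
    edges in the inferred network.
    """
    if not (0 <= t < study.n_times):
        raise ValidationError(f"time index {t} out of range")
    table = study.tables[t]
    mask = relative_abundance(table).mean(axis=0) >= threshold
    mask &= table.values.std(axis=0, ddof=1) > 0
    if mask.sum() < 3:
        raise ValidationError(
            "fewer than 3 taxa pass the per-network filter; no controlling set"
        )
    return mask


def spline_impute(study: TimeSeriesStudy, on: str = "clr") -> TimeSeriesStudy:
    """Impute missing cells of a pre-transformed study by natural cubic
    splines along each (subject, taxon) trajectory.

    Operates on clr-transformed values; observed cells are never altered.
    Trajectories with a single observed point fall back to carrying that
    value; no extrapolation beyond the observed time range (nearest observed
    value is used instead).
    """
    if on != "clr":
        raise ValueError("only clr-scale imputation is supported")
    times = np.array([float(t) for t in study.time_labels])
    stack = np.stack([t.values for t in study.tables])  # (T, n, p)
    T, n, p = stack.shape
    for s in range(n):
        if np.isnan(stack[:, s, :]).all():
            raise ValidationError(f"subject {study.subject_ids[s]} has no observations")
    out = stack.copy()
    for s in range(n):
        for j in range(p):
            y = stack[:, s, j]
            miss = np.isnan(y)
            if not miss.any():
                continue
            obs = ~miss
            n_obs = int(obs.sum())
            if n_obs == 0:
                raise ValidationError(
                    f"trajectory (subject {study.subject_ids[s]}, taxon "
                    f"{study.taxon_ids[j]}) has no observed time points"
                )
            if n_obs == 1:
                out[miss, s, j] = y[obs][0]
                continue
            t_obs = times[obs]
            # natural boundary conditions; degenerates to a line for 2 points
            interp = CubicSpline(t_obs, y[obs], bc_type="natural")
            t_miss = times[miss]
            filled = interp(np.clip(t_miss, t_obs.min(), t_obs.max()))
            out[miss, s, j] = filled
    tables = []
    for k, tab in enumerate(study.tables):
        tables.append(
            CountMatrix(
                values=out[k],
                sample_ids=list(tab.sample_ids),
                taxon_ids=list(tab.taxon_ids),
                library_sizes=tab.library_sizes.copy(),
                transformed_flag="clr",
            )
        )
    return TimeSeriesStudy(
        tables=tables,
        time_labels=list(study.time_labels),
        group_label=study.group_label,
        subject_ids=list(study.subject_ids),
    )


def standardized_log(table: CountMatrix, use_log: bool = True) -> np.ndarray:
    """The representation the latent fitters consume: log(+offset) when the
    table is raw counts, then centred and unit-scaled columns."""
    if table.transformed_flag == "raw_counts" and use_log:
        X = log_with_zero_offset(table.values)
    else:
        X = np.asarray(table.values, dtype=float)
    return center_scale(X)
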