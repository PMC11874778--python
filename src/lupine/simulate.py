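"""Benchmark data generator: longitudinal Gaussian-copula Poisson counts
whose latent dependence follows period-specific true networks.

A binary adjacency is turned into a precision matrix (nonzero off-diagonal
entries exactly on edges, diagonal inflated to strict dominance), inverted
and standardized to a correlation matrix, so that at the latent Gaussian
level "no edge" is literally "zero partial correlation". Counts are drawn
through a Gaussian copula (NORTA): Z ~ MVN(0, R), x = F^{-1}_Poisson(Phi(z)),
giving exact Poisson marginals with taxon-specific rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import CountMatrix, InferredNetwork, TimeSeriesStudy


@dataclass
class SimulationDesign:
    """Study conditions for the two-period longitudinal benchmark.

    Defaults reproduce the benchmark design: 54 taxa, 10 time points, a
    network switch after day 5, and 50 replicates; sample size is varied
    across {23, 50, 120} by the caller.
    """

    networks: list[np.ndarray] = field(default_factory=list)
    n: int = 23
    p: int = 54
    T: int = 10
    switch_after: int = 5
    edge_weight_range: tuple[float, float] = (0.3, 0.6)
    mean_log_abundance: tuple[float, float] = (3.0, 1.0)
    edge_density: float = 0.07
    replicates: int = 50
    seed: int = 0
    ar1: float = 0.0  # optional latent persistence across time points

    def __post_init__(self) -> None:
        if not self.networks:
            rng = np.random.default_rng(self.seed)
            self.networks = [
                random_network(self.p, self.edge_density, rng),
                random_network(self.p, self.edge_density, rng),
            ]
        for A in self.networks:
            A = np.asarray(A)
            if A.shape != (self.p, self.p):
                raise ValueError("network shape does not match p")
            if not np.array_equal(A, A.T) or np.diag(A).any():
                raise ValueError("networks must be symmetric with zero diagonal")
        if not 1 <= self.switch_after <= self.T:
            raise ValueError("switch_after must lie in 1..T")

    def period_of(self, t: int) -> int:
        """Period index (0 or 1) of 0-based time point t."""
        return 0 if t < self.switch_after else min(1, len(self.networks) - 1)


def random_network(p: int, density: float, seed=None) -> np.ndarray:
    """Symmetric binary adjacency with ~density of possible edges, zero diagonal."""
    rng = np.random.default_rng(seed)
    A = np.zeros((p, p), dtype=int)
    iu = np.triu_indices(p, 1)
    edges = rng.random(len(iu[0])) < density
    A[iu] = edges.astype(int)
    return A + A.T


def correlation_from_network(
    adjacency: np.ndarray,
    edge_weight_range: tuple[float, float] = (0.3, 0.6),
    seed=None,
) -> np.ndarray:
    """Latent correlation matrix whose partial correlations are nonzero
    exactly on the edges of ``adjacency``.

    Off-diagonal precision entries on edges get magnitudes uniform in
    ``edge_weight_range`` with random signs; the diagonal is inflated to
    strict diagonal dominance (guaranteeing positive definiteness); the
    precision is inverted and standardized to a correlation matrix.
    """
    A = np.asarray(adjacency)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    p = A.shape[0]
    rng = np.random.default_rng(seed)
    lo, hi = edge_weight_range
    P = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    onedge = A[iu] > 0
    mags = rng.uniform(lo, hi, size=int(onedge.sum()))
    signs = rng.choice([-1.0, 1.0], size=mags.size)
    vals = np.zeros(len(iu[0]))
    vals[onedge] = mags * signs
    P[iu] = vals
    P = P + P.T
    np.fill_diagonal(P, np.abs(P).sum(axis=1) + 1.0)
    cov = np.linalg.inv(P)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def sample_mv_poisson(
    correlation: np.ndarray,
    rates: np.ndarray,
    n: int,
    seed=None,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-copula multivariate Poisson counts: Z ~ MVN(0, R),
    x_sj = F^{-1}_Poisson(Phi(z_sj); lambda_j). Marginals are exactly
    Poisson(lambda_j)."""
    R = np.asarray(correlation, dtype=float)
    lam = np.asarray(rates, dtype=float)
    if (lam <= 0).any():
        raise ValueError("Poisson rates must be positive")
    if z is None:
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((n, R.shape[0])) @ L.T
    u = stats.norm.cdf(z)
    # clip away exact 0/1 so the quantile stays finite
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.poisson.ppf(u, lam[None, :]).astype(int)


def simulate_study(
    design: SimulationDesign,
) -> tuple[list[TimeSeriesStudy], list[list[InferredNetwork]]]:
    """Simulate ``design.replicates`` longitudinal studies with known truth.

    Per replicate: a fresh correlation matrix per period (reused within the
    period), per-taxon Poisson rates drawn once from a log-normal, and one
    n-by-p count table per time point with consistent subject labels. Returns
    the studies and, per replicate, the list of true networks per time point.
    """
    rng = np.random.default_rng(design.seed)
    taxa = [f"taxon_{k:03d}" for k in range(design.p)]
    studies: list[TimeSeriesStudy] = []
    truths: list[list[InferredNetwork]] = []
    mu, sigma = design.mean_log_abundance
    for r in range(design.replicates):
        corr = [
            correlation_from_network(A, design.edge_weight_range, rng)
            for A in design.networks
        ]
        chol = [np.linalg.cholesky(R) for R in corr]
        lam = np.exp(rng.normal(mu, sigma, size=design.p))
        subjects = [f"rep{r:02d}_s{k:03d}" for k in range(design.n)]
        tables = []
        truth_r = []
        z_prev = None
        for t in range(design.T):
            period = design.period_of(t)
            eps = rng.standard_normal((design.n, design.p)) @ chol[period].T
            if design.ar1 > 0 and z_prev is not None:
                z = design.ar1 * z_prev + np.sqrt(1 - design.ar1**2) * eps
            else:
                z = eps
            z_prev = z
            counts = sample_mv_poisson(corr[period], lam, design.n, z=z)
            # guard against an all-zero taxon (breaks scaling downstream)
            zero_cols = counts.sum(axis=0) == 0
            if zero_cols.any():
                fix = np.flatnonzero(zero_cols)
                counts[rng.integers(0, design.n, size=fix.size), fix] = 1
            tables.append(
                CountMatrix(
                    values=counts.astype(float),
                    sample_ids=[f"{s}_t{t}" for s in subjects],
                    taxon_ids=list(taxa),
                    library_sizes=counts.sum(axis=1).astype(float),
                )
            )
            truth_r.append(
                InferredNetwork(
                    adjacency=np.asarray(design.networks[period]),
                    taxon_ids=list(taxa),
                    tested_mask=np.ones(design.p, dtype=bool),
                    mode="true",
                    time_label=str(t),
                    group_label=f"replicate_{r}",
                )
            )
        studies.append(
            TimeSeriesStudy(
                tables=tables,
                time_labels=[str(t) for t in range(design.T)],
                group_label=f"replicate_{r}",
                subject_ids=subjects,
            )
        )
        truths.append(truth_r)
    return studies, truths
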