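"""Statistics for evolution experiments: competitive fitness, gene-set
permutation correlation and flow-cytometry reporter normalization.

Fitness: in a pairwise competition assay the natural log of the
query:reference abundance ratio changes linearly with elapsed generations;
its ordinary-least-squares slope is the per-generation selection
coefficient s, with a 95% CI from the slope's standard error and the
t-distribution on n − 2 degrees of freedom.  Following the field's
reporting convention, the CI is suppressed (not computed less precisely —
simply not reported) when fewer than five time points were sampled.

Gene-set correlation: the association between promoter affinity for a
transcription factor and expression log2 fold change is evaluated on a
focal set of target genes, with significance from a permutation null built
by drawing random gene sets of the same size from the full gene complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedLogError,
    ValidationError,
)

__all__ = [
    "CompetitionTimecourse",
    "FitnessEstimate",
    "GeneTable",
    "PermutationResult",
    "GFPNormalization",
    "estimate_fitness",
    "correlation_with_permutation",
    "normalize_gfp",
]


@dataclass
class CompetitionTimecourse:
    """Counts (or frequencies) of two competing genotypes over generations."""

    generations: np.ndarray
    count_query: np.ndarray
    count_reference: np.ndarray

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.count_query = np.asarray(self.count_query, dtype=float)
        self.count_reference = np.asarray(self.count_reference, dtype=float)
        n = self.generations.size
        if self.count_query.size != n or self.count_reference.size != n:
            raise ValidationError("generations and counts must have equal length")
        if n < 3:
            raise InsufficientDataError(f"need at least 3 time points, got {n}")
        if np.any(np.diff(self.generations) <= 0):
            raise ValidationError("generations must be strictly increasing")

    def __len__(self) -> int:
        return self.generations.size

    def log_ratio(self) -> np.ndarray:
        for arr, name in ((self.count_query, "query"), (self.count_reference, "reference")):
            zero = np.flatnonzero(arr <= 0)
            if zero.size:
                g = self.generations[zero[0]]
                raise UndefinedLogError(
                    f"{name} count is zero (or negative) at generation {g}; "
                    "log-ratio undefined"
                )
        return np.log(self.count_query / self.count_reference)


@dataclass(frozen=True)
class FitnessEstimate:
    """Selection coefficient per generation, with optional 95% CI.

    ``ci95`` holds (lower, upper) bounds when reported; ``ci_reported`` is
    False — and ``ci95``/``se`` still carry the computed numbers for
    diagnostics — when fewer than 5 time points were used.
    """

    s: float
    se: float
    ci95: tuple[float, float] | None
    n_points: int
    ci_reported: bool
    intercept: float


def estimate_fitness(tc: CompetitionTimecourse, ci_min_points: int = 5) -> FitnessEstimate:
    """Selection coefficient from a competition time course.

    s is the OLS slope of ln(query/reference) against generations; the 95%
    CI uses the slope standard error with a t-quantile on n − 2 degrees of
    freedom and is reported only when n ≥ ``ci_min_points``.
    """
    y = tc.log_ratio()
    fit = stats.linregress(tc.generations, y)
    n = len(tc)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    reported = n >= ci_min_points
    return FitnessEstimate(
        s=float(fit.slope),
        se=float(fit.stderr),
        ci95=ci,
        n_points=n,
        ci_reported=reported,
        intercept=float(fit.intercept),
    )


@dataclass
class GeneTable:
    """Per-gene promoter affinity and expression log2 fold change, with a
    membership flag for the focal target set."""

    genes: list[str]
    affinity: np.ndarray
    lfc: np.ndarray
    is_target: np.ndarray

    def __post_init__(self) -> None:
        self.affinity = np.asarray(self.affinity, dtype=float)
        self.lfc = np.asarray(self.lfc, dtype=float)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        n = len(self.genes)
        if not (self.affinity.size == self.lfc.size == self.is_target.size == n):
            raise ValidationError("all columns must have the same length")
        if len(set(self.genes)) != n:
            raise ValidationError("gene ids must be unique")
        m = int(self.is_target.sum())
        if m < 3:
            raise ValidationError(f"focal set must contain at least 3 genes, got {m}")
        if m >= n:
            raise ValidationError("focal set must be a strict subset of all genes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_target(self) -> int:
        return int(self.is_target.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.genes,
                "affinity": self.affinity,
                "lfc": self.lfc,
                "is_target": self.is_target,
            }
        )


@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float
    method: str
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    alternative: str


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def correlation_with_permutation(
    table: GeneTable,
    method: str = "spearman",
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
    include_focal_in_pool: bool = True,
) -> PermutationResult:
    """Affinity–expression correlation on the focal gene set, with an
    empirical p-value from random same-size gene sets.

    The null distribution draws ``n_perm`` gene subsets of the focal size
    without replacement from all genes (by default including the focal
    genes themselves in the pool) and recomputes the statistic on each.
    The p-value uses the add-one convention, p = (1 + #{null ≥ obs}) /
    (n_perm + 1), so it never returns 0; ``alternative`` may be "greater"
    (positive association, the default), "less" or "two-sided".
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")

    focal = table.is_target
    aff_f = table.affinity[focal]
    lfc_f = table.lfc[focal]
    if np.ptp(aff_f) == 0 or np.ptp(lfc_f) == 0:
        raise DegenerateInputError(
            "zero variance on the focal set; correlation undefined"
        )

    if method == "spearman":
        observed = float(stats.spearmanr(aff_f, lfc_f).statistic)
    else:
        observed = float(stats.pearsonr(aff_f, lfc_f).statistic)

    rng = np.random.default_rng(seed)
    m = aff_f.size
    pool = np.arange(table.n_genes) if include_focal_in_pool else np.flatnonzero(~focal)
    if pool.size < m:
        raise ValidationError("background pool smaller than the focal set")

    # uniform random m-subsets per row: argpartition of iid uniforms
    u = rng.random((n_perm, pool.size))
    idx = pool[np.argpartition(u, m - 1, axis=1)[:, :m]]
    aff_null = table.affinity[idx]
    lfc_null = table.lfc[idx]
    if method == "spearman":
        aff_null = stats.rankdata(aff_null, axis=1)
        lfc_null = stats.rankdata(lfc_null, axis=1)
    null = _rowwise_pearson(aff_null, lfc_null)
    # degenerate draws (zero variance within a null subset) count as ties at 0
    null = np.nan_to_num(null, nan=0.0)

    if alternative == "greater":
        exceed = np.sum(null >= observed)
    elif alternative == "less":
        exceed = np.sum(null <= observed)
    else:
        exceed = np.sum(np.abs(null) >= abs(observed))
    p = (1.0 + exceed) / (n_perm + 1.0)

    return PermutationResult(
        statistic_observed=observed,
        method=method,
        null_stats=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


class GFPNormalization(NamedTuple):
    values: np.ndarray
    n_dropped: int


def normalize_gfp(gfp, fsc) -> GFPNormalization:
    """Per-event reporter normalization: log10(GFP / FSC-A).

    Events with non-positive GFP intensity are dropped (their log is
    undefined) and the dropped count reported; non-positive forward
    scatter is a validation error since FSC-A is the divisor for every
    event.
    """
    gfp = np.asarray(gfp, dtype=float)
    fsc = np.asarray(fsc, dtype=float)
    if gfp.shape != fsc.shape or gfp.ndim != 1:
        raise ValidationError("gfp and fsc must be 1-D arrays of equal length")
    if np.any(fsc <= 0):
        raise ValidationError("forward scatter (FSC-A) must be positive for every event")
    keep = gfp > 0
    return GFPNormalization(
        values=np.log10(gfp[keep] / fsc[keep]),
        n_dropped=int(np.sum(~keep)),
    )
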