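"""Protein–DNA binding quantification: EMSA dose–response fits and PWMs.

An electrophoretic mobility shift assay (EMSA) titrates purified protein
against a fixed amount of labelled DNA; densitometry of the shifted (bound)
and free bands gives a fraction bound per protein dose.  The dose–response
is summarised by a two-parameter Michaelis–Menten binding model

    Fr(x) = Frmax · x / (x + Kx)

with ``Frmax`` the upper limit of the fraction bound and ``Kx`` the protein
dose (μg) at which binding is half-maximal.  Lower affinity shows up as a
larger Kx and/or smaller Frmax.

The module also builds a position weight matrix (PWM) from the top-scoring
k-mers of a protein binding microarray experiment, by ungapped alignment and
per-position base tallying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateInputError,
    FitConvergenceError,
    InsufficientDataError,
    InvalidParameterError,
    ValidationError,
)

__all__ = [
    "DoseResponse",
    "MMFitResult",
    "PWM",
    "fraction_bound",
    "predict_fraction",
    "fit_michaelis_menten",
    "pwm_from_top_kmers",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class DoseResponse:
    """A single EMSA titration: protein doses (μg) and fractions bound."""

    doses: np.ndarray
    fractions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.doses.shape != self.fractions.shape or self.doses.ndim != 1:
            raise ValidationError("doses and fractions must be 1-D arrays of equal length")
        if np.any(self.doses < 0):
            raise ValidationError("doses must be non-negative")
        if np.any(np.diff(self.doses) < 0):
            raise ValidationError("doses must be ordered non-decreasingly")

    def __len__(self) -> int:
        return self.doses.size

    @property
    def out_of_range(self) -> bool:
        """True when measurement noise pushed any fraction outside [0, 1].

        Such points are flagged, never rejected: least squares is defined
        regardless, and dropping them would bias the fit.
        """
        return bool(np.any((self.fractions < 0) | (self.fractions > 1)))


@dataclass(frozen=True)
class MMFitResult:
    """Michaelis–Menten fit of an EMSA titration.

    ``p_frmax`` and ``p_kx`` are two-sided p-values from per-coefficient
    t-statistics (estimate over asymptotic standard error, n − 2 degrees of
    freedom), the conventional per-parameter significance report for
    dose–response fits.
    """

    frmax: float
    kx: float
    se_frmax: float
    se_kx: float
    p_frmax: float
    p_kx: float
    rss: float
    fitted: np.ndarray
    n: int
    data_out_of_range: bool = False

    def significant(self, alpha: float = 0.02) -> bool:
        """Both parameter estimates significant at ``alpha`` (default 0.02)."""
        return self.p_frmax < alpha and self.p_kx < alpha

    def ci95(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Asymptotic 95% confidence intervals for (frmax, kx)."""
        tcrit = stats.t.ppf(0.975, self.n - 2)
        return (
            (self.frmax - tcrit * self.se_frmax, self.frmax + tcrit * self.se_frmax),
            (self.kx - tcrit * self.se_kx, self.kx + tcrit * self.se_kx),
        )


def fraction_bound(bound_intensity: float, unbound_intensity: float) -> float:
    """Fraction bound from band densitometry: bound / (bound + unbound)."""
    if bound_intensity < 0 or unbound_intensity < 0:
        raise ValidationError("band intensities must be non-negative")
    total = bound_intensity + unbound_intensity
    if total == 0:
        raise DegenerateInputError("total band intensity is zero; fraction undefined")
    return bound_intensity / total


def predict_fraction(frmax: float, kx: float, doses) -> np.ndarray:
    """Michaelis–Menten prediction ``frmax·x/(x + kx)`` per dose."""
    if kx <= 0:
        raise InvalidParameterError(f"kx must be positive, got {kx}")
    x = np.asarray(doses, dtype=float)
    return frmax * x / (x + kx)


def fit_michaelis_menten(data: DoseResponse) -> MMFitResult:
    """Fit ``Fr = Frmax·x/(x + Kx)`` to a titration by nonlinear least squares.

    The zero-dose point is kept in the fit (the model passes through the
    origin).  Starting values are deterministic: Frmax at the maximum
    observed fraction and Kx at the dose whose observed fraction is nearest
    half of that maximum.  Standard errors come from the estimated covariance
    at the optimum (residual-variance scaled).
    """
    n = len(data)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 dose points to fit 2 parameters, got {n}"
        )
    if not np.any(data.doses > 0):
        raise ValidationError("at least one dose must be positive")

    frmax0 = float(np.max(data.fractions))
    if frmax0 <= 0:
        frmax0 = 0.5
    positive = data.doses > 0
    half_target = frmax0 / 2.0
    kx0 = float(
        data.doses[positive][np.argmin(np.abs(data.fractions[positive] - half_target))]
    )
    if kx0 <= 0:
        kx0 = float(np.median(data.doses[positive]))

    def model(x, frmax, kx):
        return frmax * x / (x + kx)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, data.doses, data.fractions, p0=[frmax0, kx0], maxfev=10000
            )
    except RuntimeError as exc:
        raise FitConvergenceError(
            "Michaelis-Menten fit did not converge",
            diagnostics={"p0": [frmax0, kx0], "message": str(exc)},
        ) from exc
    if not np.all(np.isfinite(popt)):
        raise FitConvergenceError(
            "fit produced non-finite parameter estimates",
            diagnostics={"popt": list(popt)},
        )

    frmax, kx = popt
    fitted = model(data.doses, frmax, kx)
    rss = float(np.sum((data.fractions - fitted) ** 2))
    se = np.sqrt(np.diag(pcov))
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.abs(popt) / se
    pvals = 2.0 * stats.t.sf(tvals, df)
    # an exact (noise-free) fit has zero residual variance: report p = 0
    pvals = np.where(np.isnan(pvals), 0.0, pvals)

    return MMFitResult(
        frmax=float(frmax),
        kx=float(kx),
        se_frmax=float(se[0]),
        se_kx=float(se[1]),
        p_frmax=float(pvals[0]),
        p_kx=float(pvals[1]),
        rss=rss,
        fitted=fitted,
        n=n,
        data_out_of_range=data.out_of_range,
    )


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base frequencies over ACGT.

    ``columns[i, j]`` is the frequency of base ``"ACGT"[j]`` at position
    ``i``; each row sums to 1.
    """

    columns: np.ndarray
    alphabet: str = field(default=_BASES)

    @property
    def width(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(self.alphabet[j] for j in np.argmax(self.columns, axis=1))


def _revcomp(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def _identity(a: str, b: str) -> int:
    return sum(1 for p, q in zip(a, b) if p == q)


def pwm_from_top_kmers(
    kmers,
    scores,
    top_n: int = 10,
    allow_revcomp: bool = True,
) -> PWM:
    """Build a PWM from the ``top_n`` highest-scoring k-mers.

    K-mers are ranked by score (ties broken lexicographically, so the
    selection is deterministic), aligned ungapped at offset zero against the
    top-scoring k-mer — optionally flipping each to its reverse complement
    when that orientation matches the anchor better — and base frequencies
    are tallied per position.
    """
    kmers = list(kmers)
    scores = list(scores)
    if not kmers:
        raise ValidationError("no k-mers supplied")
    if len(kmers) != len(scores):
        raise ValidationError("kmers and scores must have equal length")
    width = len(kmers[0])
    for k in kmers:
        if len(k) != width:
            raise ValidationError("all k-mers must have equal length")
        if any(b not in _BASES for b in k.upper()):
            raise ValidationError(f"k-mer {k!r} contains non-ACGT characters")
    if len(kmers) < top_n:
        warnings.warn(
            f"only {len(kmers)} k-mers available; using all (top_n={top_n})",
            stacklevel=2,
        )
        top_n = len(kmers)

    order = sorted(range(len(kmers)), key=lambda i: (-scores[i], kmers[i]))
    chosen = [kmers[i].upper() for i in order[:top_n]]

    anchor = chosen[0]
    aligned = [anchor]
    for k in chosen[1:]:
        if allow_revcomp and _identity(_revcomp(k), anchor) > _identity(k, anchor):
            aligned.append(_revcomp(k))
        else:
            aligned.append(k)

    counts = np.zeros((width, 4))
    for k in aligned:
        for pos, base in enumerate(k):
            counts[pos, _BASES.index(base)] += 1
    return PWM(columns=counts / counts.sum(axis=1, keepdims=True))
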