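"""Seeded generators for every input the analysis modules consume.

Each generator is a pure function of its arguments and a seed: the same
call twice yields bit-identical output.  Defaults mirror the study
conditions the analyses were designed around — six-point EMSA titrations
from 0 to 20 μg, a 42-sequence codon alignment with a purifying-selection
window over the DNA binding domain, ~6000 genes with a 41-gene focal set,
and 1:9 competition mixes sampled at 10,000 cells per time point.

What these generators emulate (and what they do not) is laid out in
docs/methods.md; in short, they reproduce the statistical structure each
estimator assumes — not gel imaging artefacts, phylogenetic correlation
among isolates, or flow-cytometry gating effects.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .binding import DoseResponse, predict_fraction
from .errors import InvalidParameterError, ValidationError
from .evostats import CompetitionTimecourse, GeneTable
from .ffl_model import FFLParameters, FFLState, integrate_ffl
from .selection import SENSE_CODONS, CodonAlignment

__all__ = [
    "PAPER_DOSES",
    "gen_emsa_data",
    "gen_codon_alignment",
    "gen_gene_table",
    "gen_competition",
    "gen_ffl_timecourse",
]

#: EMSA protein dose series (μg) used throughout: 0, 1, 5, 10, 15, 20.
PAPER_DOSES = (0.0, 1.0, 5.0, 10.0, 15.0, 20.0)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def gen_emsa_data(
    frmax: float = 0.8,
    kx: float = 5.0,
    doses=PAPER_DOSES,
    noise_sd: float = 0.02,
    n_replicates: int = 1,
    seed: int | None = None,
    label: str = "synthetic",
) -> list[DoseResponse]:
    """Synthetic EMSA titrations: Michaelis–Menten curve plus Gaussian noise.

    Fractions are the model curve ``frmax·x/(x + kx)`` with iid Gaussian
    noise of standard deviation ``noise_sd`` added; values pushed outside
    [0, 1] are kept (the consuming fit flags, never rejects, them).
    """
    if not (0 < frmax <= 1):
        raise InvalidParameterError(f"frmax must be in (0, 1], got {frmax}")
    if kx <= 0:
        raise InvalidParameterError(f"kx must be positive, got {kx}")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be non-negative, got {noise_sd}")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be at least 1")

    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    truth = predict_fraction(frmax, kx, doses)
    out = []
    for rep in range(n_replicates):
        fractions = truth + rng.normal(0.0, noise_sd, size=doses.size)
        out.append(DoseResponse(doses=doses.copy(), fractions=fractions, label=f"{label}_{rep}"))
    return out


@lru_cache(maxsize=None)
def _neighbours(codon: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Synonymous and nonsynonymous (non-stop) single-base neighbours."""
    from Bio.Data import CodonTable

    code = CodonTable.unambiguous_dna_by_id[1].forward_table
    aa = code[codon]
    syn, nonsyn = [], []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            nb = codon[:pos] + base + codon[pos + 1 :]
            if nb in _STOPS:
                continue
            (syn if code[nb] == aa else nonsyn).append(nb)
    return tuple(syn), tuple(nonsyn)


def gen_codon_alignment(
    ancestor_len_codons: int = 510,
    n_seqs: int = 42,
    syn_rate: float = 0.05,
    nonsyn_rate: float = 0.05,
    constrained_window: tuple[int, int] = (309, 349),
    window_nonsyn_rate: float = 0.0,
    seed: int | None = None,
) -> CodonAlignment:
    """Codon alignment of ``n_seqs`` descendants of a random sense-codon
    ancestor, with a window of suppressed nonsynonymous change.

    Each codon of each descendant independently receives at most one
    single-base change: synonymous with probability ``syn_rate`` (skipped
    for codons with no synonymous neighbour, e.g. ATG, TGG), otherwise
    nonsynonymous with probability ``nonsyn_rate`` — or
    ``window_nonsyn_rate`` for codons whose 0-based index falls in
    ``constrained_window`` (half-open), emulating purifying selection over
    a functional domain.  Stop codons are never introduced.
    """
    for name, rate in (
        ("syn_rate", syn_rate),
        ("nonsyn_rate", nonsyn_rate),
        ("window_nonsyn_rate", window_nonsyn_rate),
    ):
        if not (0 <= rate < 1):
            raise InvalidParameterError(f"{name} must be in [0, 1), got {rate}")
    lo, hi = constrained_window
    if not (0 <= lo <= hi <= ancestor_len_codons):
        raise ValidationError(
            f"constrained_window {constrained_window} outside sequence of "
            f"{ancestor_len_codons} codons"
        )
    if n_seqs < 1 or ancestor_len_codons < 1:
        raise InvalidParameterError("n_seqs and ancestor_len_codons must be positive")

    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), ancestor_len_codons)]

    sequences = []
    for _ in range(n_seqs):
        codons = []
        for pos, codon in enumerate(ancestor):
            ns_rate = window_nonsyn_rate if lo <= pos < hi else nonsyn_rate
            u = rng.random()
            syn, nonsyn = _neighbours(codon)
            if u < syn_rate and syn:
                codon = syn[rng.integers(0, len(syn))]
            elif syn_rate <= u < syn_rate + ns_rate and nonsyn:
                codon = nonsyn[rng.integers(0, len(nonsyn))]
            codons.append(codon)
        sequences.append("".join(codons))

    return CodonAlignment(
        ids=[f"isolate_{i + 1:02d}" for i in range(n_seqs)], sequences=sequences
    )


def gen_gene_table(
    n_genes: int = 6000,
    n_target: int = 41,
    true_corr: float = 0.31,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> GeneTable:
    """Per-gene (affinity, log2 fold change) table with a correlated focal set.

    Focal genes draw (affinity, lfc) from a standard bivariate normal with
    correlation ``true_corr``; background genes use the identical marginal
    construction with zero correlation, so under ``true_corr = 0`` focal
    and background genes are exchangeable (the permutation null is exact).
    ``noise_sd`` adds independent Gaussian measurement noise to every lfc.
    """
    if not (3 <= n_target < n_genes):
        raise ValidationError(f"need 3 <= n_target < n_genes, got {n_target}, {n_genes}")
    if abs(true_corr) > 1:
        raise InvalidParameterError(f"|true_corr| must be <= 1, got {true_corr}")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    affinity = rng.standard_normal(n_genes)
    z = rng.standard_normal(n_genes)
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[rng.choice(n_genes, size=n_target, replace=False)] = True

    rho = np.where(is_target, true_corr, 0.0)
    lfc = rho * affinity + np.sqrt(1.0 - rho**2) * z
    if noise_sd > 0:
        lfc = lfc + rng.normal(0.0, noise_sd, size=n_genes)

    return GeneTable(
        genes=[f"gene_{i + 1:04d}" for i in range(n_genes)],
        affinity=affinity,
        lfc=lfc,
        is_target=is_target,
    )


def gen_competition(
    s_true: float = 0.1,
    init_ratio: float = 1.0 / 9.0,
    generation_points=(0.0, 3.0, 6.0, 9.0, 12.0, 15.0),
    depth: int | None = 10_000,
    seed: int | None = None,
) -> CompetitionTimecourse:
    """Competition time course with known selection coefficient.

    The query:reference ratio follows ``init_ratio · e^{s_true · t}``, so
    the query frequency is ``r/(1 + r)``.  With finite ``depth`` the
    observed query count is Binomial(depth, frequency) — the flow-cytometry
    sampling model — and the reference count is the remainder; with
    ``depth=None`` (exact mode) frequencies are returned unsampled, so the
    downstream regression recovers ``s_true`` exactly.
    """
    t = np.asarray(generation_points, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("generation_points must be strictly increasing")
    if init_ratio <= 0:
        raise InvalidParameterError(f"init_ratio must be positive, got {init_ratio}")
    if depth is not None and depth < 1:
        raise InvalidParameterError("depth must be at least 1 (or None for exact mode)")

    ratio = init_ratio * np.exp(s_true * t)
    freq = ratio / (1.0 + ratio)

    if depth is None:
        return CompetitionTimecourse(
            generations=t, count_query=freq, count_reference=1.0 - freq
        )

    rng = np.random.default_rng(seed)
    if np.any(freq <= 0) or np.any(freq >= 1):
        import warnings

        warnings.warn(
            "query frequency saturated at 0 or 1; zero counts possible downstream",
            stacklevel=2,
        )
    q = rng.binomial(depth, freq)
    return CompetitionTimecourse(
        generations=t, count_query=q.astype(float), count_reference=(depth - q).astype(float)
    )


def gen_ffl_timecourse(
    params: FFLParameters,
    sample_times,
    obs_noise_sd: float = 0.0,
    initial: FFLState | None = None,
    seed: int | None = None,
):
    """Noisy observations of an integrated feedforward-loop trajectory.

    Noise is purely observational: the dynamics are integrated once,
    deterministically, and iid Gaussian noise of sd ``obs_noise_sd`` is
    added to the sampled species levels.  Returns a DataFrame with columns
    time, gat1, dal80, mep2.
    """
    times = np.asarray(sample_times, dtype=float)
    if np.any(times < 0):
        raise ValidationError("sample_times must be non-negative")
    if obs_noise_sd < 0:
        raise InvalidParameterError("obs_noise_sd must be non-negative")

    traj, _ = integrate_ffl(
        params, initial=initial, t_end=float(times.max()) if times.max() > 0 else 0.0,
        t_eval=times,
    )
    frame = traj.to_frame()
    if obs_noise_sd > 0:
        rng = np.random.default_rng(seed)
        for col in ("gat1", "dal80", "mep2"):
            frame[col] = frame[col] + rng.normal(0.0, obs_noise_sd, size=len(frame))
    return frame
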