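"""Per-codon dN/dS profiling of a codon alignment.

For each codon, every single-nucleotide change is classified as synonymous
or nonsynonymous under the standard nuclear genetic code, giving fractional
counts of potential synonymous (S) and nonsynonymous (N) sites with
S + N = 3 (changes that create a stop codon count as nonsynonymous).
Observed differences between a codon pair are resolved by averaging over
all orderings of the single-step mutational pathway, skipping orderings
that pass through a stop codon.  Per amino-acid position, counts are pooled
over all unordered sequence pairs and

    dN = ΣNd / ΣN        dS = ΣSd / ΣS

i.e. the proportion of observed substitutions among potential ones.  These
are raw proportions — no multiple-hit correction — so values can exceed 1;
a low dN against an appreciable dS marks purifying selection, the signature
seen over a DNA binding domain in wild isolates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import StopCodonError, ValidationError

__all__ = [
    "CodonAlignment",
    "DnDsProfile",
    "codon_site_counts",
    "pairwise_codon_substitutions",
    "dnds_profile",
]

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_CODE = dict(_TABLE.forward_table)  # sense codons only

SENSE_CODONS = tuple(sorted(_CODE))


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValidationError(f"not an unambiguous codon: {codon!r}")
    if codon in _STOPS:
        raise StopCodonError(f"stop codon {codon} where a sense codon is required")
    return codon


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Potential synonymous and nonsynonymous sites (S, N) of a sense codon.

    Each of the nine single-nucleotide neighbours is classified by the
    standard code; S is the synonymous count divided by 3 and N = 3 − S.
    Neighbours that are stop codons count as nonsynonymous, keeping
    S + N = 3 exactly.
    """
    codon = _check_sense(codon)
    aa = _CODE[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour not in _STOPS and _CODE[neighbour] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pairwise_codon_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed synonymous and nonsynonymous substitutions (Sd, Nd) between
    two sense codons.

    Codons differing at k positions are connected by k! single-step
    pathways; synonymous/nonsynonymous steps are counted along each and
    averaged.  Pathways passing through a stop codon are skipped and the
    remaining ones re-weighted equally; if every pathway is stop-blocked
    (possible only at k = 3) all pathways are used with stop-crossing steps
    counted as nonsynonymous, so Sd + Nd = k is preserved.
    """
    codon_a = _check_sense(codon_a)
    codon_b = _check_sense(codon_b)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                if not allow_stops:
                    return None
                nonsyn += 1.0
            elif current in _STOPS:
                # leaving a stop codon (allow_stops pathway): nonsynonymous
                nonsyn += 1.0
            elif _CODE[current] == _CODE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn

    results = [r for order in permutations(diff) if (r := walk(order, False)) is not None]
    if not results:
        results = [walk(order, True) for order in permutations(diff)]
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


@dataclass
class CodonAlignment:
    """In-frame codon alignment: equal-length nucleotide sequences."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids and sequences must have equal length")
        if not self.sequences:
            raise ValidationError("alignment is empty")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValidationError("all sequences must have equal length")
        if length % 3 != 0:
            raise ValidationError(f"alignment length {length} is not a multiple of 3")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, seq_index: int, codon_index: int) -> str:
        return self.sequences[seq_index][3 * codon_index : 3 * codon_index + 3]

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=[r.id for r in records], sequences=[str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class DnDsProfile:
    """Per amino-acid-position dN and dS, pooled over all sequence pairs.

    Positions where no valid codon pair was available (all gapped, stops,
    or ambiguity characters) carry NaN, not zero.  ``n_pairs_used`` counts
    the codon pairs that contributed at each position; ``n_skipped`` the
    pairs dropped for gaps/ambiguity/stops.
    """

    dn: np.ndarray
    ds: np.ndarray
    n_pairs_used: np.ndarray
    n_skipped: np.ndarray
    aggregation: str = "pooled-pairwise"

    @property
    def length(self) -> int:
        return self.dn.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position_aa": np.arange(1, self.length + 1),
                "dN": self.dn,
                "dS": self.ds,
                "n_pairs_used": self.n_pairs_used,
            }
        )


def _is_clean(codon: str) -> bool:
    return all(b in _BASES for b in codon) and codon not in _STOPS


def dnds_profile(aln: CodonAlignment) -> DnDsProfile:
    """Per-codon dN/dS across all unordered pairs of aligned sequences.

    At each codon position, observed substitution counts (from
    :func:`pairwise_codon_substitutions`) and potential site counts (the
    mean of the two codons' :func:`codon_site_counts`) are summed over
    pairs, then divided: dN = ΣNd/ΣN, dS = ΣSd/ΣS.  Pairs where either
    codon contains a gap or ambiguity character, or is a stop, are skipped
    for that position.
    """
    if aln.n_sequences < 2:
        raise ValidationError("need at least 2 sequences for a dN/dS profile")

    n_pos = aln.length_codons
    sum_sd = np.zeros(n_pos)
    sum_nd = np.zeros(n_pos)
    sum_s = np.zeros(n_pos)
    sum_n = np.zeros(n_pos)
    used = np.zeros(n_pos, dtype=int)
    skipped = np.zeros(n_pos, dtype=int)

    pairs = list(combinations(range(aln.n_sequences), 2))
    for pos in range(n_pos):
        codons = [aln.codon(i, pos) for i in range(aln.n_sequences)]
        clean = [_is_clean(c) for c in codons]
        for i, j in pairs:
            if not (clean[i] and clean[j]):
                skipped[pos] += 1
                continue
            ca, cb = codons[i], codons[j]
            sd, nd = pairwise_codon_substitutions(ca, cb)
            s_a, n_a = codon_site_counts(ca)
            s_b, n_b = codon_site_counts(cb)
            sum_sd[pos] += sd
            sum_nd[pos] += nd
            sum_s[pos] += (s_a + s_b) / 2.0
            sum_n[pos] += (n_a + n_b) / 2.0
            used[pos] += 1

    if np.any(used == 0):
        warnings.warn(
            f"{int(np.sum(used == 0))} position(s) had no usable codon pair; "
            "reported as NaN",
            stacklevel=2,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        dn = np.where(sum_n > 0, sum_nd / np.where(sum_n > 0, sum_n, 1.0), np.nan)
        ds = np.where(sum_s > 0, sum_sd / np.where(sum_s > 0, sum_s, 1.0), np.nan)
    return DnDsProfile(dn=dn, ds=ds, n_pairs_used=used, n_skipped=skipped)
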