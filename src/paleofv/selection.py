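"""Nei–Gojobori (1986) dN/dS estimation and selection-regime calls.

The counting estimator works on pairs of in-frame codon sequences:

1. every codon contributes synonymous (S) and nonsynonymous (N) *site*
   counts — at each position, the fraction of the three possible
   nucleotide changes that leave the amino acid unchanged (changes
   creating stop codons count as nonsynonymous);
2. observed differences are decomposed into synonymous and nonsynonymous
   *substitutions*; codons differing at more than one position are
   averaged over all minimal mutational pathways, excluding pathways
   that pass through a stop codon (falling back to all pathways when
   every one is blocked);
3. the proportions pS = Sd/S and pN = Nd/N are corrected for multiple
   hits with the Jukes–Cantor formula d = -(3/4)·ln(1 - (4/3)·p), which
   is undefined at p >= 3/4.

omega = dN/dS is reported per pair; a family estimate is the mean over
defined pairs with its standard error.  This is a counting method: do
not expect maximum-likelihood (codeml-style) values to match it exactly,
especially at high divergence or strong codon bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Position by position, each of the three alternative nucleotides is a
    potential change; the synonymous fraction of those changes is that
    position's contribution to S.  S + N = 3 by construction.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if _translate(alt) == aa:  # stops translate to None -> nonsynonymous
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons.

    Averaged over all orderings of the differing positions; orderings
    that pass through a stop codon are excluded.  If every ordering is
    blocked, the average is taken over all orderings instead, so the
    difference count is never silently dropped.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diffs):
        syn = nonsyn = 0
        cur = c1
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if _translate(cur) == _translate(nxt) and nxt not in _STOPS and cur not in _STOPS:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else valid).append((syn, nonsyn))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


_AMBIGUOUS_OK = frozenset("ACGT")


def _clean_codon_pair(a: str, b: str) -> bool:
    """Pairwise-complete rule: both codons unambiguous sense codons."""
    return (
        set(a) <= _AMBIGUOUS_OK
        and set(b) <= _AMBIGUOUS_OK
        and a not in _STOPS
        and b not in _STOPS
    )


def ng86_pairwise(seq_a: str, seq_b: str) -> tuple[float | None, float | None]:
    """Nei–Gojobori dN and dS for one pair of aligned codon sequences.

    Sequences must be equal length and a multiple of 3.  Codon columns
    where either sequence has a gap, an ambiguity code, or a stop codon
    are excluded pairwise-complete.  Returns (dN, dS); either value is
    None when its Jukes–Cantor correction is undefined (p >= 3/4).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3 != 0:
        raise ValueError(f"alignment length {len(seq_a)} is not a multiple of 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()

    S = N = Sd = Nd = 0.0
    n_used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not _clean_codon_pair(ca, cb):
            continue
        n_used += 1
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_used == 0:
        raise ValueError("no usable codon columns in the pair")

    dN = _jukes_cantor(Nd / N) if N > 0 else None
    dS = _jukes_cantor(Sd / S) if S > 0 else None
    return dN, dS


@dataclass
class OmegaEstimate:
    family: str
    pairs: list[tuple[str, str, float | None, float | None]]  # (id_a, id_b, dN, dS)
    omega_mean: float | None
    omega_se: float | None
    n_defined: int
    regime: str  # purifying | neutral | undetermined
    notes: list[str] = field(default_factory=list)


def pairwise_omegas(pairs) -> list[float]:
    """Defined omega values from a list of (id_a, id_b, dN, dS) tuples."""
    out = []
    for _, _, dn, ds in pairs:
        if dn is not None and ds is not None and ds > 0:
            out.append(dn / ds)
    return out


def family_omega(
    sequences: dict[str, str],
    family: str = "",
    alpha: float = 0.05,
) -> OmegaEstimate:
    """Family-level omega over all sequence pairs, with a regime call.

    Pairs whose dS is zero or whose correction is undefined are excluded
    from the mean but kept in the record.  Regime: *purifying* when a
    two-sided one-sample t test of the pairwise omegas against 1 rejects
    at ``alpha`` with mean < 1; *neutral* when it does not reject;
    *undetermined* with fewer than 3 defined pairs (too few sequences).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = sorted(sequences)
    pairs = []
    for a, b in combinations(ids, 2):
        dn, ds = ng86_pairwise(sequences[a], sequences[b])
        pairs.append((a, b, dn, ds))
    omegas = pairwise_omegas(pairs)
    est = OmegaEstimate(
        family=family, pairs=pairs, omega_mean=None, omega_se=None,
        n_defined=len(omegas), regime="undetermined",
    )
    if not omegas:
        est.notes.append("omega undefined for every pair (dS = 0 or saturated)")
        return est
    arr = np.asarray(omegas)
    est.omega_mean = float(arr.mean())
    est.omega_se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
    if len(omegas) < 3:
        est.notes.append("fewer than 3 defined pairs; regime not callable")
        return est
    if arr.std(ddof=1) == 0:
        est.regime = "purifying" if est.omega_mean < 1 else "neutral"
        return est
    _, p = stats.ttest_1samp(arr, popmean=1.0)
    if p < alpha and est.omega_mean < 1:
        est.regime = "purifying"
    else:
        est.regime = "neutral"
        if p < alpha and est.omega_mean > 1:
            est.notes.append("mean omega significantly above 1 (diversifying signal)")
    return est


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    t_statistic: float
    df: int
    p_value: float
    n_a: int
    n_b: int


def compare_groups(omegas_a: list[float], omegas_b: list[float]) -> GroupComparison:
    """Pooled-variance two-sample t test between two omega collections.

    df = n_a + n_b - 2 under the equal-variance convention.  Raises on
    groups smaller than 2 or zero pooled variance.
    """
    if len(omegas_a) < 2 or len(omegas_b) < 2:
        raise ValueError("both groups must contain at least 2 values")
    a, b = np.asarray(omegas_a, float), np.asarray(omegas_b, float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=float(t), df=len(a) + len(b) - 2, p_value=float(p),
        n_a=len(a), n_b=len(b),
    )
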