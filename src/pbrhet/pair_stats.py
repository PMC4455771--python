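"""Partitioned pairwise substitution counts for MHC codon alignments.

For every unordered allele pair the number of nucleotide substitutions is
split three ways with the unweighted Nei-Gojobori pathway method (counting of
numbers only; no multiple-hit correction):

* ``K_S``  - synonymous substitutions over the entire gene,
* ``K_N``  - nonsynonymous substitutions at non-PBR codons,
* ``K_B``  - nonsynonymous substitutions at PBR codons.

``m = K_S + K_N`` counts substitutions at putatively neutral sites and serves
as the pairwise divergence-time proxy of the whole analysis.  Synonymous and
nonsynonymous *site* totals (``L_S``, ``L_N``) use the standard fractional
Nei-Gojobori definition, and the neutral pairwise divergence is

    d = (K_S + K_N / f) / (L_S + L_N),        T = d / (2 mu)

where ``f`` is the functional constraint (mean non-PBR dN/dS over pairs) and
``mu`` the neutral rate (default 1e-9 per site per year for primate MHC).

Codons containing gaps/N and stop codons are excluded per pair, per codon.
For each differing codon all minimal substitution pathways are enumerated
with equal weights; pathways passing through a stop codon are excluded and
the weights renormalised (if every pathway is blocked the stop exclusion is
waived for that codon pair).  Transitions/transversions at PBR codons are
tallied from the differing positions themselves (they are pathway
invariant).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import chi2

from .codon_alignment import AMBIGUOUS, GENETIC_CODE, STOP, CodonAlignment, PbrMask, translate

__all__ = [
    "PairCounts",
    "DivergenceParams",
    "count_sites",
    "pair_site_counts",
    "count_pair",
    "all_pair_counts",
    "functional_constraint",
    "divergence_time",
    "relative_rate_statistic",
    "relative_rate_test",
    "pairs_table",
    "write_pairs_tsv",
]

_PURINES = frozenset("AG")


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES) == (y in _PURINES)


def _is_sense(codon: str) -> bool:
    aa = GENETIC_CODE.get(codon, AMBIGUOUS)
    return aa not in (STOP, AMBIGUOUS)


@lru_cache(maxsize=None)
def _codon_ls(codon: str) -> float:
    """Fractional synonymous sites of one sense codon (Nei-Gojobori).

    Each position contributes (number of synonymous single-nucleotide
    changes)/3; changes to stop codons count as nonsynonymous.
    """
    if not _is_sense(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    ls = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if GENETIC_CODE[mut] == aa:
                ls += 1.0 / 3.0
    return ls


def count_sites(seq: str | Sequence[str]) -> tuple[float, float]:
    """Nei-Gojobori site counts (L_S, L_N) for one codon sequence.

    ``seq`` is a nucleotide string (length divisible by 3) or a list of
    codons.  Ambiguous and stop codons are skipped.  L_N here is the total
    nonsynonymous site count over the supplied codons; restriction to non-PBR
    codons is done by the caller via codon selection.
    """
    codons = _as_codons(seq)
    if not codons:
        raise ValueError("empty sequence")
    ls = 0.0
    n_used = 0
    for c in codons:
        if not _is_sense(c):
            continue
        ls += _codon_ls(c)
        n_used += 1
    if n_used == 0:
        raise ValueError("no sense codons in sequence")
    return ls, 3.0 * n_used - ls


def _as_codons(seq: str | Sequence[str]) -> list[str]:
    if isinstance(seq, str):
        if len(seq) % 3 != 0:
            raise ValueError("nucleotide string length not a multiple of 3")
        return [seq[i : i + 3].upper() for i in range(0, len(seq), 3)]
    return [c.upper() for c in seq]


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) changes between two sense codons.

    Averaged with equal weight over all minimal substitution pathways that do
    not pass through a stop codon; if all pathways are blocked the exclusion
    is waived (steps into/out of stops count as nonsynonymous).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stop: bool) -> tuple[float, float] | None:
        syn = non = 0.0
        cur = c1
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_from, aa_to = GENETIC_CODE[cur], GENETIC_CODE[nxt]
            if aa_to == STOP and not allow_stop:
                return None  # nxt == c2 cannot be a stop: c2 is sense
            if aa_from == aa_to:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        return syn, non

    orders = list(itertools.permutations(diff))
    results = [r for order in orders if (r := walk(order, False)) is not None]
    if not results:
        results = [walk(order, True) for order in orders]
    syn = sum(r[0] for r in results) / len(results)
    non = sum(r[1] for r in results) / len(results)
    return syn, non


def _ts_tv(c1: str, c2: str) -> tuple[int, int]:
    ts = tv = 0
    for x, y in zip(c1, c2):
        if x != y:
            if _is_transition(x, y):
                ts += 1
            else:
                tv += 1
    return ts, tv


@dataclass(frozen=True)
class PairCounts:
    """Partitioned substitution and site counts for one unordered allele pair."""

    allele_a: str
    allele_b: str
    K_S: float
    K_N: float
    K_B: float
    L_S: float
    L_N: float
    Ts_pbr: float
    Tv_pbr: float
    n_codons_used: int = 0
    n_codons_skipped: int = 0

    @property
    def m(self) -> float:
        return self.K_S + self.K_N

    @property
    def m_bin(self) -> int:
        # round to nearest integer, ties up
        return math.floor(self.m + 0.5)

    def key(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))


@dataclass(frozen=True)
class DivergenceParams:
    """Functional constraint f and neutral rate mu (per site per year)."""

    f: float
    mu: float = 1e-9

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("functional constraint f must be > 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


def pair_site_counts(
    codons_a: Sequence[str],
    codons_b: Sequence[str],
    pbr: frozenset[int],
) -> tuple[float, float, int]:
    """Pairwise-averaged (L_S over all codons, L_N over non-PBR codons).

    Codons that are ambiguous or stop in either sequence are excluded in both.
    Returns (L_S, L_N_nonpbr, n_codons_used).
    """
    ls = ln = 0.0
    used = 0
    for idx, (ca, cb) in enumerate(zip(codons_a, codons_b), start=1):
        if not (_is_sense(ca) and _is_sense(cb)):
            continue
        used += 1
        ls_pair = (_codon_ls(ca) + _codon_ls(cb)) / 2.0
        ls += ls_pair
        if idx not in pbr:
            ln += 3.0 - ls_pair
    return ls, ln, used


def count_pair(
    a: str | Sequence[str],
    b: str | Sequence[str],
    mask: PbrMask | None,
    allele_a: str = "a",
    allele_b: str = "b",
) -> PairCounts:
    """Count K_S / K_N / K_B and PBR Ts/Tv for one pair of aligned sequences."""
    codons_a = _as_codons(a)
    codons_b = _as_codons(b)
    if len(codons_a) != len(codons_b):
        raise ValueError("sequences differ in codon length")
    pbr = mask.as_set() if mask is not None else frozenset()
    ks = kn = kb = 0.0
    ts = tv = 0
    used = skipped = 0
    for idx, (ca, cb) in enumerate(zip(codons_a, codons_b), start=1):
        if not (_is_sense(ca) and _is_sense(cb)):
            skipped += 1
            continue
        used += 1
        if ca == cb:
            continue
        syn, non = _pathway_counts(ca, cb)
        ks += syn
        if idx in pbr:
            kb += non
            t1, t2 = _ts_tv(ca, cb)
            ts += t1
            tv += t2
        else:
            kn += non
    ls, ln, _ = pair_site_counts(codons_a, codons_b, pbr)
    return PairCounts(
        allele_a, allele_b, ks, kn, kb, ls, ln, float(ts), float(tv), used, skipped
    )


def all_pair_counts(alignment: CodonAlignment) -> list[PairCounts]:
    """Counts for every unordered pair of alleles in the alignment."""
    names = alignment.names
    codons = {n: alignment.codons(n) for n in names}
    out = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            out.append(count_pair(codons[na], codons[nb], alignment.pbr_mask, na, nb))
    return out


def functional_constraint(pairs: Iterable[PairCounts]) -> tuple[float, int, int]:
    """Mean non-PBR dN/dS over allele pairs: f = mean[(K_N/L_N)/(K_S/L_S)].

    Pairs with K_S = 0 (rate ratio undefined) are excluded.  Returns
    (f, n_used, n_excluded); raises if no pair is eligible.
    """
    ratios = []
    excluded = 0
    for p in pairs:
        if p.K_S <= 0 or p.L_N <= 0 or p.L_S <= 0:
            excluded += 1
            continue
        ratios.append((p.K_N / p.L_N) / (p.K_S / p.L_S))
    if not ratios:
        raise ValueError("no pair with K_S > 0; functional constraint undefined")
    return sum(ratios) / len(ratios), len(ratios), excluded


def divergence_time(p: PairCounts, params: DivergenceParams) -> tuple[float, float]:
    """Neutral divergence d = (K_S + K_N/f)/(L_S + L_N) and time T = d/(2 mu)."""
    denom = p.L_S + p.L_N
    if denom <= 0:
        raise ValueError("no sites; cannot compute divergence")
    d = (p.K_S + p.K_N / params.f) / denom
    return d, d / (2.0 * params.mu)


def relative_rate_statistic(n_a: int, n_b: int) -> tuple[float, float]:
    """Tajima-style relative-rate chi-square for two unique-difference counts.

    chi2 = (n_a - n_b)^2 / (n_a + n_b) with 1 df; returns (statistic, p).
    Undefined (NaN, NaN) when n_a + n_b = 0.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    tot = n_a + n_b
    if tot == 0:
        return float("nan"), float("nan")
    stat = (n_a - n_b) ** 2 / tot
    return stat, float(chi2.sf(stat, df=1))


def relative_rate_test(
    a: str | Sequence[str],
    b: str | Sequence[str],
    outgroup: str | Sequence[str],
    mask: PbrMask | None,
) -> tuple[float, float, int, int]:
    """Relative-rate test on nonsynonymous non-PBR differences.

    A nucleotide site (within a non-PBR codon) counts as unique to ``a`` when
    a differs there while b equals the outgroup, and the change (applied to
    the b/outgroup codon context) alters the amino acid; symmetrically for
    ``b``.  Assumes the outgroup is equidistant from a and b.  Returns
    (chi-square, p, n_a, n_b); the statistic is NaN when n_a + n_b = 0.
    """
    ca, cb, co = _as_codons(a), _as_codons(b), _as_codons(outgroup)
    if not (len(ca) == len(cb) == len(co)):
        raise ValueError("sequences differ in codon length")
    pbr = mask.as_set() if mask is not None else frozenset()
    n_a = n_b = 0
    for idx, (xa, xb, xo) in enumerate(zip(ca, cb, co), start=1):
        if idx in pbr:
            continue
        if not (_is_sense(xa) and _is_sense(xb) and _is_sense(xo)):
            continue
        for pos in range(3):
            if xa[pos] != xb[pos] and xb[pos] == xo[pos]:
                mut = xb[:pos] + xa[pos] + xb[pos + 1 :]
                if GENETIC_CODE.get(mut, AMBIGUOUS) != GENETIC_CODE[xb]:
                    n_a += 1
            elif xb[pos] != xa[pos] and xa[pos] == xo[pos]:
                mut = xa[:pos] + xb[pos] + xa[pos + 1 :]
                if GENETIC_CODE.get(mut, AMBIGUOUS) != GENETIC_CODE[xa]:
                    n_b += 1
    stat, p = relative_rate_statistic(n_a, n_b)
    return stat, p, n_a, n_b


def pairs_table(
    pairs: Iterable[PairCounts], params: DivergenceParams | None = None
) -> pd.DataFrame:
    """One row per unordered pair; adds d and T_years when params are given."""
    rows = []
    for p in pairs:
        row = {
            "allele_a": p.allele_a,
            "allele_b": p.allele_b,
            "K_S": p.K_S,
            "K_N": p.K_N,
            "K_B": p.K_B,
            "L_S": p.L_S,
            "L_N": p.L_N,
            "Ts_pbr": p.Ts_pbr,
            "Tv_pbr": p.Tv_pbr,
            "m": p.m,
            "m_bin": p.m_bin,
        }
        if params is not None:
            d, t = divergence_time(p, params)
            row["d"] = d
            row["T_years"] = t
        rows.append(row)
    return pd.DataFrame(rows)


def write_pairs_tsv(
    pairs: Iterable[PairCounts], path: str | Path, params: DivergenceParams | None = None
) -> None:
    pairs_table(pairs, params).to_csv(path, sep="\t", index=False, float_format="%.6g")
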