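"""Screen for intragenic recombinant alleles with a binomial regional test.

Under clonal descent the substitutions separating two alleles fall on the
gene uniformly, so the number landing in any fixed sub-region is binomial
with success probability equal to the region's length fraction.  A splice
recombinant concentrates one parent's differences inside the exchanged
region, which the two-sided exact binomial tail detects.  Alleles are
removed greedily: the allele involved in the most flagged pairs goes first,
until no flagged pair remains.

The default region scheme tests the PBR-containing first third of the gene
(an exon-2-equivalent window for DRB1) against the remainder, plus a sliding
window (90 bp wide, 30 bp step).  The iteration order and region partition
are an explicit reconstruction of the published allele-exclusion screen; the
original description leaves both open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .codon_alignment import CodonAlignment

__all__ = [
    "RecombTest",
    "binomial_tail_p",
    "binomial_region_test",
    "pairwise_diff_positions",
    "default_regions",
    "screen_all_pairs",
    "filter_alleles",
    "write_report",
]


@dataclass(frozen=True)
class RecombTest:
    """Result of one (pair, region) binomial test; region is in nt, 0-based half-open."""

    allele_a: str
    allele_b: str
    region: tuple[int, int]
    k_region: int
    k_total: int
    p_region: float
    p_value: float
    flagged: bool


def binomial_tail_p(k_region: int, k_total: int, p_region: float) -> float:
    """Two-sided exact binomial tail: twice the smaller tail, capped at 1."""
    if not 0.0 < p_region < 1.0:
        raise ValueError("p_region must be in (0, 1)")
    if not 0 <= k_region <= k_total:
        raise ValueError("need 0 <= k_region <= k_total")
    if k_total == 0:
        return 1.0
    upper = binom.sf(k_region - 1, k_total, p_region)  # P(X >= k)
    lower = binom.cdf(k_region, k_total, p_region)  # P(X <= k)
    return float(min(1.0, 2.0 * min(upper, lower)))


def pairwise_diff_positions(alignment: CodonAlignment) -> dict[frozenset[str], np.ndarray]:
    """0-based nucleotide positions differing per pair; gap/N positions skipped."""
    names = alignment.names
    arr = {n: np.frombuffer(alignment.records[n].encode(), dtype="S1") for n in names}
    valid = {n: np.isin(arr[n], [b"A", b"C", b"G", b"T"]) for n in names}
    out: dict[frozenset[str], np.ndarray] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            ok = valid[na] & valid[nb]
            diff = (arr[na] != arr[nb]) & ok
            out[frozenset((na, nb))] = np.flatnonzero(diff)
    return out


def binomial_region_test(
    allele_a: str,
    allele_b: str,
    diff_positions: np.ndarray,
    region: tuple[int, int],
    total_length: int,
    alpha: float = 0.05,
) -> RecombTest:
    """Binomial test of substitution density inside one nt region [start, end)."""
    start, end = region
    if not (0 <= start < end <= total_length):
        raise ValueError(f"degenerate or out-of-range region {region}")
    if end - start >= total_length:
        raise ValueError("region must be a proper sub-region")
    k_total = int(diff_positions.size)
    k_region = int(np.count_nonzero((diff_positions >= start) & (diff_positions < end)))
    p_region = (end - start) / total_length
    p = binomial_tail_p(k_region, k_total, p_region)
    return RecombTest(
        allele_a, allele_b, (start, end), k_region, k_total, p_region, p, p < alpha
    )


def default_regions(
    total_length: int, window: int = 90, step: int = 30
) -> list[tuple[int, int]]:
    """Exon-2-equivalent first third plus a sliding window over the gene."""
    third = (total_length // 9) * 3  # codon-aligned first third
    regions = []
    if 0 < third < total_length:
        regions.append((0, third))
    pos = 0
    while pos + window < total_length:
        regions.append((pos, pos + window))
        pos += step
    return regions


def screen_all_pairs(
    alignment: CodonAlignment,
    regions: Sequence[tuple[int, int]] | None = None,
    alpha: float = 0.05,
) -> list[RecombTest]:
    if regions is None:
        regions = default_regions(alignment.length)
    diffs = pairwise_diff_positions(alignment)
    tests = []
    for key, positions in diffs.items():
        na, nb = sorted(key)
        for region in regions:
            tests.append(
                binomial_region_test(na, nb, positions, region, alignment.length, alpha)
            )
    return tests


def filter_alleles(
    alignment: CodonAlignment,
    regions: Sequence[tuple[int, int]] | None = None,
    alpha: float = 0.05,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Iteratively drop the allele participating in the most flagged pairs.

    A pair counts as flagged when any region's p-value clears a Bonferroni
    threshold of ``alpha`` over the number of regions tested for that pair,
    so the pair-level false-positive rate stays at ``alpha`` regardless of
    how fine the sliding window is.  Ties break lexicographically by allele
    name.  Returns (kept, removed, report of all tests from the first
    round).  Raises if fewer than three alleles are supplied or if the
    procedure would remove all alleles.
    """
    if len(alignment.names) < 3:
        raise ValueError("need at least 3 alleles to screen for recombinants")
    if regions is None:
        regions = default_regions(alignment.length)
    alpha_region = alpha / len(regions)
    current = alignment
    removed: list[str] = []
    first_report: pd.DataFrame | None = None
    while True:
        tests = screen_all_pairs(current, regions, alpha_region)
        if first_report is None:
            first_report = _report_frame(tests)
        flagged_pairs = {
            frozenset((t.allele_a, t.allele_b)) for t in tests if t.flagged
        }
        if not flagged_pairs:
            break
        degree: dict[str, int] = {}
        for pair in flagged_pairs:
            for name in pair:
                degree[name] = degree.get(name, 0) + 1
        worst = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        removed.append(worst)
        keep = [n for n in current.names if n != worst]
        if len(keep) < 2:
            raise ValueError("recombination screen removed almost all alleles")
        current = current.subset(keep)
    return current.names, removed, first_report


def _report_frame(tests: Iterable[RecombTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "allele_a": t.allele_a,
                "allele_b": t.allele_b,
                "region_start": t.region[0],
                "region_end": t.region[1],
                "k_region": t.k_region,
                "k_total": t.k_total,
                "p_region": t.p_region,
                "p_value": t.p_value,
                "flagged": t.flagged,
            }
            for t in tests
        ]
    )


def write_report(report: pd.DataFrame, removed: Sequence[str], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "recomb_report.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "removed_alleles.txt").write_text("".join(f"{n}\n" for n in removed))
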