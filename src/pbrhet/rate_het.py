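"""Detect branches with unusually fast or slow PBR substitution rates.

Each branch of the non-PBR tree contributes one point: x = non-PBR
substitutions on the branch (branch length converted to an absolute count,
or a parsimony re-estimate), y = PBR amino-acid substitutions mapped onto
the branch by parsimony.  If the molecular clock held at both partitions the
points would scatter around a proportional line; branches falling outside
the 95% band of that line are rate-shift candidates.  Candidates are
retained only when (i) the branch's x confidence interval excludes zero and
(ii) internal branches carry bootstrap support above a threshold (default
80%); retained points below the band are "slow", above it "fast".

Two statistical choices matter for count data.  First, the clock line is
fitted through the origin by a symmetrically trimmed Poisson rate estimate:
the branches the procedure hunts for are exactly the long, high-leverage
points that drag an ordinary least-squares line toward themselves and mask
their own detection (classical OLS with intercept remains available via
``fit="ols"``).  Second, because y values are small counts whose scatter
grows with branch length, candidate calls use exact overdispersed-count
tail probabilities (Poisson, or gamma-Poisson when the estimated dispersion
phi exceeds 1) instead of a homoscedastic normal band; branches whose
predicted count is below ~2 are never called, since no deviation on them is
distinguishable from zero.  The classical homoscedastic prediction band and
the (much narrower) mean-response confidence band remain available via
``band="prediction"`` / ``band="confidence"``.

Every leaf descending from a classified branch inherits the class of its
nearest classified ancestor; all other alleles are "normal".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .tree_ops import AnnotatedTree, BranchId

__all__ = [
    "BranchPoint",
    "RateRegression",
    "branch_points",
    "branch_length_cis_from_counts",
    "detect_outliers",
    "lineage_classes",
    "write_branches_tsv",
]


@dataclass
class BranchPoint:
    """One branch's (non-PBR, PBR) substitution counts plus filter inputs."""

    branch_id: BranchId
    x: float
    y: float
    bootstrap: float | None = None
    length_ci: tuple[float, float] | None = None
    is_internal: bool = True
    outlier: str = "none"  # none | above | below
    passes_filters: bool = False


#: expected-count floor used on the Poisson scale so the band never
#: collapses to zero width near the origin
POISSON_FLOOR = 0.5

#: a branch is only testable when the clock line predicts at least this many
#: events on it; below that no deviation can be distinguished from zero
MIN_TESTABLE_PRED = 2.0


@dataclass
class RateRegression:
    """Fitted clock line over branches with the flagged rate-shift outliers."""

    slope: float
    intercept: float
    sigma: float  # homoscedastic residual SD
    phi: float  # quasi-Poisson dispersion of standardized residuals
    n_branches: int
    x_mean: float
    sxx: float
    band: str
    alpha: float
    points: list[BranchPoint] = field(default_factory=list)

    @property
    def slow_branches(self) -> list[BranchId]:
        return [p.branch_id for p in self.points if p.outlier == "below"]

    @property
    def fast_branches(self) -> list[BranchId]:
        return [p.branch_id for p in self.points if p.outlier == "above"]

    def band_halfwidth(self, x: float) -> float:
        tcrit = t_dist.ppf(1.0 - self.alpha / 2.0, df=self.n_branches - 2)
        if self.band == "poisson":
            mu = max(self.predict(x), POISSON_FLOOR)
            return float(tcrit * np.sqrt(self.phi * mu))
        lever = 1.0 / self.n_branches + (x - self.x_mean) ** 2 / self.sxx
        if self.band == "prediction":
            lever += 1.0
        return float(tcrit * self.sigma * np.sqrt(lever))

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def branch_points(
    at: AnnotatedTree,
    x_source: str = "branch_length",
    nonpbr_counts: Mapping[BranchId, float] | None = None,
    length_cis: Mapping[BranchId, tuple[float, float]] | None = None,
    pbr_counts: Mapping[BranchId, float] | None = None,
) -> list[BranchPoint]:
    """One (x, y) point per branch, outgroup branches excluded.

    ``x_source`` chooses the x value: "branch_length" converts the stored
    branch length to absolute non-PBR substitutions using ``nonpbr_sites``
    when lengths are per site; "counts" reads ``nonpbr_counts`` (e.g. a
    parsimony or distance-fit re-estimate).  ``y`` defaults to the mapped
    parsimony event count (``fitch_map`` must have run); passing
    ``pbr_counts`` (e.g. from ``jtt_branch_lengths``) overrides it with
    model-based estimates, which do not saturate on a short region.
    """
    points = []
    scale = 1.0
    if x_source == "branch_length" and at.branch_length_unit == "per_site":
        if not at.nonpbr_sites:
            raise ValueError(
                "per-site branch lengths need nonpbr_sites to convert to counts"
            )
        scale = float(at.nonpbr_sites)
    for bid, node in at.branches(skip_outgroup=True):
        if x_source == "counts":
            if nonpbr_counts is None:
                raise ValueError("x_source='counts' requires nonpbr_counts")
            x = float(nonpbr_counts.get(bid, 0.0))
        else:
            if node.edge.length is None:
                raise ValueError(f"branch {bid} has no length")
            x = float(node.edge.length) * scale
        if pbr_counts is not None:
            y = float(pbr_counts.get(bid, 0.0))
        else:
            y = float(len(at.pbr_events.get(bid, [])))
        points.append(
            BranchPoint(
                bid,
                x,
                y,
                bootstrap=at.bootstrap.get(bid),
                length_ci=None if length_cis is None else length_cis.get(bid),
                is_internal=at.is_internal_branch(bid),
            )
        )
    return points


def branch_length_cis_from_counts(
    per_site_counts: Mapping[BranchId, np.ndarray],
    n_bootstrap: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict[BranchId, tuple[float, float]]:
    """Site-resampling bootstrap CIs for per-branch substitution counts.

    ``per_site_counts`` maps branch to a per-site event-count vector (e.g.
    from Fitch mapping of every non-PBR column); because parsimony scores are
    per-site additive, resampling columns reduces to reweighting the vectors,
    which makes the bootstrap essentially free.
    """
    bids = list(per_site_counts)
    if not bids:
        return {}
    mat = np.vstack([np.asarray(per_site_counts[b], dtype=float) for b in bids])
    n_sites = mat.shape[1]
    rng = np.random.default_rng(seed)
    w = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=n_bootstrap)
    boot = mat @ w.T  # branches x replicates
    lo = np.quantile(boot, (1.0 - level) / 2.0, axis=1)
    hi = np.quantile(boot, 1.0 - (1.0 - level) / 2.0, axis=1)
    return {b: (float(l), float(h)) for b, l, h in zip(bids, lo, hi)}


def _theil_sen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Median-of-pairwise-slopes line; immune to a minority of rate-shifted
    branches dragging the clock line (OLS masking)."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    mask = np.triu(dx != 0, k=1) | np.tril(dx != 0, k=-1)
    slopes = dy[mask] / dx[mask]
    slope = float(np.median(slopes))
    return slope, float(np.median(y - slope * x))


def _trimmed_poisson_slope(
    x: np.ndarray, y: np.ndarray, trim: float = 0.1, iters: int = 4
) -> tuple[float, np.ndarray]:
    """Through-origin clock rate Sum(y)/Sum(x), iteratively refitted after
    dropping the ``trim`` fraction of branches with the most extreme
    standardized residuals.

    Sum(y)/Sum(x) is the Poisson MLE of a proportional rate; the trimming
    keeps a minority of genuinely rate-shifted branches from dragging the
    line toward themselves (the masking failure of plain OLS), while zero
    counts on short branches - the typical case - carry no leverage.
    """
    keep = np.ones(x.size, dtype=bool)
    if x.sum() <= 0:
        return 0.0, keep
    slope = float(y.sum() / x.sum())
    # symmetric trim: drop the same number of extremes on each side, so the
    # refit stays centred whichever direction the shifted branches pull
    n_drop = int(np.ceil(trim * x.size))
    for _ in range(iters):
        denom = x[keep].sum()
        slope = float(y[keep].sum() / denom) if denom > 0 else slope
        std = (y - slope * x) / np.sqrt(np.maximum(slope * x, POISSON_FLOOR))
        order = np.argsort(std)
        keep = np.ones(x.size, dtype=bool)
        keep[order[:n_drop]] = False
        keep[order[-n_drop:]] = False
    return slope, keep


def detect_outliers(
    points: Sequence[BranchPoint],
    alpha: float = 0.05,
    min_bootstrap: float = 80.0,
    band: str = "poisson",
    fit: str = "trimmed-poisson",
    require_length_ci: bool = True,
) -> RateRegression:
    """Regression of PBR events on non-PBR branch length with outlier calls.

    The clock line is fitted through the origin by a trimmed Poisson rate
    estimate by default (``fit``: "trimmed-poisson", "theil-sen" or "ols"):
    the rate-shifted branches the procedure hunts for are exactly the long,
    high-leverage points that drag an OLS line toward themselves and mask
    their own detection, and most branches carry zero events, which defeats
    a pairwise-median slope.  A point is a candidate
    when it falls outside the ``1 - alpha`` band of the regression (``band``:
    "poisson" quasi-Poisson prediction band, "prediction" homoscedastic
    prediction band, "confidence" mean-response band); it is retained as a
    rate-shift only if its branch-length CI excludes zero (when CIs are
    available or required) and, for internal branches, bootstrap support
    exceeds ``min_bootstrap``.  Terminal branches bypass the bootstrap
    filter.
    """
    if band not in ("poisson", "prediction", "confidence"):
        raise ValueError("band must be 'poisson', 'prediction' or 'confidence'")
    if fit not in ("trimmed-poisson", "theil-sen", "ols"):
        raise ValueError("fit must be 'trimmed-poisson', 'theil-sen' or 'ols'")
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 branch points")
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("all branch x values identical; regression undefined")
    kept = np.ones(x.size, dtype=bool)
    if fit == "trimmed-poisson":
        slope, kept = _trimmed_poisson_slope(x, y)
        intercept = 0.0
    elif fit == "theil-sen":
        slope, intercept = _theil_sen(x, y)
    else:
        slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
        intercept = float(y.mean() - slope * x.mean())
    pred = intercept + slope * x
    resid = y - pred
    dof = len(pts) - 2
    std = resid / np.sqrt(np.maximum(pred, POISSON_FLOOR))
    mean_sigma = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    mean_phi = float((std**2).sum() / dof) if dof > 0 else 0.0
    if fit in ("trimmed-poisson", "theil-sen"):
        # robust scales over testable, trim-retained branches only, so that
        # rate-shift candidates and the un-testable short-branch majority do
        # not distort their own band; fall back to mean scales if degenerate
        testable = (pred >= MIN_TESTABLE_PRED) & kept
        if not testable.any():
            testable = pred >= MIN_TESTABLE_PRED
        base = std[testable] if testable.any() else std
        base_r = resid[testable] if testable.any() else resid
        sigma = float(1.4826 * np.median(np.abs(base_r))) or mean_sigma
        phi = float((1.4826 * np.median(np.abs(base))) ** 2) or mean_phi
        # counts cannot be less dispersed than Poisson; a discrete median on
        # small counts can suggest otherwise, so floor the dispersion at 1
        phi = max(phi, 1.0)
    else:
        sigma = mean_sigma
        phi = mean_phi
    reg = RateRegression(
        slope, intercept, sigma, phi, len(pts), float(x.mean()), sxx, band, alpha, pts
    )
    spread = sigma if band != "poisson" else phi
    for p in pts:
        ci_ok = True
        if require_length_ci:
            ci_ok = p.length_ci is not None and p.length_ci[0] > 0.0
        boot_ok = (not p.is_internal) or (
            p.bootstrap is not None and p.bootstrap > min_bootstrap
        )
        p.passes_filters = ci_ok and boot_ok
        p.outlier = "none"
        if spread == 0.0 or not p.passes_filters:
            continue
        mu = reg.predict(p.x)
        if band == "poisson":
            if mu < MIN_TESTABLE_PRED:
                continue
            lo_p, hi_p = _count_tails(p.y, mu, phi)
            if hi_p < alpha / 2.0:
                p.outlier = "above"
            elif lo_p < alpha / 2.0:
                p.outlier = "below"
            continue
        half = reg.band_halfwidth(p.x)
        if p.y > mu + half:
            p.outlier = "above"
        elif p.y < mu - half:
            p.outlier = "below"
    return reg


def _count_tails(y: float, mu: float, phi: float) -> tuple[float, float]:
    """Exact lower/upper tail probabilities of an overdispersed count.

    Poisson when phi <= 1, else a gamma-Poisson mixture (negative binomial
    parameterized so the mean is mu and the variance phi * mu); exact tails
    respect the skew of small counts where a normal band does not.
    """
    from scipy.stats import nbinom, poisson

    k = int(np.floor(y))
    if phi <= 1.0 + 1e-9:
        lo = float(poisson.cdf(k, mu))
        hi = float(poisson.sf(k - 1, mu))
    else:
        r = mu / (phi - 1.0)
        prob = 1.0 / phi
        lo = float(nbinom.cdf(k, r, prob))
        hi = float(nbinom.sf(k - 1, r, prob))
    return lo, hi


def lineage_classes(
    reg: RateRegression, at: AnnotatedTree
) -> dict[str, str]:
    """Per-allele rate class inherited from the nearest classified ancestor.

    Branches flagged "above" are fast, "below" slow; every leaf under a
    classified branch takes the class of the closest such ancestor branch;
    all remaining alleles (including the outgroup) are "normal".
    """
    flagged: dict[BranchId, str] = {}
    for p in reg.points:
        if p.outlier == "above":
            flagged[p.branch_id] = "fast"
        elif p.outlier == "below":
            flagged[p.branch_id] = "slow"
    at.branch_class = {
        bid: flagged.get(bid, "normal") for bid, _ in at.branches()
    }
    classes: dict[str, str] = {}
    for leaf in at.tree.leaf_node_iter():
        label = leaf.taxon.label
        node = leaf
        cls = "normal"
        while node.parent_node is not None:
            bid = at.branch_id(node)
            if bid in flagged:
                cls = flagged[bid]
                break
            node = node.parent_node
        classes[label] = cls
    return classes


def write_branches_tsv(reg: RateRegression, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "branch_id": "|".join(p.branch_id),
                "x": p.x,
                "y": p.y,
                "bootstrap": p.bootstrap,
                "ci_low": None if p.length_ci is None else p.length_ci[0],
                "ci_high": None if p.length_ci is None else p.length_ci[1],
                "internal": p.is_internal,
                "passes_filters": p.passes_filters,
                "outlier": p.outlier,
            }
            for p in reg.points
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
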