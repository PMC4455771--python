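import numpy as np
import pytest
from scipy.stats import t as t_dist

import dendropy

from pbrhet.rate_het import (
    BranchPoint,
    branch_length_cis_from_counts,
    branch_points,
    detect_outliers,
    lineage_classes,
)
from pbrhet.tree_ops import annotate_tree, fitch_map


def tree_from(newick, **kw):
    t = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return annotate_tree(t, **kw)


def make_points(xy, bootstrap=100.0, ci=(1.0, 5.0)):
    return [
        BranchPoint(
            (f"b{i}",), float(x), float(y), bootstrap=bootstrap, length_ci=ci,
            is_internal=False,
        )
        for i, (x, y) in enumerate(xy)
    ]


class TestBranchPoints:
    def test_star_tree_zero_lengths(self):
        at = tree_from("(A:0,B:0,C:0,D:0);", branch_length_unit="absolute")
        pts = branch_points(at, x_source="branch_length")
        assert all(p.x == 0 and p.y == 0 for p in pts)
        assert len(pts) == 4

    def test_internal_branch_carries_mapped_event(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);", branch_length_unit="absolute")
        fitch_map(at, {"A": "V", "B": "V", "C": "G", "D": "G"})
        pts = branch_points(at)
        internal = [p for p in pts if p.is_internal]
        assert sorted(p.y for p in internal) == [0.0, 1.0]

    def test_outgroup_branches_excluded(self):
        at = tree_from(
            "((A:1,B:1):1,OG:3);", branch_length_unit="absolute"
        )
        at.outgroup = ("OG",)
        pts = branch_points(at)
        assert all("OG" not in p.branch_id for p in pts)

    def test_counts_source(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);", branch_length_unit="absolute")
        counts = {bid: 7.0 for bid, _ in at.branches()}
        pts = branch_points(at, x_source="counts", nonpbr_counts=counts)
        assert all(p.x == 7.0 for p in pts)

    def test_per_site_lengths_need_site_count(self):
        at = tree_from("((A:1,B:1):1,C:1);", branch_length_unit="per_site")
        with pytest.raises(ValueError):
            branch_points(at)


class TestDetectOutliers:
    def test_perfectly_collinear_no_outliers(self):
        pts = make_points([(x, 2 * x) for x in range(10)])
        reg = detect_outliers(pts)
        assert reg.slow_branches == [] and reg.fast_branches == []
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == 0.0

    def test_ols_mode_recovers_line_with_intercept(self):
        pts = make_points([(x, 2 * x + 1) for x in range(10)])
        reg = detect_outliers(pts, fit="ols", band="prediction")
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.slow_branches == [] and reg.fast_branches == []

    def test_gross_outlier_flagged_fast(self):
        xy = [(x, 0.5 * x + np.sin(x) * 0.05) for x in range(20)]
        xbar = np.mean([x for x, _ in xy])
        xy.append((xbar, 5.0 * (0.5 * xbar)))
        pts = make_points(xy)
        reg = detect_outliers(pts)
        assert pts[-1].outlier == "above"
        assert reg.fast_branches == [pts[-1].branch_id]

    def test_identical_x_errors(self):
        pts = make_points([(1.0, y) for y in range(5)])
        with pytest.raises(ValueError):
            detect_outliers(pts)

    def test_band_halfwidth_matches_closed_form(self):
        rng = np.random.default_rng(5)
        xy = [(x, x + rng.normal(0, 1)) for x in np.linspace(0, 10, 15)]
        pts = make_points(xy)
        reg = detect_outliers(pts, band="prediction", fit="ols")
        x = np.array([p.x for p in pts])
        y = np.array([p.y for p in pts])
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        icpt = y.mean() - slope * x.mean()
        s = np.sqrt(((y - icpt - slope * x) ** 2).sum() / (n - 2))
        x0 = 3.3
        half = t_dist.ppf(0.975, n - 2) * s * np.sqrt(1 + 1 / n + (x0 - x.mean()) ** 2 / sxx)
        assert reg.band_halfwidth(x0) == pytest.approx(half)

    def test_confidence_band_is_narrower(self):
        rng = np.random.default_rng(6)
        xy = [(x, x + rng.normal(0, 1)) for x in np.linspace(0, 10, 15)]
        conf = detect_outliers(make_points(xy), band="confidence")
        pred = detect_outliers(make_points(xy), band="prediction")
        assert conf.band_halfwidth(5.0) < pred.band_halfwidth(5.0)

    def test_filters_block_outlier_calls(self):
        xy = [(x, 0.5 * x) for x in range(20)] + [(9.5, 40.0)]
        # candidate's CI includes zero -> not flagged
        pts = make_points(xy, ci=(0.0, 5.0))
        reg = detect_outliers(pts)
        assert reg.fast_branches == []
        assert not pts[-1].passes_filters

    def test_low_bootstrap_internal_branch_blocked(self):
        xy = [(x, 0.5 * x) for x in range(20)] + [(9.5, 40.0)]
        pts = make_points(xy, bootstrap=50.0)
        for p in pts:
            p.is_internal = True
        reg = detect_outliers(pts, min_bootstrap=80.0)
        assert reg.fast_branches == []

    def test_terminal_branches_bypass_bootstrap_filter(self):
        xy = [(x, 0.5 * x) for x in range(20)] + [(9.5, 40.0)]
        pts = make_points(xy, bootstrap=None)  # terminal: is_internal False
        reg = detect_outliers(pts)
        assert reg.fast_branches == [pts[-1].branch_id]

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        xy = [(x, x + rng.normal(0, 0.5)) for x in np.linspace(0, 10, 12)]
        xy.append((5.0, 25.0))
        a = detect_outliers(make_points(xy))
        b = detect_outliers(make_points(xy[::-1]))
        xy_a = {(p.x, p.y) for p in a.points if p.outlier == "above"}
        xy_b = {(p.x, p.y) for p in b.points if p.outlier == "above"}
        assert xy_a == xy_b and xy_a == {(5.0, 25.0)}


class TestBranchLengthCIs:
    def test_constant_counts_have_degenerate_ci(self):
        per_site = {("b0",): np.ones(100)}
        cis = branch_length_cis_from_counts(per_site, n_bootstrap=50, seed=1)
        lo, hi = cis[("b0",)]
        assert lo == pytest.approx(100.0) and hi == pytest.approx(100.0)

    def test_sparse_counts_ci_includes_zero(self):
        vec = np.zeros(200)
        vec[0] = 1.0  # single event -> resampling often drops it
        cis = branch_length_cis_from_counts({("b0",): vec}, n_bootstrap=200, seed=1)
        lo, _ = cis[("b0",)]
        assert lo == 0.0

    def test_dense_counts_ci_excludes_zero(self):
        rng = np.random.default_rng(2)
        vec = (rng.random(200) < 0.1).astype(float)  # ~20 events
        cis = branch_length_cis_from_counts({("b0",): vec}, n_bootstrap=200, seed=1)
        lo, _ = cis[("b0",)]
        assert lo > 0.0


class TestLineageClasses:
    def test_no_flags_all_normal(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);", branch_length_unit="absolute")
        pts = branch_points(at)
        for p in pts:
            p.length_ci = (1.0, 2.0)
        reg = detect_outliers(
            [BranchPoint(("z1",), x, float(x), None, (1, 2), False) for x in range(5)]
        )
        classes = lineage_classes(reg, at)
        assert set(classes.values()) == {"normal"}

    def test_descendants_inherit_slow_class(self):
        at = tree_from(
            "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", branch_length_unit="absolute"
        )
        reg = detect_outliers(
            make_points([(x, 0.5 * x) for x in range(10)])
        )
        slow_bid = ("A", "B", "C")
        reg.points.append(
            BranchPoint(slow_bid, 5.0, 0.0, 100.0, (1, 2), True, "below", True)
        )
        classes = lineage_classes(reg, at)
        assert classes["A"] == classes["B"] == classes["C"] == "slow"
        assert classes["D"] == classes["E"] == "normal"

    def test_nearest_classified_ancestor_wins(self):
        at = tree_from(
            "(((A:1,B:1):1,C:1):1,D:1);", branch_length_unit="absolute"
        )
        reg = detect_outliers(make_points([(x, 0.5 * x) for x in range(10)]))
        reg.points.append(
            BranchPoint(("A", "B", "C"), 5.0, 50.0, 100.0, (1, 2), True, "above", True)
        )
        reg.points.append(
            BranchPoint(("A", "B"), 3.0, 0.0, 100.0, (1, 2), True, "below", True)
        )
        classes = lineage_classes(reg, at)
        assert classes["A"] == "slow"  # nearest ancestor (A,B) is slow
        assert classes["C"] == "fast"
        assert classes["D"] == "normal"
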