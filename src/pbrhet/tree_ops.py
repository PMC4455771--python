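"""Tree handling: import, NJ/HKY fallback, Fitch mapping of PBR changes, JTT.

The analysis places amino-acid substitutions at the peptide-binding region
(PBR) onto the branches of a phylogeny built from non-PBR nucleotide sites
only, so that the x-axis (neutral-ish branch length) and the y-axis (PBR
events) of the rate-heterogeneity regression come from disjoint data.

A user-supplied newick tree (e.g. from an external ML program, with
bootstrap supports as internal-node labels) is the preferred input; the
``nj_tree_hky`` fallback builds a neighbour-joining tree from pairwise ML
distances under the HKY model restricted to non-PBR sites, with
site-resampling bootstrap supports.

PBR events are mapped by generalized Fitch parsimony with a delayed-
transformation (DELTRAN) tie-break: when the placement of a change is
ambiguous it is pushed toward the tips, which is conservative for
attributing rate shifts to deep branches.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .codon_alignment import CodonAlignment

__all__ = [
    "BranchId",
    "AnnotatedTree",
    "ParallelSubstitution",
    "read_tree",
    "nj_tree_hky",
    "hky_distance_matrix",
    "fitch_events",
    "fitch_map",
    "fitch_site_score",
    "jtt_distance",
    "nnls_branch_lengths",
    "jtt_branch_lengths",
    "parallel_census",
    "write_events_tsv",
]

#: a branch is identified by the sorted tuple of leaf labels below it
BranchId = tuple[str, ...]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
JTT_MAX_DISTANCE = 10.0
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class AnnotatedTree:
    """Rooted tree with per-branch lengths, supports, PBR events and rate class.

    ``branch_length_unit`` records whether lengths are substitutions per site
    ("per_site") or absolute substitution counts ("absolute");
    ``nonpbr_sites`` allows conversion between the two.
    """

    tree: dendropy.Tree
    branch_length_unit: str = "per_site"
    nonpbr_sites: int | None = None
    bootstrap: dict[BranchId, float] = field(default_factory=dict)
    pbr_events: dict[BranchId, list[tuple[int, str, str]]] = field(default_factory=dict)
    branch_class: dict[BranchId, str] = field(default_factory=dict)
    outgroup: tuple[str, ...] = ()

    def leaf_names(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def branch_id(self, node: dendropy.Node) -> BranchId:
        return tuple(sorted(l.taxon.label for l in node.leaf_iter()))

    def branches(self, skip_outgroup: bool = False) -> list[tuple[BranchId, dendropy.Node]]:
        """All branches (edge above each non-root node), optionally without
        the outgroup-side branches."""
        out = []
        og = set(self.outgroup)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            bid = self.branch_id(node)
            if skip_outgroup and og and set(bid) <= og:
                continue
            out.append((bid, node))
        return out

    def branch_lengths(self, skip_outgroup: bool = False) -> dict[BranchId, float]:
        return {
            bid: (node.edge.length or 0.0)
            for bid, node in self.branches(skip_outgroup)
        }

    def is_internal_branch(self, bid: BranchId) -> bool:
        return len(bid) > 1

    def total_pbr_events(self) -> int:
        return sum(len(v) for v in self.pbr_events.values())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


class TreeError(ValueError):
    """Malformed tree input or tree/alignment mismatch."""


def _root_at_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> None:
    taxa = [t for t in tree.taxon_namespace if t.label in set(outgroup)]
    if not taxa:
        raise TreeError(f"outgroup leaves {list(outgroup)} not found in tree")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
    if node is tree.seed_node:
        # already positioned; try rooting on the complement's mrca
        return
    tree.reroot_at_edge(node.edge, update_bipartitions=False)


def read_tree(
    path: str | Path,
    alignment: CodonAlignment | None = None,
    outgroup: Sequence[str] = (),
    branch_length_unit: str = "per_site",
    nonpbr_sites: int | None = None,
) -> AnnotatedTree:
    """Read a newick tree; internal-node labels are taken as bootstrap supports.

    Leaves must match alignment allele names exactly when an alignment is
    given.  The tree is (re)rooted on the named outgroup leaves if supplied.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse newick file {path}: {exc}") from exc
    return annotate_tree(tree, alignment, outgroup, branch_length_unit, nonpbr_sites)


def annotate_tree(
    tree: dendropy.Tree,
    alignment: CodonAlignment | None = None,
    outgroup: Sequence[str] = (),
    branch_length_unit: str = "per_site",
    nonpbr_sites: int | None = None,
) -> AnnotatedTree:
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise TreeError("duplicate leaf labels in tree")
    if alignment is not None:
        missing = set(leaves) - set(alignment.names)
        if missing:
            raise TreeError(f"tree leaves absent from alignment: {sorted(missing)}")
    if outgroup:
        _root_at_outgroup(tree, outgroup)
    at = AnnotatedTree(
        tree,
        branch_length_unit=branch_length_unit,
        nonpbr_sites=nonpbr_sites,
        outgroup=tuple(outgroup),
    )
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        if node.label not in (None, ""):
            try:
                at.bootstrap[at.branch_id(node)] = float(node.label)
            except ValueError:
                pass
    return at


# ---------------------------------------------------------------------------
# pairwise ML distances (HKY for nucleotides, JTT for PBR amino acids)
# ---------------------------------------------------------------------------


def _normalized_q(exchangeabilities: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Reversible rate matrix Q_ij = s_ij * pi_j scaled to one expected
    substitution per unit time."""
    q = exchangeabilities * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    return q / scale


class _ReversibleModel:
    """Eigendecomposed reversible model; P(t) via the symmetrized spectrum."""

    def __init__(self, exchangeabilities: np.ndarray, freqs: np.ndarray):
        self.freqs = freqs
        self.q = _normalized_q(exchangeabilities, freqs)
        rt = np.sqrt(freqs)
        sym = (rt[:, None] * self.q) / rt[None, :]
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        self._vals = vals
        self._left = vecs / rt[:, None]
        self._right = (vecs * rt[:, None]).T

    def transition_probs(self, t: float) -> np.ndarray:
        p = (self._left * np.exp(self._vals * t)) @ self._right
        return np.clip(p, 1e-300, None)

    def log_likelihood(self, t: float, pattern_counts: np.ndarray) -> float:
        p = self.transition_probs(t)
        joint = self.freqs[:, None] * p
        return float((pattern_counts * np.log(joint)).sum())

    def ml_distance(self, pattern_counts: np.ndarray, t_max: float) -> float:
        off = pattern_counts.sum() - np.trace(pattern_counts)
        if off == 0:
            return 0.0
        res = minimize_scalar(
            lambda t: -self.log_likelihood(t, pattern_counts),
            bounds=(1e-9, t_max),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)


def _hky_exchangeabilities(kappa: float) -> np.ndarray:
    s = np.ones((4, 4))
    # transitions: A<->G (0,2) and C<->T (1,3)
    s[0, 2] = s[2, 0] = s[1, 3] = s[3, 1] = kappa
    np.fill_diagonal(s, 0.0)
    return s


def _encode_sites(alignment: CodonAlignment, positions: np.ndarray) -> dict[str, np.ndarray]:
    enc = {}
    for name, seq in alignment.records.items():
        arr = np.full(len(seq), -1, dtype=np.int8)
        for nt, i in _NT_INDEX.items():
            arr[np.frombuffer(seq.encode(), dtype="S1") == nt.encode()] = i
        enc[name] = arr[positions]
    return enc


def _pattern_counts(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    ok = (a >= 0) & (b >= 0)
    code = a[ok] * 4 + b[ok]
    w = None if weights is None else weights[ok]
    return np.bincount(code, weights=w, minlength=16).reshape(4, 4).astype(float)


def estimate_kappa(alignment: CodonAlignment, positions: np.ndarray) -> float:
    """Pooled ML estimate of the HKY transition/transversion rate ratio.

    Maximizes the likelihood of the summed pairwise pattern counts over a
    common divergence and kappa; adequate for the NJ fallback's distances.
    """
    enc = _encode_sites(alignment, positions)
    names = alignment.names
    pooled = np.zeros((4, 4))
    for na, nb in itertools.combinations(names, 2):
        pooled += _pattern_counts(enc[na], enc[nb])
    pooled = (pooled + pooled.T) / 2.0
    freqs = _empirical_freqs(pooled)

    def neg(params: np.ndarray) -> float:
        t, log_kappa = params
        if t <= 0:
            return np.inf
        model = _ReversibleModel(_hky_exchangeabilities(np.exp(log_kappa)), freqs)
        return -model.log_likelihood(t, pooled)

    res = minimize(neg, x0=np.array([0.05, np.log(2.0)]), method="Nelder-Mead")
    return float(np.exp(res.x[1]))


def _empirical_freqs(pooled: np.ndarray) -> np.ndarray:
    f = pooled.sum(axis=1) + pooled.sum(axis=0)
    f = f / f.sum()
    return np.clip(f, 1e-6, None) / np.clip(f, 1e-6, None).sum()


def hky_distance_matrix(
    alignment: CodonAlignment,
    positions: np.ndarray,
    kappa: float | None = None,
    weights: np.ndarray | None = None,
    t_max: float = 20.0,
) -> tuple[np.ndarray, list[str], float]:
    """Pairwise ML distances under HKY restricted to the given nt positions.

    ``weights`` (per position) implement site-resampling bootstrap without
    re-extracting columns.  Raises when a pair's distance hits ``t_max``
    (saturation), naming the pair.
    """
    names = alignment.names
    enc = _encode_sites(alignment, positions)
    pooled = np.zeros((4, 4))
    for na, nb in itertools.combinations(names, 2):
        pooled += _pattern_counts(enc[na], enc[nb], weights)
    freqs = _empirical_freqs(pooled)
    if kappa is None:
        kappa = estimate_kappa(alignment, positions)
    model = _ReversibleModel(_hky_exchangeabilities(kappa), freqs)
    n = len(names)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        counts = _pattern_counts(enc[names[i]], enc[names[j]], weights)
        d = model.ml_distance(counts, t_max)
        if d >= t_max * 0.999:
            raise TreeError(
                f"HKY distance saturated for pair ({names[i]}, {names[j]})"
            )
        dm[i, j] = dm[j, i] = d
    return dm, names, kappa


def _nj_newick(dm: np.ndarray, names: list[str]) -> str:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(dm, ids=names))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0")
    return str(tree)


def _splits(newick: str, taxa: Sequence[str]) -> set[frozenset[str]]:
    """Canonical unrooted splits: each split keyed by the side not containing
    the alphabetically first taxon."""
    ref = min(taxa)
    t = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    all_taxa = frozenset(l.taxon.label for l in t.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(side)
    return out


def nj_tree_hky(
    alignment: CodonAlignment,
    n_bootstrap: int = 100,
    seed: int = 0,
    outgroup: Sequence[str] = (),
    kappa: float | None = None,
) -> AnnotatedTree:
    """Neighbour-joining on non-PBR HKY ML distances with bootstrap supports.

    Fallback for when no externally estimated tree is supplied.  Bootstrap
    resamples non-PBR nucleotide sites; supports are split frequencies in
    percent attached to internal branches.  Deterministic given ``seed``.
    """
    if len(alignment.names) < 4:
        raise TreeError("need at least 4 sequences for the NJ fallback")
    nonpbr_codons = alignment.nonpbr_codon_indices()
    positions = np.array(
        [3 * (c - 1) + k for c in nonpbr_codons for k in range(3)], dtype=int
    )
    dm, names, kappa_hat = hky_distance_matrix(alignment, positions, kappa)
    newick = _nj_newick(dm, names)
    split_counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    n_sites = positions.size
    for _ in range(n_bootstrap):
        w = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites)).astype(float)
        dm_b, _, _ = hky_distance_matrix(alignment, positions, kappa_hat, weights=w)
        for s in _splits(_nj_newick(dm_b, names), names):
            split_counts[s] = split_counts.get(s, 0) + 1
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    at = annotate_tree(
        tree,
        alignment,
        outgroup,
        branch_length_unit="per_site",
        nonpbr_sites=n_sites,
    )
    all_taxa = frozenset(names)
    ref = min(names)
    for bid, node in at.branches():
        if n_bootstrap <= 0 or not at.is_internal_branch(bid):
            continue
        side = frozenset(bid)
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            at.bootstrap[bid] = 100.0 * split_counts.get(side, 0) / n_bootstrap
    return at


# ---------------------------------------------------------------------------
# Fitch parsimony mapping
# ---------------------------------------------------------------------------


def _fitch_site(
    tree: dendropy.Tree, states: Mapping[str, str]
) -> tuple[int, list[tuple[dendropy.Node, str, str]]]:
    """One-site generalized Fitch with DELTRAN tie-break.

    ``states`` maps leaf label to a single character; characters outside the
    ordinary alphabet (gap, X, *) act as wildcards that never force events.
    Returns (event count, [(child node, from_state, to_state), ...]).
    """
    sets: dict[int, frozenset[str] | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            sets[id(node)] = None if s in ("-", "X", "*", "?") else frozenset(s)
        else:
            # majority-rule (Hartigan) state sets: exact for multifurcations,
            # identical to Fitch intersection/union on binary nodes
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            concrete = [c for c in child_sets if c is not None]
            if not concrete:
                sets[id(node)] = None
                continue
            counts: dict[str, int] = {}
            for cs in concrete:
                for s in cs:
                    counts[s] = counts.get(s, 0) + 1
            k = max(counts.values())
            sets[id(node)] = frozenset(s for s, c in counts.items() if c == k)
    events: list[tuple[dendropy.Node, str, str]] = []
    assign: dict[int, str | None] = {}
    root = tree.seed_node
    root_set = sets[id(root)]
    assign[id(root)] = min(root_set) if root_set else None
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assign[id(node.parent_node)]
        node_set = sets[id(node)]
        if node_set is None:
            assign[id(node)] = parent_state
            continue
        if parent_state is not None and parent_state in node_set:
            assign[id(node)] = parent_state
        else:
            new_state = min(node_set)
            assign[id(node)] = new_state
            if parent_state is not None:
                events.append((node, parent_state, new_state))
    return len(events), events


def fitch_site_score(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    """Parsimony score of one character on the tree (wildcards free)."""
    return _fitch_site(tree, states)[0]


def fitch_events(
    at: AnnotatedTree, char_strings: Mapping[str, str]
) -> dict[BranchId, list[tuple[int, str, str]]]:
    """Map every character column onto branches by Fitch/DELTRAN.

    ``char_strings`` maps each leaf label to an equal-length state string
    (amino acids, nucleotides, ...).  Site indices in the result are 1-based
    column positions within the supplied strings.
    """
    leaves = at.leaf_names()
    missing = [l for l in leaves if l not in char_strings]
    if missing:
        raise TreeError(f"no character string for leaves: {missing}")
    lengths = {len(char_strings[l]) for l in leaves}
    if len(lengths) != 1:
        raise TreeError("character strings differ in length")
    (n_sites,) = lengths
    out: dict[BranchId, list[tuple[int, str, str]]] = {}
    for site in range(n_sites):
        states = {l: char_strings[l][site] for l in leaves}
        if len({s for s in states.values() if s not in ("-", "X", "*", "?")}) <= 1:
            continue
        _, events = _fitch_site(at.tree, states)
        for node, frm, to in events:
            out.setdefault(at.branch_id(node), []).append((site + 1, frm, to))
    return out


def fitch_map(at: AnnotatedTree, pbr_aa: Mapping[str, str]) -> AnnotatedTree:
    """Place PBR amino-acid substitutions on the tree (in place, returned).

    ``pbr_aa`` maps each leaf to its amino-acid string over the PBR codons;
    site numbers in the stored events are 1-based positions within that
    string.  The per-site event total equals the Fitch parsimony score.
    """
    at.pbr_events = fitch_events(at, pbr_aa)
    return at


# ---------------------------------------------------------------------------
# JTT amino-acid ML distance
# ---------------------------------------------------------------------------

_jtt_model: _ReversibleModel | None = None


def _load_jtt() -> _ReversibleModel:
    global _jtt_model
    if _jtt_model is None:
        text = importlib.resources.files("pbrhet").joinpath("data", "jtt.tsv").read_text()
        rows = [
            [float(x) for x in line.split("\t")]
            for line in text.splitlines()
            if line and not line.startswith("#")
        ]
        s = np.zeros((20, 20))
        for i in range(1, 20):
            for j, v in enumerate(rows[i - 1]):
                s[i, j] = s[j, i] = v
        freqs = np.array(rows[19])
        freqs = freqs / freqs.sum()
        _jtt_model = _ReversibleModel(s, freqs)
    return _jtt_model


def jtt_pattern_counts(aa_a: str, aa_b: str) -> np.ndarray:
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    counts = np.zeros((20, 20))
    for x, y in zip(aa_a, aa_b):
        if x in idx and y in idx:
            counts[idx[x], idx[y]] += 1.0
    return counts


def jtt_distance(aa_a: str, aa_b: str, t_max: float = JTT_MAX_DISTANCE) -> float:
    """ML distance between two amino-acid strings under the JTT model.

    Expected substitutions per site; sites where either string is ambiguous
    are excluded.  Saturated pairs return ``t_max`` with a warning rather
    than failing.
    """
    if len(aa_a) != len(aa_b):
        raise ValueError("amino-acid strings differ in length")
    counts = jtt_pattern_counts(aa_a, aa_b)
    if counts.sum() == 0:
        raise ValueError("no comparable (unambiguous) sites")
    model = _load_jtt()
    d = model.ml_distance((counts + counts.T) / 2.0, t_max)
    if d >= t_max * 0.999:
        warnings.warn("JTT distance saturated; returning the documented cap")
        return t_max
    return d


# ---------------------------------------------------------------------------
# parallel substitutions
# ---------------------------------------------------------------------------


def nnls_branch_lengths(
    at: AnnotatedTree, dm: np.ndarray, names: Sequence[str]
) -> dict[BranchId, float]:
    """Branch lengths fitted to pairwise distances on the fixed topology.

    Unweighted least squares with non-negativity (the classical
    distance-fitting approach): solve ``A b ~ d`` where A is the pair-path
    incidence matrix.  Model-based distances (HKY, JTT) correct for multiple
    hits, so the fitted lengths do not saturate the way per-branch parsimony
    counts do on a short region.
    """
    from scipy.optimize import nnls

    order = list(names)
    idx = {n: i for i, n in enumerate(order)}
    branches = at.branches()
    bids = [b for b, _ in branches]
    bindex = {b: i for i, b in enumerate(bids)}
    node_by = {l.taxon.label: l for l in at.tree.leaf_node_iter()}
    anc: dict[str, set[int]] = {}
    for label in order:
        node = node_by[label]
        path = set()
        while node.parent_node is not None:
            path.add(bindex[at.branch_id(node)])
            node = node.parent_node
        anc[label] = path
    rows, d = [], []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            row = np.zeros(len(bids))
            row[list(anc[a] ^ anc[b])] = 1.0
            rows.append(row)
            d.append(dm[idx[a], idx[b]])
    sol, _ = nnls(np.vstack(rows), np.asarray(d))
    return {bid: float(v) for bid, v in zip(bids, sol)}


def jtt_branch_lengths(
    at: AnnotatedTree, pbr_aa: Mapping[str, str]
) -> dict[BranchId, float]:
    """Per-branch PBR amino-acid substitution counts from JTT distances.

    Pairwise JTT ML distances between the leaves' PBR strings are fitted to
    the fixed topology by non-negative least squares and converted to
    absolute substitution counts (length x number of PBR sites).
    """
    names = at.leaf_names()
    n_sites = len(pbr_aa[names[0]])
    dm = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            dm[i, j] = dm[j, i] = jtt_distance(pbr_aa[a], pbr_aa[names[j]])
    lengths = nnls_branch_lengths(at, dm, names)
    return {b: v * n_sites for b, v in lengths.items()}


@dataclass(frozen=True)
class ParallelSubstitution:
    """Identical amino-acid exchange at one site on two or more branches."""

    site: int
    exchange: frozenset[str]
    branches: tuple[BranchId, ...]


def parallel_census(at: AnnotatedTree) -> list[ParallelSubstitution]:
    """Group identical (site, unordered exchange) events on >= 2 branches."""
    groups: dict[tuple[int, frozenset[str]], list[BranchId]] = {}
    for bid, events in at.pbr_events.items():
        for site, frm, to in events:
            groups.setdefault((site, frozenset((frm, to))), []).append(bid)
    out = [
        ParallelSubstitution(site, exch, tuple(sorted(bids)))
        for (site, exch), bids in sorted(groups.items(), key=lambda kv: kv[0][0])
        if len(bids) >= 2
    ]
    return out


def parallel_phase_tally(
    at: AnnotatedTree,
    pair_phase: Mapping[frozenset[str], str],
) -> pd.DataFrame:
    """Per-phase counts of parallel exchanges seen along allele-pair paths.

    For each allele pair the path between the two leaves is collected and a
    parallel event is counted when the same (site, exchange) occurs on at
    least two distinct branches of that path.  Output: one row per phase with
    the summed count (Table-S2-style shape).
    """
    node_by_label = {
        l.taxon.label: l for l in at.tree.leaf_node_iter()
    }
    tally: dict[str, int] = {}
    for pair, phase in pair_phase.items():
        a, b = sorted(pair)
        path = _path_branches(at, node_by_label[a], node_by_label[b])
        seen: dict[tuple[int, frozenset[str]], int] = {}
        for bid in path:
            for site, frm, to in at.pbr_events.get(bid, []):
                key = (site, frozenset((frm, to)))
                seen[key] = seen.get(key, 0) + 1
        n_parallel = sum(1 for v in seen.values() if v >= 2)
        tally[phase] = tally.get(phase, 0) + n_parallel
    return pd.DataFrame(
        [{"phase": k, "parallel_count": v} for k, v in sorted(tally.items())]
    )


def _path_branches(at: AnnotatedTree, a: dendropy.Node, b: dendropy.Node) -> list[BranchId]:
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_set = {id(n) for n in anc_a}
    path_b = []
    node = b
    while id(node) not in anc_set:
        path_b.append(node)
        node = node.parent_node
    mrca = node
    path_a = []
    node = a
    while node is not mrca:
        path_a.append(node)
        node = node.parent_node
    return [at.branch_id(n) for n in path_a + path_b]


def write_events_tsv(at: AnnotatedTree, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"branch_id": "|".join(bid), "site": site, "from_aa": frm, "to_aa": to}
        for bid, events in sorted(at.pbr_events.items())
        for site, frm, to in events
    ]
    pd.DataFrame(rows, columns=["branch_id", "site", "from_aa", "to_aa"]).to_csv(
        outdir / "events.tsv", sep="\t", index=False
    )
    census = parallel_census(at)
    rows = [
        {
            "site": c.site,
            "exchange": "/".join(sorted(c.exchange)),
            "n_branches": len(c.branches),
            "branches": ";".join("|".join(b) for b in c.branches),
        }
        for c in census
    ]
    pd.DataFrame(
        rows, columns=["site", "exchange", "n_branches", "branches"]
    ).to_csv(outdir / "parallel.tsv", sep="\t", index=False)
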