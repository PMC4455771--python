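"""Synthetic codon alignments with the statistical structure of MHC data.

The generator emulates what the real analysis assumes about class II MHC
alleles: a deep allelic genealogy (divergences of the oldest pairs reach
tens of millions of years, i.e. several times the species-level coalescent),
separate substitution processes at PBR and non-PBR codons, a
transition/transversion proposal bias, branch-specific multipliers on the
PBR nonsynonymous rate, and optional splice-type recombinants.

PBR sites accept only nonsynonymous, non-stop changes (rejection sampling),
so the PBR event count per branch is the exact quantity the pipeline's
parsimony mapping tries to recover; synonymous changes at PBR codons are
deliberately absent, which slightly depresses K_S relative to real data and
is documented in the methods note.  Stop codons are never accepted anywhere.

Every accepted event is logged to a truth table (per-branch counts plus the
true tree with branch classes), so each pipeline stage can be scored against
ground truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .codon_alignment import GENETIC_CODE, CodonAlignment, PbrMask
from .tree_ops import AnnotatedTree, BranchId, annotate_tree

__all__ = [
    "SynthConfig",
    "TruthTable",
    "generate_genealogy",
    "evolve_alignment",
    "inject_recombinant",
    "choose_shift_branches",
    "default_pbr_mask_for",
    "generate_dataset",
]

_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
_PURINES = frozenset("AG")
_NTS = "ACGT"


def default_pbr_mask_for(n_codons: int, n_pbr: int = 27, spacing_seed: int = 7) -> PbrMask:
    """Evenly spread PBR mask used when no explicit mask is configured."""
    rng = np.random.default_rng(spacing_seed)
    idx = np.sort(rng.choice(np.arange(2, n_codons), size=n_pbr, replace=False)) + 0
    return PbrMask(tuple(int(i) for i in idx), provenance="synthetic-default")


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the DRB1 analysis scale: 56 alleles of 230 codons
    (~690 bp) with 27 PBR codons; a lineage-structured ("mhc") genealogy of
    8 deep allelic lineages whose stems carry most of the tree length, the
    shape balancing selection produces (plain Kingman and Yule genealogies
    are available as alternatives); non-PBR nucleotide rate and PBR
    nonsynonymous proposal rate chosen so deep pairs accumulate m of a few
    tens and K_B around 10-20, the ranges the real curve spans; kappa=2, a
    typical nuclear transition/transversion proposal bias.
    """

    n_alleles: int = 56
    n_codons: int = 230
    pbr_mask: PbrMask | None = None
    genealogy: str = "mhc"  # or "kingman", "yule"
    n_lineages: int = 8
    crown_frac: float = 0.15
    lineage_span: float = 2.5  # depth of the lineage-level genealogy, time units
    depth_scale: float = 1.0
    kappa: float = 2.0
    rate_nonpbr: float = 0.02  # substitutions / site / unit time
    # PBR proposal rate; ~70% of proposals are accepted (nonsynonymous,
    # non-stop), giving ~0.13 accepted events/site/unit.  Chosen so that
    # early pairs show K_B close to m, the ratio the real curve starts at.
    rate_pbr_nonsyn: float = 0.18
    branch_shifts: dict[BranchId, float] = field(default_factory=dict)
    recombinants: tuple[tuple[str, str, tuple[int, int]], ...] = ()
    seed: int = 0

    def mask(self) -> PbrMask:
        return self.pbr_mask or default_pbr_mask_for(self.n_codons)


@dataclass
class TruthTable:
    """Ground truth emitted alongside a synthetic alignment."""

    true_tree: AnnotatedTree
    branch_counts: pd.DataFrame  # branch_id, pbr_nonsyn, nonpbr_nonsyn, nonpbr_syn
    pbr_events: dict[BranchId, list[tuple[int, str, str]]]
    branch_shifts: dict[BranchId, float]
    recombinant_alleles: list[str] = field(default_factory=list)

    def shifted_branches(self) -> dict[BranchId, float]:
        return {b: m for b, m in self.branch_shifts.items() if m != 1.0}


def _allele_names(n: int) -> list[str]:
    return [f"AL{i:03d}" for i in range(1, n + 1)]


def generate_genealogy(config: SynthConfig) -> AnnotatedTree:
    """Random genealogy under the Kingman coalescent or a Yule process.

    Branch lengths are in the model's own time units, multiplied by
    ``depth_scale``; deterministic given ``config.seed``.
    """
    if config.n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    rng = np.random.default_rng(config.seed)
    names = _allele_names(config.n_alleles)
    if config.genealogy == "kingman":
        newick = _kingman_newick(names, rng, config.depth_scale)
    elif config.genealogy == "yule":
        newick = _yule_newick(names, rng, config.depth_scale)
    elif config.genealogy == "mhc":
        newick = _mhc_newick(
            names, rng, config.depth_scale, config.n_lineages, config.crown_frac,
            config.lineage_span,
        )
    else:
        raise ValueError(f"unknown genealogy model {config.genealogy!r}")
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return annotate_tree(tree, branch_length_unit="time")


def _coalesce(names: Sequence[str], rng: np.random.Generator):
    """Kingman coalescent merge structure: nested ((children...), height) with
    leaves (name, 0.0); returns (root_node, tmrca) in coalescent units."""
    nodes: list[tuple] = [(n, 0.0) for n in names]
    k = len(nodes)
    t = 0.0
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, b), t))
        k -= 1
    return nodes[0], t


def _even_spaced_merge(names: Sequence[str], rng: np.random.Generator, depth: float):
    """Random merge order with merge times evenly spaced up to ``depth``."""
    nodes: list[tuple] = [(n, 0.0) for n in names]
    k = len(nodes)
    times = np.linspace(depth / (k - 1), depth, k - 1) if k > 1 else []
    for t in times:
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, b), float(t)))
        k -= 1
    return nodes[0], float(depth)


def _write_node(node, parent_h: float, scale: float) -> str:
    sub, h = node
    if isinstance(sub, str):
        return f"{sub}:{(parent_h - h) * scale:.10g}"
    inner = ",".join(_write_node(c, h, scale) for c in sub)
    return f"({inner}):{(parent_h - h) * scale:.10g}"


def _kingman_newick(names: list[str], rng: np.random.Generator, scale: float) -> str:
    root, h = _coalesce(names, rng)
    if isinstance(root[0], str):
        return f"({root[0]}:0);"
    body = ",".join(_write_node(c, h, scale) for c in root[0])
    return f"({body});"


def _mhc_newick(
    names: list[str],
    rng: np.random.Generator,
    scale: float,
    n_lineages: int,
    crown_frac: float,
    lineage_span: float = 2.5,
) -> str:
    """Lineage-structured allelic genealogy.

    Deep allelic lineages persist through speciations under balancing
    selection, which both stretches the genealogy and spaces lineage
    coalescences roughly evenly through time instead of piling them near the
    present.  The model therefore merges the L lineages at evenly spaced
    times up to a fixed deep span (2.5 time units x depth_scale, i.e. tens
    of millions of years at MHC rates) with a random merge order, and crowns
    each lineage with a shallow Kingman cluster of depth crown_frac x its
    attachment time.  Stems carry the bulk of the tree length, as in real
    MHC genealogies.
    """
    n = len(names)
    L = max(2, min(n_lineages, n))
    sizes = [n // L + (1 if i < n % L else 0) for i in range(L)]
    groups: list[list[str]] = []
    k = 0
    for s in sizes:
        groups.append(names[k : k + s])
        k += s
    ltree, lh = _even_spaced_merge([f"@{i}" for i in range(L)], rng, depth=lineage_span)

    def write(node, parent_h: float) -> str:
        sub, h = node
        if isinstance(sub, str):
            group = groups[int(sub[1:])]
            if len(group) == 1:
                return f"{group[0]}:{parent_h * scale:.10g}"
            dc = crown_frac * parent_h
            cstruct, ct = _coalesce(group, rng)
            cscale = scale * dc / ct
            if isinstance(cstruct[0], str):
                inner = f"{cstruct[0]}:{dc * scale:.10g}"
            else:
                inner = ",".join(_write_node(c, ct, cscale) for c in cstruct[0])
            return f"({inner}):{(parent_h - dc) * scale:.10g}"
        inner = ",".join(write(c, h) for c in sub)
        return f"({inner}):{(parent_h - h) * scale:.10g}"

    body = ",".join(write(c, lh) for c in ltree[0])
    return f"({body});"


def _yule_newick(names: list[str], rng: np.random.Generator, scale: float) -> str:
    # grow forward in time at birth rate 1 per lineage until n tips
    n = len(names)
    split_times = [0.0]
    t = 0.0
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    depth = t + rng.exponential(1.0 / n)  # run a little past the last split
    # build by sequential random attachment consistent with split times
    class _N:
        __slots__ = ("children", "time", "name")

        def __init__(self, time, name=None):
            self.children: list[_N] = []
            self.time = time
            self.name = name

    root = _N(0.0)
    tips = [root]
    for k in range(1, n):
        idx = int(rng.integers(len(tips)))
        node = tips.pop(idx)
        node.time = split_times[k]
        c1, c2 = _N(depth), _N(depth)
        node.children = [c1, c2]
        tips += [c1, c2]
    order = list(rng.permutation(n))
    it = iter(order)

    def write(node: _N, parent_time: float) -> str:
        if not node.children:
            name = names[next(it)]
            return f"{name}:{(depth - parent_time) * scale:.10g}"
        inner = ",".join(write(c, node.time) for c in node.children)
        return f"({inner}):{(node.time - parent_time) * scale:.10g}"

    body = ",".join(write(c, 0.0) for c in root.children)
    return f"({body});"


def _propose_nt(current: str, rng: np.random.Generator, kappa: float) -> str:
    weights = []
    targets = []
    for nt in _NTS:
        if nt == current:
            continue
        transition = (nt in _PURINES) == (current in _PURINES)
        weights.append(kappa if transition else 1.0)
        targets.append(nt)
    w = np.array(weights) / sum(weights)
    return targets[int(rng.choice(3, p=w))]


def evolve_alignment(
    tree: AnnotatedTree, config: SynthConfig
) -> tuple[CodonAlignment, TruthTable]:
    """Evolve sequences down the genealogy and log every accepted event.

    Non-PBR sites take any non-stop nucleotide change at ``rate_nonpbr``;
    PBR sites propose changes at ``rate_pbr_nonsyn`` (times the branch's
    multiplier) and accept only nonsynonymous non-stop ones.  Proposal
    targets are kappa-biased toward transitions.
    """
    rng = np.random.default_rng(config.seed + 1)
    mask = config.mask()
    pbr_set = mask.as_set()
    n_nt = 3 * config.n_codons
    pbr_positions = np.array(
        [3 * (c - 1) + k for c in sorted(pbr_set) for k in range(3)], dtype=int
    )
    nonpbr_positions = np.setdiff1d(np.arange(n_nt), pbr_positions)
    root_seq = list("".join(rng.choice(_SENSE_CODONS) for _ in range(config.n_codons)))

    records: dict[str, str] = {}
    branch_rows = []
    pbr_events: dict[BranchId, list[tuple[int, str, str]]] = {}
    pbr_index = {c: i + 1 for i, c in enumerate(sorted(pbr_set))}

    def codon_of(seq: list[str], pos: int) -> tuple[int, str]:
        ci = pos // 3
        return ci, "".join(seq[3 * ci : 3 * ci + 3])

    def evolve_branch(seq: list[str], bid: BranchId, length: float) -> list[str]:
        seq = seq[:]
        mult = config.branch_shifts.get(bid, 1.0)
        counts = {"pbr_nonsyn": 0, "nonpbr_nonsyn": 0, "nonpbr_syn": 0}
        n_np = rng.poisson(config.rate_nonpbr * nonpbr_positions.size * length)
        n_pb = rng.poisson(config.rate_pbr_nonsyn * mult * pbr_positions.size * length)
        jobs = [("nonpbr", int(p)) for p in rng.choice(nonpbr_positions, size=n_np)] + [
            ("pbr", int(p)) for p in rng.choice(pbr_positions, size=n_pb)
        ] if (n_np or n_pb) else []
        rng.shuffle(jobs)
        for region, pos in jobs:
            ci, old_codon = codon_of(seq, pos)
            new_nt = _propose_nt(seq[pos], rng, config.kappa)
            off = pos - 3 * ci
            new_codon = old_codon[:off] + new_nt + old_codon[off + 1 :]
            aa_old, aa_new = GENETIC_CODE[old_codon], GENETIC_CODE[new_codon]
            if aa_new == "*":
                continue
            if region == "pbr":
                if aa_new == aa_old:
                    continue  # PBR process is nonsynonymous-only
                counts["pbr_nonsyn"] += 1
                pbr_events.setdefault(bid, []).append(
                    (pbr_index[ci + 1], aa_old, aa_new)
                )
            else:
                counts["nonpbr_syn" if aa_new == aa_old else "nonpbr_nonsyn"] += 1
            seq[pos] = new_nt
        branch_rows.append({"branch_id": "|".join(bid), **counts})
        return seq

    seqs_at: dict[int, list[str]] = {id(tree.tree.seed_node): root_seq}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs_at[id(node.parent_node)]
        bid = tree.branch_id(node)
        seqs_at[id(node)] = evolve_branch(parent_seq, bid, node.edge.length or 0.0)
        if node.is_leaf():
            records[node.taxon.label] = "".join(seqs_at[id(node)])

    alignment = CodonAlignment(records, mask)
    truth = TruthTable(
        tree,
        pd.DataFrame(branch_rows),
        pbr_events,
        {bid: m for bid, m in config.branch_shifts.items()},
    )
    for bid, m in truth.branch_shifts.items():
        tree.branch_class[bid] = "slow" if m < 1 else ("fast" if m > 1 else "normal")
    for acceptor, donor, region in config.recombinants:
        alignment = inject_recombinant(alignment, acceptor, donor, region)
        truth.recombinant_alleles.append(acceptor)
    return alignment, truth


def inject_recombinant(
    alignment: CodonAlignment,
    acceptor: str,
    donor: str,
    region: tuple[int, int],
) -> CodonAlignment:
    """Replace the acceptor's codons [start, end] (1-based, inclusive) by the
    donor's, emulating a splice recombinant."""
    for name in (acceptor, donor):
        if name not in alignment.records:
            raise KeyError(f"unknown allele {name!r}")
    start, end = region
    if not (1 <= start <= end <= alignment.n_codons):
        raise ValueError(f"region {region} outside alignment of {alignment.n_codons} codons")
    records = dict(alignment.records)
    a, d = records[acceptor], records[donor]
    lo, hi = 3 * (start - 1), 3 * end
    records[acceptor] = a[:lo] + d[lo:hi] + a[hi:]
    return CodonAlignment(records, alignment.pbr_mask, alignment.region_bounds)


def choose_shift_branches(
    tree: AnnotatedTree,
    n: int,
    seed: int = 0,
    min_clade: int = 3,
    max_clade_frac: float = 0.5,
    by: str = "clade",
) -> list[BranchId]:
    """Pick internal mid-depth branches to rate-shift, non-nested.

    ``by="clade"`` prefers the largest subtended clades (stems of major
    allelic lineages, the configuration behind the observed plateau);
    ``by="length"`` prefers the longest stems, where a rate shift leaves the
    clearest signal in the branch regression.
    """
    n_leaves = len(tree.leaf_names())
    lengths = tree.branch_lengths()
    rng = np.random.default_rng(seed)
    candidates = [
        bid
        for bid, node in tree.branches()
        if min_clade <= len(bid) <= int(max_clade_frac * n_leaves)
    ]
    if by == "length":
        # long stems carry the clearest signal for rate-shift detection
        candidates.sort(key=lambda b: -lengths[b])
        order = candidates
    elif by == "mid-depth":
        # stems whose midpoint sits at intermediate height: slowing them
        # depresses pairs of intermediate divergence (a mid-range plateau)
        node_of = {bid: node for bid, node in tree.branches()}
        height = max(
            l.distance_from_root() for l in tree.tree.leaf_node_iter()
        )
        mids = {}
        for bid in candidates:
            node = node_of[bid]
            top = node.distance_from_root()
            mids[bid] = height - (top - (node.edge.length or 0.0) / 2.0)
        order = [
            b for b in candidates if 0.25 <= mids[b] / height <= 0.65
        ]
        order.sort(key=lambda b: -lengths[b])
        order += [b for b in candidates if b not in order]
    else:
        candidates.sort(key=lambda b: -len(b))
        order = candidates
    picked: list[BranchId] = []
    for bid in order:
        if len(picked) >= n:
            break
        if all(not (set(bid) <= set(p) or set(p) <= set(bid)) for p in picked):
            picked.append(bid)
    if len(picked) < n:
        rest = [b for b in order if b not in picked]
        while len(picked) < n and rest:
            picked.append(rest.pop(int(rng.integers(len(rest)))))
    return picked


def generate_dataset(
    config: SynthConfig,
) -> tuple[CodonAlignment, TruthTable]:
    """Genealogy plus evolved alignment in one call (synth CLI entry point)."""
    tree = generate_genealogy(config)
    return evolve_alignment(tree, config)


def write_truth(truth: TruthTable, alignment: CodonAlignment, outdir: str | Path) -> None:
    from .codon_alignment import write_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(alignment, outdir / "synthetic.fasta")
    (outdir / "true_tree.nwk").write_text(truth.true_tree.as_newick() + "\n")
    truth.branch_counts.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if truth.recombinant_alleles:
        (outdir / "recombinants.txt").write_text(
            "".join(f"{n}\n" for n in truth.recombinant_alleles)
        )
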