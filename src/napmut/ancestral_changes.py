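"""Ancestral state reconstruction and high-confidence change calling.

Given a multiple genome alignment of closely related strains, a rooted
phylogeny with bootstrap supports, and a substitution model, this module
reconstructs per-site marginal ancestral state posteriors (Felsenstein
pruning plus an outside pass, the standard empirical-Bayes marginal
reconstruction) and calls a conservative set of single-nucleotide changes
using three filters:

(a) parsimony: only a single event is needed to explain the column
    (Fitch/Hartigan count equals 1),
(b) the ancestral node of the implicated branch has posterior probability
    >= 0.9 for the ancestral base,
(c) the inference does not depend on poorly supported topology: all nodes
    with bootstrap support below 98 are collapsed into polytomies and the
    change is kept only if the event count and the implicated branch are
    unchanged on the collapsed tree.

Alignment columns enter the analysis only if no strain (including the
outgroup) carries a gap or ambiguity and the column does not overlap the
genome uniqueness mask (regions whose 300 nt windows map to a second
genomic locale at <= 2 mismatches, mirroring the unique-mapping requirement
of the ChIP-Seq binding calls).  A column is polymorphic only if it varies
within the ingroup; columns where only the outgroup differs are counted in
the at-risk census but yield no change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


class DataError(ValueError):
    pass


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=0.0, support=None):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and internal-node bootstrap supports."""

    def __init__(self, root: TreeNode, outgroup: str = "outgroup"):
        self.root = root
        self.outgroup = outgroup
        self._name_internal_nodes()

    # -- construction ------------------------------------------------------
    def _name_internal_nodes(self):
        for i, node in enumerate(self.postorder()):
            if not node.is_leaf and node.name is None:
                node.name = f"node{i}"

    @classmethod
    def from_newick(cls, newick: str, outgroup: str = "outgroup") -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(dnode):
            name = dnode.taxon.label if dnode.taxon else None
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    name = name or dnode.label
            node = TreeNode(name=name, length=dnode.edge.length or 0.0, support=support)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(tree.seed_node), outgroup=outgroup)

    def to_newick(self) -> str:
        """Deterministic newick with supports as internal-node labels."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    @property
    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self):
        return [n.name for n in self.leaves]

    @property
    def internal_nodes(self):
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def leafsets(self) -> dict:
        """Map node -> frozenset of descendant leaf names (computed fresh)."""
        sets = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.name])
            else:
                acc = frozenset()
                for c in node.children:
                    acc |= sets[c]
                sets[node] = acc
        return sets

    def collapse_low_support(self, threshold: float) -> "Phylogeny":
        """Copy of the tree with internal nodes of support < threshold
        collapsed into their parent (branch length absorbed by children)."""

        def copy_into(src: TreeNode, dst_parent: TreeNode | None, extra_len=0.0):
            node = TreeNode(src.name, src.length + extra_len, src.support)
            if dst_parent is None:
                new_root = node
            else:
                dst_parent.add_child(node)
                new_root = None
            for child in src.children:
                collapse = (
                    not child.is_leaf
                    and child.support is not None
                    and child.support < threshold
                )
                if collapse:
                    # graft grandchildren straight onto `node`
                    for gc in child.children:
                        copy_collapsed(gc, node, child.length)
                else:
                    copy_into(child, node)
            return new_root

        def copy_collapsed(src: TreeNode, dst_parent: TreeNode, extra_len: float):
            collapse = (
                not src.is_leaf and src.support is not None and src.support < threshold
            )
            if collapse:
                for gc in src.children:
                    copy_collapsed(gc, dst_parent, extra_len + src.length)
            else:
                copy_into(src, dst_parent, extra_len)

        new_root = copy_into(self.root, None)
        return Phylogeny(new_root, outgroup=self.outgroup)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentBlock:
    """One locally collinear block: equal-length aligned sequences with a
    reference-coordinate anchor (0-based half-open on the reference)."""

    ref_start: int
    sequences: dict  # strain -> str

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise DataError(f"block at {self.ref_start}: unequal sequence lengths")
        self.length = lengths.pop()

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length


class StrainAlignment:
    """Per-strain aligned blocks plus the outgroup identifier."""

    def __init__(self, blocks, outgroup: str = "outgroup", reference: str | None = None):
        self.blocks = sorted(blocks, key=lambda b: b.ref_start)
        starts = [b.ref_start for b in self.blocks]
        if sorted(set(starts)) != starts:
            raise DataError("block reference coordinates must be strictly increasing")
        strain_sets = {frozenset(b.sequences) for b in self.blocks}
        if len(strain_sets) > 1:
            missing = set.union(*map(set, strain_sets)) - set.intersection(*map(set, strain_sets))
            raise DataError(f"strains missing from some blocks: {sorted(missing)}")
        self.strains = sorted(self.blocks[0].sequences)
        self.outgroup = outgroup
        if outgroup not in self.strains:
            raise DataError(f"outgroup {outgroup!r} absent from alignment")
        self.ingroup = [s for s in self.strains if s != outgroup]
        self.reference = reference if reference is not None else self.ingroup[0]

    def codes(self, block: AlignmentBlock, strain_order) -> np.ndarray:
        """(n_strains, block_length) int8 matrix; non-ACGT -> -1."""
        lut = np.full(256, -1, dtype=np.int8)
        for b, i in BASE_CODE.items():
            lut[ord(b)] = i
            lut[ord(b.lower())] = i
        return np.vstack(
            [lut[np.frombuffer(block.sequences[s].encode(), dtype=np.uint8)] for s in strain_order]
        )

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq("".join(b.sequences[s] for b in self.blocks)), id=s, description="")
            for s in self.strains
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_block_index(self, path) -> None:
        pd.DataFrame(
            {"ref_start": [b.ref_start for b in self.blocks],
             "ref_end": [b.ref_end for b in self.blocks]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fasta(cls, fasta_path, block_index=None, outgroup="outgroup", reference=None):
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        if block_index is None:
            blocks = [AlignmentBlock(0, seqs)]
        else:
            idx = pd.read_csv(block_index, sep="\t")
            blocks, offset = [], 0
            for _, row in idx.iterrows():
                n = int(row.ref_end) - int(row.ref_start)
                blocks.append(
                    AlignmentBlock(int(row.ref_start), {s: q[offset:offset + n] for s, q in seqs.items()})
                )
                offset += n
        return cls(blocks, outgroup=outgroup, reference=reference)


# ---------------------------------------------------------------------------
# Uniqueness mask
# ---------------------------------------------------------------------------


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def compute_uniqueness_mask(
    sequence: str, window: int = 300, step: int = 10, max_mismatch: int = 2
) -> np.ndarray:
    """Non-unique regions by in-silico digestion and self-mapping.

    The genome is cut into overlapping windows (default 300 nt, offset 10 nt)
    and each window is mapped back against the genome on both strands
    allowing up to `max_mismatch` mismatches.  A window that hits a second
    locale is non-unique; the union of such window spans is returned as an
    (n, 2) array of merged 0-based half-open intervals.

    Candidate locales are found exactly by pigeonhole seeding: any match with
    <= k mismatches must contain one of k+1 equal slices of the window as an
    exact substring, so exact seed lookup plus Hamming verification misses
    nothing.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if window > n:
        raise InvalidParameterError("window longer than sequence")
    n_seg = max_mismatch + 1
    seg_len = window // n_seg

    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_CODE.items():
        lut[ord(b)] = i
    genome = lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]

    index: dict[str, list] = {}
    for pos in range(0, n - seg_len + 1):
        index.setdefault(sequence[pos:pos + seg_len], []).append(pos)

    rc_all = _revcomp(sequence)
    hits = []
    for i in range(0, n - window + 1, step):
        win = genome[i:i + window]
        win_fwd = sequence[i:i + window]
        win_rc = rc_all[n - window - i:n - i]  # reverse complement of the window
        found = False
        candidates: set[tuple[str, int]] = set()
        for s in range(n_seg):
            off = s * seg_len
            for pos in index.get(win_fwd[off:off + seg_len], ()):
                j = pos - off
                if 0 <= j <= n - window and j != i:
                    candidates.add(("+", j))
            for pos in index.get(win_rc[off:off + seg_len], ()):
                j = pos - off
                if 0 <= j <= n - window and j != i:
                    candidates.add(("-", j))
        for strand, j in candidates:
            target = genome[j:j + window]
            query = win if strand == "+" else lut[np.frombuffer(win_rc.encode(), np.uint8)]
            if int(np.count_nonzero(target != query)) <= max_mismatch:
                found = True
                break
        if found:
            hits.append((i, i + window))
    from .binding_profiles import merge_intervals

    return merge_intervals(hits)


# ---------------------------------------------------------------------------
# Analyzable sites
# ---------------------------------------------------------------------------


@dataclass
class AnalyzableSites:
    """Census of gap-free, unmasked alignment columns.

    `census` has one row per retained site (position, reference base,
    polymorphic flag); `states` holds the leaf state codes of the
    polymorphic columns (n_polymorphic, n_strains) in `strain_order`.
    """

    census: pd.DataFrame
    states: np.ndarray
    strain_order: list

    @property
    def polymorphic_positions(self) -> np.ndarray:
        return self.census.loc[self.census.polymorphic, "position"].to_numpy()


def extract_analyzable_sites(alignment: StrainAlignment, mask=None) -> AnalyzableSites:
    """Apply the gap, uniqueness-mask and ingroup-polymorphism filters.

    Retained columns (no gap/ambiguity in any strain including the outgroup,
    outside the mask) form the at-risk census; those varying within the
    ingroup are additionally flagged polymorphic and their leaf states kept.
    Columns where only the outgroup differs stay in the census but are not
    polymorphic.
    """
    strain_order = alignment.ingroup + [alignment.outgroup]
    ref_idx = strain_order.index(alignment.reference)
    masked = None
    if mask is not None and len(mask):
        mask = np.asarray(mask).reshape(-1, 2)

    pos_all, ref_all, poly_all, state_cols = [], [], [], []
    for block in alignment.blocks:
        codes = alignment.codes(block, strain_order)
        ok = (codes >= 0).all(axis=0)
        positions = block.ref_start + np.arange(block.length)
        if mask is not None and len(mask):
            in_mask = np.zeros(block.length, dtype=bool)
            for s, e in mask:
                lo = max(int(s) - block.ref_start, 0)
                hi = min(int(e) - block.ref_start, block.length)
                if hi > lo:
                    in_mask[lo:hi] = True
            ok &= ~in_mask
        ingroup_codes = codes[:-1]
        poly = ok & (ingroup_codes != ingroup_codes[0]).any(axis=0)
        pos_all.append(positions[ok])
        ref_all.append(codes[ref_idx][ok])
        poly_all.append(poly[ok])
        if poly.any():
            state_cols.append(codes[:, poly].T)

    census = pd.DataFrame(
        {
            "position": np.concatenate(pos_all),
            "ref_base": [BASES[c] for c in np.concatenate(ref_all)],
            "polymorphic": np.concatenate(poly_all),
        }
    )
    states = (
        np.vstack(state_cols) if state_cols else np.empty((0, len(strain_order)), np.int8)
    )
    return AnalyzableSites(census=census, states=states, strain_order=strain_order)


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionModel:
    """Time-reversible nucleotide model: rate matrix Q (rows sum to zero,
    scaled to one expected substitution per unit branch length) and
    stationary frequencies."""

    name: str
    freqs: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.Q = np.asarray(self.Q, float)
        if not np.isclose(self.freqs.sum(), 1.0):
            raise InvalidParameterError("frequencies must sum to 1")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-9):
            raise InvalidParameterError("rate matrix rows must sum to 0")
        if (self.Q - np.diag(np.diag(self.Q)) < -1e-12).any():
            raise InvalidParameterError("off-diagonal rates must be non-negative")

    def transition_matrix(self, t: float) -> np.ndarray:
        return expm(self.Q * max(t, 0.0))


def _build_gtr(freqs, exchangeabilities) -> np.ndarray:
    freqs = np.asarray(freqs, float)
    Q = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(i + 1, 4):
            Q[i, j] = exchangeabilities[k] * freqs[j]
            Q[j, i] = exchangeabilities[k] * freqs[i]
            k += 1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(freqs * np.diag(Q)).sum()
    return Q / scale


def jc_model() -> SubstitutionModel:
    return SubstitutionModel("JC", np.full(4, 0.25), _build_gtr(np.full(4, 0.25), [1] * 6))


def k80_model(kappa: float = 2.0) -> SubstitutionModel:
    return hky_model(np.full(4, 0.25), kappa, name="K80")


def hky_model(freqs, kappa: float, name: str = "HKY") -> SubstitutionModel:
    # exchangeability order: AC, AG, AT, CG, CT, GT; AG and CT are transitions
    ex = [1.0, kappa, 1.0, 1.0, kappa, 1.0]
    return SubstitutionModel(name, freqs, _build_gtr(freqs, ex))


def gtr_model(freqs, exchangeabilities) -> SubstitutionModel:
    return SubstitutionModel("GTR", freqs, _build_gtr(freqs, exchangeabilities))


def estimate_hky(sites: AnalyzableSites) -> SubstitutionModel:
    """HKY with empirical base frequencies and a method-of-moments kappa.

    kappa is chosen so the instantaneous transition:transversion flux ratio,
    2*kappa*(pi_A pi_G + pi_C pi_T) : 2*(pi_A+pi_G)(pi_C+pi_T)-ish weights,
    matches the observed ratio of transition to transversion differences in
    pairwise leaf comparisons of the polymorphic columns.
    """
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_CODE.items():
        lut[ord(b)] = i
    ref_codes = lut[np.frombuffer("".join(sites.census.ref_base).encode(), np.uint8)]
    counts = np.bincount(ref_codes, minlength=4).astype(float)
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    freqs = np.clip(freqs, 1e-6, None)
    freqs /= freqs.sum()

    ts = tv = 0
    states = sites.states
    for a in range(states.shape[1]):
        for b in range(a + 1, states.shape[1]):
            diff = states[:, a] != states[:, b]
            for i, j in zip(states[diff, a], states[diff, b]):
                if (int(i), int(j)) in _TRANSITION_PAIRS:
                    ts += 1
                else:
                    tv += 1
    ts_weight = freqs[0] * freqs[2] + freqs[1] * freqs[3]
    tv_weight = (
        freqs[0] * freqs[1] + freqs[0] * freqs[3] + freqs[1] * freqs[2] + freqs[2] * freqs[3]
    )
    if tv == 0 or ts == 0 or ts_weight == 0:
        kappa = 2.0
    else:
        kappa = (ts / tv) * (tv_weight / ts_weight)
    return hky_model(freqs, float(np.clip(kappa, 0.05, 100.0)))


# ---------------------------------------------------------------------------
# Marginal ancestral reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralReconstruction:
    """Per-site, per-internal-node marginal posteriors over {A,C,G,T}."""

    positions: np.ndarray
    node_names: list
    posteriors: np.ndarray  # (n_internal_nodes, n_sites, 4)
    leaf_states: np.ndarray  # (n_sites, n_leaves)
    leaf_order: list
    model: SubstitutionModel

    def posterior(self, node_name: str) -> np.ndarray:
        return self.posteriors[self.node_names.index(node_name)]


def marginal_ancestral_reconstruction(
    sites: AnalyzableSites, tree: Phylogeny, model: SubstitutionModel | None = None
) -> AncestralReconstruction:
    """Exact marginal posteriors at every internal node for every
    polymorphic column, by the pruning (inside) and outside recursions.

    Missing leaf states (code -1) contribute a flat partial likelihood.
    """
    if model is None:
        model = estimate_hky(sites)
    leaf_names = set(tree.leaf_names)
    strains = set(sites.strain_order)
    if leaf_names != strains:
        raise DataError(
            f"tree leaves and alignment strains differ: {sorted(leaf_names ^ strains)}"
        )

    states = sites.states  # (n_sites, n_strains)
    n_sites = states.shape[0]
    col_of = {s: i for i, s in enumerate(sites.strain_order)}

    post_nodes = tree.postorder()
    P = {
        node: model.transition_matrix(node.length)
        for node in post_nodes
        if node.parent is not None
    }

    inside = {}   # node -> (n_sites, 4) conditional likelihood of subtree
    message = {}  # node -> (n_sites, 4) inside message to the parent
    for node in post_nodes:
        if node.is_leaf:
            codes = states[:, col_of[node.name]]
            L = np.zeros((n_sites, 4))
            known = codes >= 0
            L[known, codes[known]] = 1.0
            L[~known] = 1.0
        else:
            L = np.ones((n_sites, 4))
            for child in node.children:
                L = L * message[child]
            # per-site rescale to dodge underflow; posteriors are scale-free
            scale = L.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            L = L / scale
        inside[node] = L
        if node.parent is not None:
            message[node] = L @ P[node].T

    outside = {tree.root: np.broadcast_to(model.freqs, (n_sites, 4)).copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for child in node.children:
            T = outside[node].copy()
            for sib in node.children:
                if sib is not child:
                    T = T * message[sib]
            O = T @ P[child]
            scale = O.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            outside[child] = O / scale

    internal = [n for n in post_nodes if not n.is_leaf]
    posteriors = np.empty((len(internal), n_sites, 4))
    for k, node in enumerate(internal):
        joint = outside[node] * inside[node]
        total = joint.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        posteriors[k] = joint / total

    return AncestralReconstruction(
        positions=sites.polymorphic_positions,
        node_names=[n.name for n in internal],
        posteriors=posteriors,
        leaf_states=states,
        leaf_order=list(sites.strain_order),
        model=model,
    )


def enumerate_ancestral_posteriors(
    tree: Phylogeny, leaf_states: dict, model: SubstitutionModel
) -> dict:
    """Brute-force marginal posteriors by summing over every assignment of
    states to internal nodes.  Exponential in the number of internal nodes;
    used as an independent oracle for small trees."""
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    P = {n: model.transition_matrix(n.length) for n in nodes if n.parent is not None}
    totals = {n: np.zeros(4) for n in internal}
    grand = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        states = {n: s for n, s in zip(internal, assign)}
        states.update({n: leaf_states[n.name] for n in nodes if n.is_leaf})
        lik = model.freqs[states[tree.root]]
        for n in nodes:
            if n.parent is not None:
                lik *= P[n][states[n.parent], states[n]]
        grand += lik
        for n in internal:
            totals[n][states[n]] += lik
    return {n.name: totals[n] / grand for n in internal}


# ---------------------------------------------------------------------------
# Parsimony and change calling
# ---------------------------------------------------------------------------


def hartigan_count(tree: Phylogeny, leaf_state: dict) -> int:
    """Minimum number of state changes on a rooted (possibly multifurcating)
    tree, by Hartigan's generalisation of Fitch counting.  Leaves with
    missing state (None/-1) are ignored."""
    cost = 0
    upper: dict[TreeNode, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = leaf_state.get(node.name)
            upper[node] = frozenset() if s is None or s < 0 else frozenset([s])
        else:
            counts = np.zeros(4, dtype=int)
            n_informative = 0
            for c in node.children:
                if upper[c]:
                    n_informative += 1
                    for s in upper[c]:
                        counts[s] += 1
            if n_informative == 0:
                upper[node] = frozenset()
                continue
            m = counts.max()
            upper[node] = frozenset(np.flatnonzero(counts == m).tolist())
            cost += n_informative - int(m)
    return cost


@dataclass
class ChangeSet:
    """High-confidence single-nucleotide changes (ancestral -> derived)."""

    table: pd.DataFrame

    COLUMNS = (
        "position", "from_base", "to_base", "branch",
        "posterior", "fitch_count", "min_support",
    )

    def __len__(self):
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChangeSet":
        return cls(pd.read_csv(path, sep="\t"))


def _single_event_branch(tree: Phylogeny, leafsets: dict, leaf_state: dict, outgroup: str):
    """Locate the branch carrying the single event of a two-state column.

    Returns (clade_node, ancestral_code, derived_code) or None when the
    attribution is ambiguous (event could sit on either side of the root).
    """
    observed = {}
    for name, s in leaf_state.items():
        if s is not None and s >= 0:
            observed.setdefault(s, set()).add(name)
    if len(observed) != 2:
        return None
    (s1, set1), (s2, set2) = observed.items()
    node_of = {ls: n for n, ls in leafsets.items()}
    candidates = []
    for derived, dset, anc in ((s1, set1, s2), (s2, set2, s1)):
        node = node_of.get(frozenset(dset))
        if node is not None and node.parent is not None:
            candidates.append((node, anc, derived))
    if not candidates:
        return None
    if len(candidates) == 2:
        # both state classes are clades: the two children of the root.  Keep
        # the one not containing the outgroup (ancestral state polarised by
        # the outgroup); discard if the outgroup cannot polarise.
        candidates = [
            (n, a, d) for (n, a, d) in candidates if outgroup not in leafsets[n]
        ]
        if len(candidates) != 1:
            return None
    return candidates[0]


def call_high_confidence_changes(
    reconstruction: AncestralReconstruction,
    tree: Phylogeny,
    support_threshold: float = 98.0,
    posterior_threshold: float = 0.9,
) -> ChangeSet:
    """Apply the single-event, posterior and bootstrap-support filters.

    For every polymorphic column: the Hartigan event count must be exactly 1
    (filter a); the event branch must be unambiguous; the marginal posterior
    of the ancestral base at the node above the event branch must reach
    `posterior_threshold` (filter b); and on a copy of the tree with all
    nodes of support < `support_threshold` collapsed into polytomies the
    count must remain 1 with the same derived clade present (filter c).
    """
    leaf_order = reconstruction.leaf_order
    collapsed = tree.collapse_low_support(support_threshold)
    leafsets = tree.leafsets()
    collapsed_leafsets = collapsed.leafsets()
    collapsed_node_of = {ls: n for n, ls in collapsed_leafsets.items()}
    node_by_name = {n.name: n for n in tree.postorder()}
    post_index = {name: i for i, name in enumerate(reconstruction.node_names)}

    records = []
    for i, pos in enumerate(reconstruction.positions):
        leaf_state = {s: int(c) for s, c in zip(leaf_order, reconstruction.leaf_states[i])}
        count = hartigan_count(tree, leaf_state)
        if count != 1:
            continue
        located = _single_event_branch(tree, leafsets, leaf_state, tree.outgroup)
        if located is None:
            continue
        clade, anc, derived = located

        parent = clade.parent
        posterior = float(reconstruction.posteriors[post_index[parent.name]][i, anc])
        if posterior < posterior_threshold:
            continue

        # filter (c): identical inference on the low-support-collapsed tree
        ccount = hartigan_count(collapsed, leaf_state)
        cnode = collapsed_node_of.get(leafsets[clade])
        if ccount != 1 or cnode is None or cnode.parent is None:
            continue

        supports = []
        node = clade
        while node is not None:
            if not node.is_leaf and node.support is not None:
                supports.append(node.support)
            node = node.parent
        records.append(
            {
                "position": int(pos),
                "from_base": BASES[anc],
                "to_base": BASES[derived],
                "branch": clade.name,
                "posterior": posterior,
                "fitch_count": 1,
                "min_support": min(supports) if supports else np.nan,
            }
        )
    table = pd.DataFrame(records, columns=list(ChangeSet.COLUMNS))
    return ChangeSet(table)
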