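"""Synthetic genomes, trees, binding landscapes and evolved alignments.

Everything downstream of the raw data — ancestral change calling, binding
stratification, odds ratios, the methylation-context permutation test and
the classifier randomization test — can be exercised on data simulated
here, with full ground truth:

* a random rooted strain phylogeny with an outgroup and per-node bootstrap
  supports drawn from a high/low mixture (so the support filter has both
  classes to act on);
* a circular genome with non-overlapping protein-coding genes, every third
  codon position classified by degeneracy from the standard genetic code;
* per-(protein, phase) binding interval sets with a tunable degree of
  interval sharing between growth phases (temporally closer phases share
  more intervals, as observed for the real NAPs), with Fis restricted to
  the two exponential phases;
* an alignment evolved on the tree by per-site, per-branch Bernoulli
  mutation draws whose probabilities are base rate x branch length x
  binding-category modifier x CCWGG-context multiplier, with every placed
  event recorded as ground truth;
* a direct logistic site-table generator that skips sequence evolution so
  classifier behaviour can be tested against known feature effects.

All coordinates are 0-based half-open.  Mutations are placed as at most one
event per site per branch, which matches the single-event assumption of the
downstream parsimony filter; the multiple-hit regime is rejected outright.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.special import expit

from .ancestral_changes import (
    BASES,
    BASE_CODE,
    COMPLEMENT,
    AlignmentBlock,
    InvalidParameterError,
    Phylogeny,
    StrainAlignment,
    TreeNode,
)
from .binding_profiles import (
    FIS_PHASES,
    PHASES,
    PROTEINS,
    BindingProfile,
    classify_all_sites,
)

#: the 12 strand-specific mutation types (ordered base pairs)
MUTATION_TYPES = tuple(f"{a}>{b}" for a in BASES for b in BASES if a != b)

#: default per-tree-unit rates, transition-biased with C:G -> T:A dominant,
#: echoing the 4-fold synonymous spectrum of enterobacteria
DEFAULT_BASE_RATES = {
    "C>T": 0.12, "G>A": 0.12,
    "A>G": 0.05, "T>C": 0.05,
    "C>A": 0.015, "G>T": 0.015,
    "A>C": 0.012, "T>G": 0.012,
    "A>T": 0.008, "T>A": 0.008,
    "C>G": 0.004, "G>C": 0.004,
}


class PlacementError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    `base_rates` are probabilities per site per unit branch length for each
    of the 12 strand-specific mutation types (reference-strand convention).
    `binding_effect` maps ``(protein, category, mutation_type)`` to a
    multiplicative rate modifier; `ccwgg_multiplier` scales C->T at the
    focal (second) cytosine of CCWGG motifs on either strand.
    `interphase_overlap` is the fraction of the anchor (stationary) phase's
    bound bases re-used by the most distant (mid-exponential) phase;
    intermediate phases interpolate geometrically.
    """

    genome_length: int = 50_000
    n_genes: int = 40
    n_strains: int = 8
    phase_names: tuple = PHASES
    binding_fraction_per_phase: float = 0.05
    interphase_overlap: float = 0.5
    base_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    binding_effect: dict = field(default_factory=dict)
    ccwgg_multiplier: float = 1.0
    seed: int = 0
    # secondary knobs
    gc: float = 0.5
    gene_length_range: tuple = (300, 900)
    binding_interval_mean: float = 200.0
    branch_length_mean: float = 0.02
    outgroup_length_factor: float = 3.0
    support_low_fraction: float = 0.2
    n_ccwgg_planted: int = 0  # extra CCWGG motifs planted into the genome

    def __post_init__(self):
        if len(self.phase_names) != 4:
            raise InvalidParameterError("phase_names must have exactly 4 entries")
        for p in (self.binding_fraction_per_phase, self.interphase_overlap,
                  self.gc, self.support_low_fraction):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"proportion {p} outside [0, 1]")
        unknown = set(self.base_rates) - set(MUTATION_TYPES)
        if unknown:
            raise InvalidParameterError(f"unknown mutation types: {sorted(unknown)}")
        if any(r < 0 for r in self.base_rates.values()):
            raise InvalidParameterError("rates must be >= 0")
        if self.ccwgg_multiplier < 0:
            raise InvalidParameterError("ccwgg_multiplier must be >= 0")
        self.base_rates = {t: float(self.base_rates.get(t, 0.0)) for t in MUTATION_TYPES}


@dataclass
class GroundTruth:
    """Recorded truth of a simulation run.

    `true_changes` has one row per placed mutation event (site, branch,
    from_base, to_base).  `implied_or` returns the odds (rate) ratio between
    two binding categories implied by the configured modifiers — closed
    form, independent of the realised data.
    """

    true_changes: pd.DataFrame | None = None
    true_binding_effect: dict = field(default_factory=dict)
    logistic_coefficients: dict | None = None

    def implied_or(self, protein: str, cat_num: str, cat_den: str, mutation_type: str) -> float:
        num = self.true_binding_effect.get((protein, cat_num, mutation_type), 1.0)
        den = self.true_binding_effect.get((protein, cat_den, mutation_type), 1.0)
        return num / den

    def to_tsv(self, path) -> None:
        (self.true_changes if self.true_changes is not None else pd.DataFrame()).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Strain tree
# ---------------------------------------------------------------------------


def make_strain_tree(
    n_strains: int,
    seed: int,
    branch_length_mean: float = 0.02,
    support_low_fraction: float = 0.2,
    outgroup_name: str = "outgroup",
    outgroup_length_factor: float = 3.0,
) -> Phylogeny:
    """Random rooted binary ingroup tree plus a (longer) outgroup branch.

    Internal-node bootstrap supports are drawn from a two-component mixture:
    high (98-100) with probability ``1 - support_low_fraction`` and low
    (50-97) otherwise, so the support filter always has material to act on
    when the low fraction is non-zero.
    """
    if n_strains < 3:
        raise InvalidParameterError("n_strains must be >= 3")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"strain{i + 1:02d}") for i in range(n_strains)]
    for leaf in nodes:
        leaf.length = float(rng.exponential(branch_length_mean))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.exponential(branch_length_mean)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    ingroup_root = nodes[0]
    root = TreeNode()
    root.add_child(ingroup_root)
    out_leaf = TreeNode(
        name=outgroup_name,
        length=float(rng.exponential(branch_length_mean * outgroup_length_factor)),
    )
    root.add_child(out_leaf)
    tree = Phylogeny(root, outgroup=outgroup_name)
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        if rng.random() < support_low_fraction:
            node.support = float(np.round(rng.uniform(50, 97), 1))
        else:
            node.support = float(np.round(rng.uniform(98, 100), 1))
    tree.root.support = 100.0  # the root split is fixed by outgroup rooting
    return tree


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def _third_position_degeneracy() -> dict:
    """codon -> number of third-position bases preserving the amino acid."""
    table = CodonTable.unambiguous_dna_by_id[1]
    def aa(codon):
        return "*" if codon in table.stop_codons else table.forward_table[codon]
    out = {}
    for c1 in BASES:
        for c2 in BASES:
            for c3 in BASES:
                codon = c1 + c2 + c3
                out[codon] = sum(aa(c1 + c2 + b) == aa(codon) for b in BASES)
    return out


_DEGENERACY = _third_position_degeneracy()


@dataclass
class Genome:
    """Simulated circular genome with annotation arrays (one entry per bp).

    degeneracy: -1 intergenic, 0 for codon positions 1-2, else the number of
    synonymous third-position bases (1, 2, 3 or 4).
    """

    sequence: str
    genes: pd.DataFrame
    degeneracy: np.ndarray
    gene_strand: np.ndarray  # 0 intergenic, +1 / -1
    codon_position: np.ndarray  # -1 intergenic, else 0/1/2 (gene reading frame)
    gene_index: np.ndarray  # -1 intergenic

    def __len__(self):
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        lut = np.full(256, -1, dtype=np.int8)
        for b, i in BASE_CODE.items():
            lut[ord(b)] = i
        return lut[np.frombuffer(self.sequence.encode(), dtype=np.uint8)]

    @property
    def fourfold_positions(self) -> np.ndarray:
        return np.flatnonzero(self.degeneracy == 4)

    @property
    def twofold_positions(self) -> np.ndarray:
        return np.flatnonzero(self.degeneracy == 2)

    def write_fasta(self, path, name: str = "genome") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i:i + 70] + "\n")

    def write_gene_table(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def simulate_genome(config: SimConfig) -> Genome:
    """Random genome with non-overlapping genes and codon classification."""
    L = config.genome_length
    if L < 1000:
        raise InvalidParameterError("genome_length must be >= 1000")
    rng = np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    codes = rng.choice(4, size=L, p=p).astype(np.int8)

    lo, hi = config.gene_length_range
    lengths = (rng.integers(lo // 3, hi // 3 + 1, size=config.n_genes) * 3).astype(int)
    total_genic = int(lengths.sum())
    if total_genic > L:
        raise PlacementError(
            f"{config.n_genes} genes of total length {total_genic} exceed genome of {L} bp"
        )
    # distribute the leftover length over n_genes + 1 intergenic gaps
    slack = L - total_genic
    cuts = np.sort(rng.integers(0, slack + 1, size=config.n_genes))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    strands = rng.choice([1, -1], size=config.n_genes)

    if config.n_ccwgg_planted:
        motif = np.array([BASE_CODE[b] for b in "CCAGG"], dtype=np.int8)
        spots = rng.choice(L - 5, size=config.n_ccwgg_planted, replace=False)
        for s in np.sort(spots):
            codes[s:s + 5] = motif

    sequence = "".join(BASES[c] for c in codes)
    degeneracy = np.full(L, -1, dtype=np.int8)
    gene_strand = np.zeros(L, dtype=np.int8)
    codon_position = np.full(L, -1, dtype=np.int8)
    gene_index = np.full(L, -1, dtype=np.int32)

    rows = []
    for g, (start, length, strand) in enumerate(zip(starts, lengths, strands)):
        end = int(start + length)
        start = int(start)
        rows.append(
            {"gene_id": f"gene{g + 1:03d}", "start": start, "end": end,
             "strand": "+" if strand > 0 else "-", "frame": 0}
        )
        gene_strand[start:end] = strand
        gene_index[start:end] = g
        gene_seq = sequence[start:end]
        if strand < 0:
            gene_seq = gene_seq.translate(COMPLEMENT)[::-1]
        for k in range(0, length, 3):
            codon = gene_seq[k:k + 3]
            deg = _DEGENERACY[codon]
            for off in range(3):
                gpos = start + k + off if strand > 0 else end - 1 - (k + off)
                codon_position[gpos] = off
                degeneracy[gpos] = deg if off == 2 else 0
    genes = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "frame"])
    return Genome(sequence, genes, degeneracy, gene_strand, codon_position, gene_index)


def simulate_expression(genome: Genome, seed: int, phase_names=PHASES) -> pd.DataFrame:
    """Log-normal per-gene expression for each growth phase (confounder)."""
    rng = np.random.default_rng(seed)
    data = {"gene_id": genome.genes.gene_id}
    for phase in phase_names:
        data[f"expression_{phase}"] = rng.lognormal(mean=0.0, sigma=1.0, size=len(genome.genes))
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Binding profiles
# ---------------------------------------------------------------------------


def _draw_intervals(rng, L, target_bases, mean_len, forbidden=None, max_tries=200_000):
    """Random non-overlapping intervals until `target_bases` are covered."""
    occupied = np.zeros(L, dtype=bool)
    if forbidden is not None:
        occupied |= forbidden
    intervals, covered, tries = [], 0, 0
    while covered < target_bases:
        tries += 1
        if tries > max_tries:
            raise PlacementError("could not place binding intervals (coverage too high?)")
        length = 1 + int(rng.geometric(1.0 / mean_len))
        start = int(rng.integers(0, L))
        end = min(start + length, L)
        if occupied[start:end].any():
            continue
        occupied[start:end] = True
        intervals.append((start, end))
        covered += end - start
    return intervals


def simulate_binding_profiles(genome: Genome, config: SimConfig) -> dict:
    """Interval sets per (protein, phase) with tunable inter-phase sharing.

    The temporally last assayed phase acts as the anchor (stationary phase;
    late exponential for Fis, which is undetectable later).  Each earlier
    phase re-uses a fraction ``interphase_overlap ** (d / 3)`` of the
    anchor's bound bases, where d is the phase distance to the anchor, and
    tops up to its coverage target with fresh intervals placed outside the
    anchor set — so the realised anchor-vs-phase overlap equals the re-use
    fraction up to interval granularity, and phases closer to the anchor
    share more sequence.
    """
    frac = config.binding_fraction_per_phase
    if frac >= 1.0:
        raise InvalidParameterError("binding fraction per phase must be < 1")
    L = len(genome)
    rng = np.random.default_rng(config.seed + 1)
    target = int(round(frac * L))
    profiles = {}
    for protein in PROTEINS:
        phases = FIS_PHASES if protein == "Fis" else config.phase_names
        anchor_phase = phases[-1]
        anchor_iv = _draw_intervals(rng, L, target, config.binding_interval_mean)
        profiles[(protein, anchor_phase)] = BindingProfile(protein, anchor_phase, anchor_iv)
        anchor_mask = profiles[(protein, anchor_phase)].membership(L)
        anchor_cov = profiles[(protein, anchor_phase)].coverage

        for d, phase in enumerate(reversed(phases[:-1]), start=1):
            r = config.interphase_overlap ** (d / 3.0)
            order = rng.permutation(len(anchor_iv))
            reused, reused_cov = [], 0
            for idx in order:
                if reused_cov >= r * anchor_cov:
                    break
                s, e = anchor_iv[idx]
                reused.append((s, e))
                reused_cov += e - s
            fresh = []
            if reused_cov < target:
                fresh = _draw_intervals(
                    rng, L, target - reused_cov, config.binding_interval_mean,
                    forbidden=anchor_mask,
                )
            profiles[(protein, phase)] = BindingProfile(protein, phase, reused + fresh)
    return profiles


def write_binding_beds(profiles: dict, outdir, chrom: str = "genome") -> list:
    import os

    paths = []
    for (protein, phase), prof in sorted(profiles.items()):
        path = os.path.join(str(outdir), f"{protein}_{phase}.bed")
        prof.to_bed(path, chrom=chrom)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_CCWGG_FWD = re.compile(r"(?=CC[AT]GG)")


def _ccwgg_focal_arrays(sequence: str, multiplier: float):
    """Per-site C->T and G->A context multipliers for the current sequence."""
    L = len(sequence)
    ct = np.ones(L)
    ga = np.ones(L)
    if multiplier == 1.0:
        return ct, ga
    for m in _CCWGG_FWD.finditer(sequence):
        ct[m.start() + 1] = multiplier  # second C of the forward motif
    rc = sequence.translate(COMPLEMENT)[::-1]
    for m in _CCWGG_FWD.finditer(rc):
        ga[L - 2 - m.start()] = multiplier  # second C on the reverse strand
    return ct, ga


def evolve_alignment(
    genome: Genome, tree: Phylogeny, config: SimConfig, profiles: dict | None = None
):
    """Evolve the genome down the tree; returns (StrainAlignment, GroundTruth).

    Per branch and site, at most one Bernoulli-drawn event with probability
    base_rate x branch_length x binding modifier x context multiplier; the
    regime where any such probability reaches 0.5 is rejected because the
    downstream single-event machinery is not meaningful there.
    """
    L = len(genome)
    rng = np.random.default_rng(config.seed + 2)

    type_mult = {t: np.ones(L) for t in MUTATION_TYPES if config.base_rates[t] > 0}
    if config.binding_effect:
        if profiles is None:
            raise InvalidParameterError("binding_effect configured but no profiles given")
        cats = classify_all_sites(profiles, L)
        for (protein, category, mtype), eff in config.binding_effect.items():
            if mtype in type_mult:
                sel = (cats[f"cat_{protein}"] == category).to_numpy()
                type_mult[mtype][sel] *= eff

    root_codes = genome.codes
    sequences = {tree.root: root_codes}
    events = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_codes = sequences[node.parent]
        parent_seq = "".join(BASES[c] for c in parent_codes)
        ctx_ct, ctx_ga = _ccwgg_focal_arrays(parent_seq, config.ccwgg_multiplier)

        prob = np.zeros((L, 4))
        for t, mult in type_mult.items():
            a, b = BASE_CODE[t[0]], BASE_CODE[t[2]]
            sel = parent_codes == a
            p = config.base_rates[t] * node.length * mult[sel]
            if t == "C>T":
                p = p * ctx_ct[sel]
            elif t == "G>A":
                p = p * ctx_ga[sel]
            prob[sel, b] = p
        total = prob.sum(axis=1)
        if (total >= 0.5).any():
            raise InvalidParameterError(
                f"per-site mutation probability reaches {total.max():.3f} >= 0.5 "
                f"on branch {node.name}; multiple-hit regime"
            )
        u = rng.random(L)
        hit = np.flatnonzero(u < total)
        child_codes = parent_codes.copy()
        if hit.size:
            cond = prob[hit] / total[hit, None]
            v = rng.random(hit.size)
            target = np.minimum(
                (np.cumsum(cond, axis=1) < v[:, None]).sum(axis=1), 3
            )
            for site, tgt in zip(hit, target):
                if tgt == parent_codes[site]:  # float round-off at the cumsum edge
                    continue
                events.append(
                    {"site": int(site), "branch": node.name,
                     "from_base": BASES[parent_codes[site]], "to_base": BASES[tgt]}
                )
                child_codes[site] = np.int8(tgt)
        sequences[node] = child_codes

    seq_strings = {
        leaf.name: "".join(BASES[c] for c in sequences[leaf]) for leaf in tree.leaves
    }
    alignment = StrainAlignment(
        [AlignmentBlock(0, seq_strings)], outgroup=tree.outgroup
    )
    truth = GroundTruth(
        true_changes=pd.DataFrame(events, columns=["site", "branch", "from_base", "to_base"]),
        true_binding_effect=dict(config.binding_effect),
    )
    return alignment, truth


# ---------------------------------------------------------------------------
# Logistic site-table shortcut
# ---------------------------------------------------------------------------

#: default binding-category marginals for the site-table generator
_CATEGORY_PROBS = {"never": 0.65, "early": 0.12, "late": 0.12, "always": 0.06, "other": 0.05}
_CATEGORY_PROBS_FIS = {"never": 0.75, "early": 0.20, "late": 0.0, "always": 0.0, "other": 0.05}


@dataclass
class SiteTableConfig:
    """Parameters of the direct logistic site-table generator.

    `coefficients` maps feature names to log-odds effects.  Numeric features
    use their column name (e.g. ``"local_gc"``); binding categories use
    ``"cat_<protein>=<category>"`` indicator terms.  The intercept is the
    log-odds of a change at baseline.
    """

    n_sites: int = 10_000
    # baseline change probability 3%, matching the changed-site fraction the
    # sequence-evolution generator realises at its default rates
    intercept: float = float(np.log(0.03 / 0.97))
    coefficients: dict = field(default_factory=dict)
    #: optional per-protein binding-category marginals, e.g.
    #: {"H-NS": {"never": 0.5, "early": 0.5}}; unlisted proteins use defaults
    category_probs: dict = field(default_factory=dict)
    seed: int = 0


def simulate_site_table(config: SiteTableConfig, seed: int | None = None):
    """Draw a site table from a logistic model over configured features.

    Returns ``(DataFrame, GroundTruth)``; the frame has one row per at-risk
    site with per-protein binding categories, confounder features and the
    binary ``changed`` outcome.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_sites
    data = {}
    from .binding_profiles import CATEGORIES

    for protein in PROTEINS:
        probs = _CATEGORY_PROBS_FIS if protein == "Fis" else _CATEGORY_PROBS
        probs = config.category_probs.get(protein, probs)
        p = np.array([probs.get(c, 0.0) for c in CATEGORIES])
        data[f"cat_{protein}"] = pd.Categorical.from_codes(
            rng.choice(len(CATEGORIES), size=n, p=p / p.sum()), categories=list(CATEGORIES)
        )
    for phase in PHASES:
        data[f"expression_{phase}"] = rng.lognormal(0.0, 1.0, size=n)
    data["leading_strand"] = rng.integers(0, 2, size=n).astype(np.int8)
    data["origin_distance"] = rng.uniform(0.0, 1.0, size=n)
    data["local_gc"] = np.clip(rng.normal(0.5, 0.05, size=n), 0.0, 1.0)
    data["twofold"] = (rng.random(n) < 0.3).astype(np.int8)
    table = pd.DataFrame(data)

    lp = np.full(n, config.intercept)
    for key, coef in config.coefficients.items():
        if "=" in key:
            col, level = key.split("=", 1)
            lp += coef * (table[col] == level).to_numpy(dtype=float)
        else:
            lp += coef * table[key].to_numpy(dtype=float)
    p_change = expit(lp)
    if (p_change >= 0.5).any():
        raise InvalidParameterError(
            f"per-site change probability reaches {p_change.max():.3f} >= 0.5"
        )
    table["changed"] = (rng.random(n) < p_change).astype(np.int8)
    truth = GroundTruth(logistic_coefficients=dict(config.coefficients))
    return table, truth
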