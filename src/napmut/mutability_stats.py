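"""Stratified mutability, odds ratios, methylation contexts and the FDR.

Mutability is defined throughout as changes per at-risk nucleotide: the
number of high-confidence changes of a given type observed across the
phylogeny, divided by the number of nucleotides in the same site/binding
category that could have experienced that change (every C for C->T, and so
on).  Estimates are computed per mutation type x binding stratum x site
class, at strand-specific (12 types) and strand-collapsed ("couple", 6
types, e.g. C:G->T:A) resolution.

Strand convention: genic sites are expressed on the sense (non-transcribed)
strand of their gene, so "C->T" means C->T as read off the mRNA-like
strand; intergenic sites have no defined transcriptional strand and enter
only couple-level summaries (on the reference strand).

Binding contrasts are summarised as odds ratios with Woolf (log-scale
normal) 95% confidence intervals, with the Haldane-Anscombe +0.5 continuity
correction applied to all four cells whenever any cell is zero.

The 5-methylcytosine machinery: the Dcm methyltransferase methylates the
second cytosine of CCWGG (W = A/T) motifs, whose deamination to thymine is
a C->T hotspot repaired by stationary-phase-specific VSP repair.  CCWHH
(H = A/C/T) serves as the matched unmethylated control.  Both strands are
scanned; the focal site is the second C of each occurrence on its strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ancestral_changes import BASES, COMPLEMENT

#: strand-collapsed mutation couples, labelled pyrimidine-first
COUPLES = ("C:G>T:A", "T:A>C:G", "C:G>A:T", "C:G>G:C", "T:A>A:T", "T:A>G:C")

_PYRIMIDINE = {"C", "T"}


def couple_of(mutation_type: str) -> str:
    """Strand-collapsed couple label of a strand-specific type."""
    a, b = mutation_type[0], mutation_type[2]
    if a not in _PYRIMIDINE:
        a, b = a.translate(COMPLEMENT), b.translate(COMPLEMENT)
    comp = lambda x: x.translate(COMPLEMENT)
    return f"{a}:{comp(a)}>{b}:{comp(b)}"


@dataclass
class MutabilityEstimate:
    mutation_type: str
    stratum: str
    site_class: str
    n_changes: int
    n_at_risk: int

    @property
    def rate(self) -> float:
        return self.n_changes / self.n_at_risk


def tabulate_mutability(
    changes: pd.DataFrame,
    sites: pd.DataFrame,
    stratum_col: str,
    site_class: str = "fourfold",
    strand_specific: bool = True,
) -> pd.DataFrame:
    """Changes per at-risk nucleotide, per mutation type and stratum.

    `sites` needs one row per at-risk site with columns ``position``,
    ``ref_base``, ``site_class``, ``strand`` ('+'/'-'/'' for intergenic) and
    the stratum column.  `changes` needs ``position``, ``from_base``,
    ``to_base``.  Site classes: ``coding``, ``intergenic``, ``fourfold``
    (and ``fourfold+twofold`` which adds 2-fold sites, used for
    transitions).  With ``strand_specific`` genic types are re-expressed on
    the gene's sense strand and intergenic sites are excluded; otherwise
    counts are collapsed to couples with each duplex site counted once
    (labelled by its pyrimidine base).

    Strata with an empty denominator are omitted with a warning.
    """
    if site_class == "fourfold+twofold":
        sel = sites["site_class"].isin(["fourfold", "twofold"])
    elif site_class == "coding":
        sel = sites["site_class"].isin(["fourfold", "twofold", "coding_other"])
    else:
        sel = sites["site_class"] == site_class
    sub = sites.loc[sel].copy()
    ch = changes.merge(
        sub[["position", "ref_base", "strand", stratum_col]], on="position", how="inner"
    )
    # only count a change toward the denominator's base (ancestral == at-risk base)
    ch = ch.loc[ch.from_base == ch.ref_base]

    rows = []
    strata = [s for s in sub[stratum_col].unique() if not pd.isna(s)]
    for stratum in sorted(map(str, strata)):
        s_sites = sub.loc[sub[stratum_col].astype(str) == stratum]
        s_ch = ch.loc[ch[stratum_col].astype(str) == stratum]
        if strand_specific:
            s_sites = s_sites.loc[s_sites.strand.isin(["+", "-"])]
            s_ch = s_ch.loc[s_ch.strand.isin(["+", "-"])]
            base_of = _sense_base(s_sites.ref_base, s_sites.strand)
            at_risk = base_of.value_counts()
            if len(s_ch):
                from_sense = _sense_base(s_ch.from_base, s_ch.strand)
                to_sense = _sense_base(s_ch.to_base, s_ch.strand)
                tcounts = (from_sense + ">" + to_sense).value_counts()
            else:
                tcounts = pd.Series(dtype=int)
            for a in BASES:
                n_risk = int(at_risk.get(a, 0))
                for b in BASES:
                    if a == b:
                        continue
                    t = f"{a}>{b}"
                    if n_risk == 0:
                        if tcounts.get(t, 0):
                            warnings.warn(f"stratum {stratum}: zero denominator for {t}; omitted")
                        continue
                    rows.append(
                        {"mutation_type": t, "stratum": stratum, "site_class": site_class,
                         "n_changes": int(tcounts.get(t, 0)), "n_at_risk": n_risk}
                    )
        else:
            pyr = s_sites.ref_base.where(
                s_sites.ref_base.isin(list(_PYRIMIDINE)),
                s_sites.ref_base.str.translate(COMPLEMENT),
            )
            at_risk = pyr.value_counts()
            if len(s_ch):
                ccounts = (s_ch.from_base + ">" + s_ch.to_base).map(couple_of).value_counts()
            else:
                ccounts = pd.Series(dtype=int)
            for cpl in COUPLES:
                base = cpl[0]  # pyrimidine member labels the duplex site
                n_risk = int(at_risk.get(base, 0))
                if n_risk == 0:
                    if ccounts.get(cpl, 0):
                        warnings.warn(f"stratum {stratum}: zero denominator for {cpl}; omitted")
                    continue
                rows.append(
                    {"mutation_type": cpl, "stratum": stratum, "site_class": site_class,
                     "n_changes": int(ccounts.get(cpl, 0)), "n_at_risk": n_risk}
                )
    out = pd.DataFrame(
        rows, columns=["mutation_type", "stratum", "site_class", "n_changes", "n_at_risk"]
    )
    out["rate"] = out.n_changes / out.n_at_risk
    return out


def _sense_base(bases: pd.Series, strands: pd.Series) -> pd.Series:
    flipped = bases.str.translate(COMPLEMENT)
    return bases.where(strands.to_numpy() == "+", flipped)


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------


@dataclass
class OddsRatioResult:
    """OR of stratum 2 (numerator) vs stratum 1, with Woolf 95% CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    numerator: str = "stratum2"
    haldane: bool = False
    defined: bool = True


def odds_ratio_ci(
    changed_1: int, at_risk_1: int, changed_2: int, at_risk_2: int,
    numerator: str = "stratum2",
) -> OddsRatioResult:
    """Odds ratio with Woolf log-scale 95% CI.

    OR = [c2/(n2-c2)] / [c1/(n1-c1)], stratum 2 on top (unbound in the
    bound-vs-unbound contrast, early in the early-vs-late contrast).  When
    any cell is zero the Haldane-Anscombe correction adds 0.5 to all four
    cells.  If neither stratum has any change the result is flagged
    undefined rather than silently reported as 1.
    """
    for c, n in ((changed_1, at_risk_1), (changed_2, at_risk_2)):
        if not 0 <= c <= n:
            raise ValueError("need at_risk >= changed >= 0 in both strata")
    if changed_1 == 0 and changed_2 == 0:
        return OddsRatioResult(np.nan, np.nan, np.nan, numerator, defined=False)
    cells = np.array(
        [changed_2, at_risk_2 - changed_2, changed_1, at_risk_1 - changed_1], dtype=float
    )
    haldane = bool((cells == 0).any())
    if haldane:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a / b) - np.log(c / d)
    se = float(np.sqrt((1.0 / cells).sum()))
    z = norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        numerator=numerator,
        haldane=haldane,
    )


# ---------------------------------------------------------------------------
# Methylation contexts
# ---------------------------------------------------------------------------

_CCWGG = re.compile(r"(?=CC[AT]GG)")
_CCWHH = re.compile(r"(?=CC[AT][ACT][ACT])")


@dataclass
class ContextCensus:
    """Focal cytosines of CCWGG motifs and CCWHH controls, strand-resolved.

    Positions are reference coordinates of the focal (second) C; strand '+'
    means the motif lies on the reference strand (focal base C), '-' that
    it lies on the reverse strand (reference base G).
    """

    ccwgg: pd.DataFrame  # columns: position, strand
    control: pd.DataFrame

    def __post_init__(self):
        a = set(map(tuple, self.ccwgg.to_numpy()))
        b = set(map(tuple, self.control.to_numpy()))
        if a & b:
            raise ValueError("CCWGG and control focal sets overlap")


def scan_methylation_contexts(sequence: str) -> ContextCensus:
    """Scan both strands for CCWGG motifs and CCWHH controls.

    The focal site is the second C of each occurrence on its own strand
    (reference position of the paired G for reverse-strand hits).
    Overlapping occurrences are all reported; CCWHH excludes G at the last
    two positions so no CCWGG occurrence can double as a control.
    Non-ACGT characters never match and trigger a warning.
    """
    sequence = sequence.upper()
    if re.search(r"[^ACGT]", sequence):
        warnings.warn("sequence contains ambiguity codes; those positions are skipped")
    L = len(sequence)
    rc = sequence.translate(COMPLEMENT)[::-1]

    def occurrences(pattern):
        fwd = [(m.start() + 1, "+") for m in pattern.finditer(sequence)]
        rev = [(L - 2 - m.start(), "-") for m in pattern.finditer(rc)]
        return pd.DataFrame(sorted(fwd + rev), columns=["position", "strand"])

    return ContextCensus(ccwgg=occurrences(_CCWGG), control=occurrences(_CCWHH))


def context_mutability(
    census: ContextCensus,
    changes: pd.DataFrame,
    timing: pd.DataFrame,
    never_any_nap: np.ndarray,
    naps=("H-NS", "IhfA", "IhfB"),
) -> pd.DataFrame:
    """C->T mutability per (motif class x NAP x binding-timing stratum).

    Counts strand-resolved C->T changes at focal positions only: a change
    at a '+' focal site must be C->T on the reference strand, at a '-'
    focal site G->A.  Strata per focal NAP: exclusively_early and
    exclusively_late from `timing` (columns ``timing_<NAP>`` indexed by
    position); plus ``never`` = sites never bound by any NAP (boolean
    per-position array), shared across NAPs.
    """
    ch = changes.copy()
    ch["is_ct"] = (ch.from_base == "C") & (ch.to_base == "T")
    ch["is_ga"] = (ch.from_base == "G") & (ch.to_base == "A")
    hit_pos = {
        "+": set(ch.loc[ch.is_ct, "position"].astype(int)),
        "-": set(ch.loc[ch.is_ga, "position"].astype(int)),
    }

    rows = []
    for motif, focal in (("CCWGG", census.ccwgg), ("control", census.control)):
        pos = focal.position.to_numpy(dtype=int)
        strands = focal.strand.to_numpy()
        changed = np.array(
            [p in hit_pos[s] for p, s in zip(pos, strands)], dtype=bool
        )
        for nap in naps:
            flags = timing[f"timing_{nap}"].to_numpy()[pos]
            for stratum, sel in (
                ("exclusively_early", flags == "exclusively_early"),
                ("exclusively_late", flags == "exclusively_late"),
                ("never", never_any_nap[pos]),
            ):
                n_ctx = int(sel.sum())
                if n_ctx == 0:
                    warnings.warn(f"{motif}/{nap}/{stratum}: no contexts at risk; omitted")
                    continue
                rows.append(
                    {"motif": motif, "nap": nap, "stratum": stratum,
                     "n_changes": int(changed[sel].sum()), "n_contexts": n_ctx}
                )
    out = pd.DataFrame(rows, columns=["motif", "nap", "stratum", "n_changes", "n_contexts"])
    out["rate"] = out.n_changes / out.n_contexts
    return out


# ---------------------------------------------------------------------------
# Expected-false-positive FDR
# ---------------------------------------------------------------------------


@dataclass
class FdrEstimate:
    """Expected-false-positive FDR: alpha*m tests expected positive by
    chance among k observed positives."""

    alpha: float
    m: int
    k: int
    fdr: float
    defined: bool = True


def estimate_fdr(alpha: float, m: int, k: int) -> FdrEstimate:
    """fdr = min(1, alpha * m / k); k = 0 is flagged undefined.

    E.g. six tests at alpha = 0.1 with four positives give
    0.6 / 4 = 15% expected false discoveries.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not (isinstance(m, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise ValueError("m and k must be integers")
    if not m >= k >= 0:
        raise ValueError("need m >= k >= 0")
    if k == 0:
        return FdrEstimate(alpha, m, k, np.nan, defined=False)
    return FdrEstimate(alpha, int(m), int(k), min(1.0, alpha * m / k))
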