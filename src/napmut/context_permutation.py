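"""Permutation test for the joint CCWGG / control mutability pattern.

The biological claim under test: C->T changes at methylated CCWGG focal
cytosines are *more* frequent in sequence bound exclusively late (when the
cognate VSP repair pathway is active) than in sequence bound exclusively
early, while changes at matched unmethylated CCWHH control contexts show
the *opposite* ordering — jointly, across three NAPs (H-NS, IhfA, IhfB).

The null keeps the total number of mutations within each NAP+context
combination fixed and redistributes each mutation independently to the
late- or early-bound category with probability proportional to the number
of contexts in each category (a binomial allocation; the description of
the procedure implies no without-replacement constraint).  The p-value is
the add-one-corrected fraction of replicates in which all six combinations
conform to the observed pattern, which avoids reporting p = 0.

"Conform" uses strict inequalities of the category rates (mutations per
context); ties count against conformity, the conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .ancestral_changes import InvalidParameterError

#: expected orderings: rate_late > rate_early inside CCWGG, reversed outside
PATTERN = {"CCWGG": "late_gt_early", "control": "early_gt_late"}


@dataclass
class ComboCounts:
    """Counts for one NAP x motif-class combination."""

    nap: str
    motif: str  # "CCWGG" or "control"
    n_mut_early: int
    n_mut_late: int
    n_ctx_early: int
    n_ctx_late: int

    def __post_init__(self):
        if self.motif not in PATTERN:
            raise InvalidParameterError(f"motif must be CCWGG or control, got {self.motif!r}")
        if min(self.n_mut_early, self.n_mut_late, self.n_ctx_early, self.n_ctx_late) < 0:
            raise InvalidParameterError("counts must be >= 0")
        if self.n_mut_early > self.n_ctx_early or self.n_mut_late > self.n_ctx_late:
            raise InvalidParameterError("mutations cannot exceed contexts at risk")

    @property
    def n_mut_total(self) -> int:
        return self.n_mut_early + self.n_mut_late

    @property
    def evaluable(self) -> bool:
        return self.n_ctx_early > 0 and self.n_ctx_late > 0

    def conforms(self, n_late: int | np.ndarray, n_early: int | np.ndarray):
        """Does a (possibly permuted) allocation match the expected pattern?"""
        rate_late = np.asarray(n_late) / self.n_ctx_late
        rate_early = np.asarray(n_early) / self.n_ctx_early
        if PATTERN[self.motif] == "late_gt_early":
            return rate_late > rate_early
        return rate_early > rate_late


@dataclass
class PermutationResult:
    observed_conformity: dict  # (nap, motif) -> bool
    n_reps: int
    n_all_conform: int
    p_value: float


def observed_conformity_pattern(combos) -> dict:
    """Strict-inequality conformity of each combination's observed rates."""
    out = {}
    for combo in combos:
        if not combo.evaluable:
            raise InvalidParameterError(
                f"{combo.nap}/{combo.motif}: zero contexts in a category, unevaluable"
            )
        out[(combo.nap, combo.motif)] = bool(
            combo.conforms(combo.n_mut_late, combo.n_mut_early)
        )
    return out


def permutation_pvalue(combos, n_reps: int = 100_000, seed: int = 0) -> PermutationResult:
    """Monte-Carlo probability that every combination conforms under the
    binomial redistribution null, with the add-one correction
    p = (n_all_conform + 1) / (n_reps + 1)."""
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    observed = observed_conformity_pattern(combos)
    rng = np.random.default_rng(seed)
    all_conform = np.ones(n_reps, dtype=bool)
    for combo in combos:
        p_late = combo.n_ctx_late / (combo.n_ctx_early + combo.n_ctx_late)
        n_late = rng.binomial(combo.n_mut_total, p_late, size=n_reps)
        all_conform &= combo.conforms(n_late, combo.n_mut_total - n_late)
    k = int(all_conform.sum())
    return PermutationResult(
        observed_conformity=observed,
        n_reps=n_reps,
        n_all_conform=k,
        p_value=(k + 1) / (n_reps + 1),
    )


def exact_pvalue_oracle(combos, max_states: int = 1_000_000) -> float:
    """Exact all-conform probability under the same null, by enumerating
    every allocation of each combination's mutations (combinations are
    independent, so the joint probability is the product of per-combination
    conform probabilities).  Refuses when the product state space exceeds
    `max_states`."""
    space = 1
    for combo in combos:
        space *= combo.n_mut_total + 1
        if space > max_states:
            raise InvalidParameterError(
                f"state space of {space}+ outcomes exceeds limit {max_states}"
            )
    prob = 1.0
    for combo in combos:
        if not combo.evaluable:
            raise InvalidParameterError(
                f"{combo.nap}/{combo.motif}: zero contexts in a category, unevaluable"
            )
        p_late = combo.n_ctx_late / (combo.n_ctx_early + combo.n_ctx_late)
        k = np.arange(combo.n_mut_total + 1)
        pmf = binom.pmf(k, combo.n_mut_total, p_late)
        prob *= float(pmf[combo.conforms(k, combo.n_mut_total - k)].sum())
    return prob


def combos_from_context_table(table) -> list:
    """Build ComboCounts from a `context_mutability` result frame
    (exclusively_early / exclusively_late strata only)."""
    combos = []
    for (nap, motif), grp in table.groupby(["nap", "motif"], observed=True):
        grp = grp.set_index("stratum")
        if not {"exclusively_early", "exclusively_late"} <= set(grp.index):
            continue
        combos.append(
            ComboCounts(
                nap=nap,
                motif=motif,
                n_mut_early=int(grp.loc["exclusively_early", "n_changes"]),
                n_mut_late=int(grp.loc["exclusively_late", "n_changes"]),
                n_ctx_early=int(grp.loc["exclusively_early", "n_contexts"]),
                n_ctx_late=int(grp.loc["exclusively_late", "n_contexts"]),
            )
        )
    return combos
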