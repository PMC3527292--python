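"""Growth-phase-resolved NAP binding profiles and per-site binding categories.

Binding of the four abundant nucleoid-associated proteins (Fis, H-NS, IhfA,
IhfB) was assayed by ChIP-Seq at four points of the *E. coli* batch growth
cycle: mid-exponential, late exponential, transition to stationary, and
stationary phase.  Occupancy is binary (a site is inside a called binding
interval or not).  This module loads per-(protein, phase) interval sets from
BED files, merges them, and recodes the 4-bit phase-membership pattern of
every genomic site into the growth-phase binding categories used throughout
the analysis:

``always``
    bound in all four assayed phases,
``early``
    bound during mid-exponential only, or mid- plus late exponential,
``late``
    bound during stationary only, or stationary plus transition,
``never``
    bound in no phase,
``other``
    any remaining pattern (kept visible rather than silently dropped; it is
    a first-class level for the classifier but is excluded from the
    four-category univariate contrasts).

A separate, coarser recode flags sites bound *exclusively* during the
exponential era (mid/late exponential, nothing later) or exclusively during
the stationary era (transition/stationary, nothing earlier); these rare
sites give the cleanest separation of binding timing from binding per se.

Fis is only detectable during the two exponential phases, so profiles for
Fis exist only for those phases and the ``late``/``always`` categories are
impossible for it.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEINS = ("Fis", "H-NS", "IhfA", "IhfB")
PHASES = ("mid_exponential", "late_exponential", "transition", "stationary")
#: phases at which Fis is detectable (absent from transition/stationary cultures)
FIS_PHASES = ("mid_exponential", "late_exponential")

EARLY_PHASES = frozenset({"mid_exponential", "late_exponential"})
LATE_PHASES = frozenset({"transition", "stationary"})

CATEGORIES = ("never", "early", "late", "always", "other")
TIMING_FLAGS = ("unbound", "exclusively_early", "exclusively_late", "neither")


class BedParseError(ValueError):
    pass


class BedNamingError(ValueError):
    pass


def merge_intervals(intervals) -> np.ndarray:
    """Union of 0-based half-open intervals; abutting intervals are joined."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    if (arr[:, 1] < arr[:, 0]).any():
        raise ValueError("interval with negative length")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class BindingProfile:
    """Merged interval set for one (protein, growth phase) pair."""

    protein: str
    phase: str
    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))

    def __post_init__(self):
        if self.protein not in PROTEINS:
            raise BedNamingError(f"unknown protein {self.protein!r}")
        if self.phase not in PHASES:
            raise BedNamingError(f"unknown phase {self.phase!r}")
        self.intervals = merge_intervals(self.intervals)

    @property
    def coverage(self) -> int:
        """Total bases covered."""
        if self.intervals.size == 0:
            return 0
        return int((self.intervals[:, 1] - self.intervals[:, 0]).sum())

    def membership(self, genome_length: int) -> np.ndarray:
        """Boolean per-base occupancy vector."""
        out = np.zeros(genome_length, dtype=bool)
        for s, e in self.intervals:
            out[s:e] = True
        return out

    def to_bed(self, path, chrom: str = "genome") -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{self.protein}_{self.phase}\n")

    @classmethod
    def from_bed(cls, path, protein: str, phase: str, chrom: str | None = None):
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                if start < 0 or end < start:
                    raise BedParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
                if chrom is not None and fields[0] != chrom:
                    raise BedParseError(
                        f"{path}:{lineno}: chrom {fields[0]!r} does not match reference {chrom!r}"
                    )
                intervals.append((start, end))
        return cls(protein, phase, np.asarray(intervals, np.int64).reshape(-1, 2))


_BED_NAME_RE = re.compile(
    r"^(?P<protein>[^_]+(?:-[^_]+)?)_(?P<phase>[a-z_]+)\.bed$"
)


def load_binding_profiles(paths, chrom: str | None = None) -> dict:
    """Load BED files named ``<protein>_<phase>.bed`` into merged profiles.

    `paths` may be a directory or an iterable of file paths.  Returns a dict
    keyed by ``(protein, phase)``.
    """
    if isinstance(paths, (str, os.PathLike)) and os.path.isdir(paths):
        paths = sorted(
            os.path.join(paths, p) for p in os.listdir(paths) if p.endswith(".bed")
        )
    profiles = {}
    for path in paths:
        base = os.path.basename(str(path))
        m = _BED_NAME_RE.match(base)
        if not m:
            raise BedNamingError(f"{base}: expected <protein>_<phase>.bed")
        protein, phase = m.group("protein"), m.group("phase")
        if protein not in PROTEINS:
            raise BedNamingError(f"{base}: unknown protein {protein!r}")
        if phase not in PHASES:
            raise BedNamingError(f"{base}: unknown phase {phase!r}")
        profiles[(protein, phase)] = BindingProfile.from_bed(path, protein, phase, chrom)
    return profiles


def phase_membership_matrix(profiles: dict, genome_length: int) -> dict:
    """Per protein, a (4, L) boolean matrix of phase occupancy (PHASES order).

    A phase without a profile (e.g. Fis outside exponential growth) counts
    as unbound everywhere.
    """
    out = {}
    for protein in PROTEINS:
        mat = np.zeros((len(PHASES), genome_length), dtype=bool)
        for i, phase in enumerate(PHASES):
            prof = profiles.get((protein, phase))
            if prof is not None:
                mat[i] = prof.membership(genome_length)
        out[protein] = mat
    return out


# (mid_exp, late_exp, transition, stationary) -> category; anything else is "other"
_NAMED_PATTERNS = {
    (False, False, False, False): "never",
    (True, True, True, True): "always",
    (True, False, False, False): "early",   # mid-exponential only
    (True, True, False, False): "early",    # mid + late exponential
    (False, False, False, True): "late",    # stationary only
    (False, False, True, True): "late",     # stationary + transition
}


def classify_pattern(bound) -> str:
    """Category for one phase-membership pattern (PHASES order)."""
    return _NAMED_PATTERNS.get(tuple(bool(b) for b in bound), "other")


def classify_site_binding(position: int, profiles: dict) -> dict:
    """Per-protein binding category for a single site.

    Returns ``{protein: category}`` plus the combined ``"any_nap"`` flag
    (bound by at least one protein in at least one phase).
    """
    result = {}
    any_bound = False
    for protein in PROTEINS:
        pattern = []
        for phase in PHASES:
            prof = profiles.get((protein, phase))
            hit = False
            if prof is not None and prof.intervals.size:
                idx = np.searchsorted(prof.intervals[:, 0], position, side="right") - 1
                hit = idx >= 0 and position < prof.intervals[idx, 1]
            pattern.append(hit)
        any_bound = any_bound or any(pattern)
        result[protein] = classify_pattern(pattern)
    result["any_nap"] = "bound" if any_bound else "never"
    return result


def classify_all_sites(profiles: dict, genome_length: int) -> pd.DataFrame:
    """Vectorised per-site category table.

    Columns: ``cat_<protein>`` (5-level categorical), ``timing_<protein>``
    (exclusive-timing flag), and boolean ``any_nap_bound``.
    """
    membership = phase_membership_matrix(profiles, genome_length)
    data = {}
    any_bound = np.zeros(genome_length, dtype=bool)
    for protein in PROTEINS:
        mat = membership[protein]
        any_bound |= mat.any(axis=0)
        # encode the 4-bit pattern and map through the pattern table
        code = (
            mat[0].astype(np.int8)
            | (mat[1].astype(np.int8) << 1)
            | (mat[2].astype(np.int8) << 2)
            | (mat[3].astype(np.int8) << 3)
        )
        lut = np.empty(16, dtype=object)
        for bits in range(16):
            pattern = tuple(bool(bits >> i & 1) for i in range(4))
            lut[bits] = classify_pattern(pattern)
        cats = pd.Categorical(lut[code], categories=list(CATEGORIES))
        data[f"cat_{protein}"] = cats

        in_early = mat[0] | mat[1]
        in_late = mat[2] | mat[3]
        timing = np.where(
            ~in_early & ~in_late,
            "unbound",
            np.where(
                in_early & ~in_late,
                "exclusively_early",
                np.where(~in_early & in_late, "exclusively_late", "neither"),
            ),
        )
        data[f"timing_{protein}"] = pd.Categorical(timing, categories=list(TIMING_FLAGS))
    data["any_nap_bound"] = any_bound
    return pd.DataFrame(data)


def flag_exclusive_timing(position: int, profiles: dict, protein: str) -> str:
    """Exclusive-timing flag for one site and one protein.

    ``exclusively_early``: bound in >=1 exponential phase and no later phase;
    ``exclusively_late``: bound in >=1 of transition/stationary and no
    exponential phase; ``unbound``: bound in no phase; otherwise ``neither``.
    """
    bound_phases = set()
    for phase in PHASES:
        prof = profiles.get((protein, phase))
        if prof is not None and prof.intervals.size:
            idx = np.searchsorted(prof.intervals[:, 0], position, side="right") - 1
            if idx >= 0 and position < prof.intervals[idx, 1]:
                bound_phases.add(phase)
    in_early = bool(bound_phases & EARLY_PHASES)
    in_late = bool(bound_phases & LATE_PHASES)
    if not bound_phases:
        return "unbound"
    if in_early and not in_late:
        return "exclusively_early"
    if in_late and not in_early:
        return "exclusively_late"
    return "neither"


def category_summary(site_table: pd.DataFrame) -> pd.DataFrame:
    """Coverage (site counts) per protein x category."""
    rows = []
    for protein in PROTEINS:
        counts = site_table[f"cat_{protein}"].value_counts()
        for cat in CATEGORIES:
            rows.append({"protein": protein, "category": cat, "n_sites": int(counts.get(cat, 0))})
    return pd.DataFrame(rows)


def overlap_fraction(a: BindingProfile, b: BindingProfile) -> float:
    """Fraction of bases of `a` that are also covered by `b`."""
    if a.coverage == 0:
        return float("nan")
    ia, ib = a.intervals, b.intervals
    total = 0
    j = 0
    for s, e in ia:
        while j < len(ib) and ib[j, 1] <= s:
            j += 1
        k = j
        while k < len(ib) and ib[k, 0] < e:
            total += min(e, ib[k, 1]) - max(s, ib[k, 0])
            k += 1
    return total / a.coverage
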