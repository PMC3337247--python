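"""Cleavage-variant enumeration, mass matching and truncation-ladder analysis.

A lanthipeptide precursor is matured by leader-peptide proteolysis plus
dehydration of core Ser/Thr residues. Given a precursor sequence and a set of
observed neutral masses, this module enumerates candidate cleavage positions,
matches each (cleavage, dehydration-count) hypothesis to the observations,
applies Edman N-terminal constraints, explains inter-product mass differences
as single residues, and checks whether a family of products is consistent
with independent cleavage and/or successive N-terminal trimming.

Only the *count* of dehydrations is inferred, never which Ser/Thr carry
them — integer-Da mass data cannot localise modifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .masses import (
    NeutralMass,
    ResidueMassTable,
    STANDARD_TABLE,
    dehydrated_mass,
    residue_from_delta,
)
from .mining import MotifHit

__all__ = [
    "Prepeptide",
    "VariantAssignment",
    "LadderStep",
    "MatchResult",
    "RouteReport",
    "enumerate_variants",
    "default_cleavage_window",
    "match_masses",
    "apply_nterm_constraint",
    "ladder_infer",
    "processing_routes",
]


@dataclass(frozen=True)
class Prepeptide:
    """A full precursor (leader + core), residues numbered from 1."""

    full_seq: str
    leader_motif_hit: MotifHit | None = None

    def __len__(self) -> int:
        return len(self.full_seq)

    def core_after(self, cleavage_after: int) -> str:
        """Core sequence left by cleaving after 1-based residue index."""
        if not 1 <= cleavage_after <= len(self.full_seq) - 1:
            raise ValueError(
                f"cleavage_after={cleavage_after} outside 1..{len(self.full_seq) - 1}"
            )
        return self.full_seq[cleavage_after:]


@dataclass(frozen=True)
class VariantAssignment:
    """One (cleavage site, dehydration count) hypothesis matched to a mass.

    ``delta`` is observed minus theoretical, in Da.
    """

    cleavage_after: int
    core_seq: str
    n_dehydr: int
    theoretical_mass: float
    observed: NeutralMass
    delta: float

    @property
    def abs_delta(self) -> float:
        return abs(self.delta)


@dataclass(frozen=True)
class LadderStep:
    """Adjacent pair in a sorted mass ladder with residue candidates."""

    lighter_mass: float
    heavier_mass: float
    delta: float
    candidate_residues: frozenset[str]

    @property
    def explained(self) -> bool:
        return bool(self.candidate_residues)


@dataclass(frozen=True)
class MatchResult:
    """Assignments sorted best-first plus observations nothing matched."""

    assignments: tuple[VariantAssignment, ...]
    unmatched: tuple[NeutralMass, ...]

    def best_per_observation(self) -> dict[NeutralMass, VariantAssignment]:
        best: dict[NeutralMass, VariantAssignment] = {}
        for a in self.assignments:  # already sorted best-first
            best.setdefault(a.observed, a)
        return best


@dataclass(frozen=True)
class RouteReport:
    """Consistency of a product family with the two maturation routes.

    ``independent_cleavage``: the protease cut each site separately.
    ``sequential_trimming``: one distal cut followed by successive removal
    of single N-terminal residues (cores at consecutive cleavage sites).
    ``status`` is "ok" or "indeterminate" (fewer than two assignments).
    """

    independent_cleavage: bool
    sequential_trimming: bool
    status: str = "ok"


def enumerate_variants(
    pre: Prepeptide, window: tuple[int, int]
) -> list[tuple[int, str]]:
    """All (cleavage_after, core_seq) for sites in an inclusive 1-based window.

    ``window=(a, b)`` yields one variant per inter-residue position
    ``a..b``; an empty window (b < a) yields an empty list.
    """
    a, b = window
    if b < a:
        return []
    if a < 1 or b > len(pre.full_seq) - 1:
        raise ValueError(
            f"window {window} outside valid cleavage range 1..{len(pre.full_seq) - 1}"
        )
    return [(p, pre.core_after(p)) for p in range(a, b + 1)]


def default_cleavage_window(pre: Prepeptide, width: int = 10) -> tuple[int, int]:
    """Cleavage window: ``width`` positions centred on the leader-motif end.

    Leader-protease sites cluster a few residues C-terminal of the FDL[DN]
    box, so when the precursor carries a leader motif the search is centred
    on its last residue; without one the full sequence is searched.
    """
    n = len(pre.full_seq)
    if pre.leader_motif_hit is None:
        return (1, n - 1)
    centre = pre.leader_motif_hit.end_1based
    a = centre - (width - 1) // 2
    b = centre + width // 2
    return (max(1, a), min(n - 1, b))


def match_masses(
    variants: Sequence[tuple[int, str]],
    observed: Sequence[NeutralMass],
    max_dehydr: int | None = None,
    tol: float = 1.0,
    scale: str = "average",
    table: ResidueMassTable = STANDARD_TABLE,
) -> MatchResult:
    """Match dehydrated cleavage variants to observed neutral masses.

    For every variant and every dehydration count up to
    ``min(max_dehydr, Ser+Thr count of the core)`` (``max_dehydr=None``
    means the Ser+Thr count itself), an assignment is emitted when the
    theoretical mass falls within ``tol`` Da of an observation. Assignments
    are sorted by absolute mass error, then fewer dehydrations, then the
    more C-terminal cleavage site; near-ties are therefore adjacent in the
    output, never dropped. Observations with no assignment are returned in
    ``unmatched``. The result is invariant to input order.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    assignments = []
    hit_obs = set()
    for cleavage_after, core in variants:
        n_st = sum(core.count(a) for a in "ST")
        cap = n_st if max_dehydr is None else min(max_dehydr, n_st)
        for n in range(cap + 1):
            theo = dehydrated_mass(core, n, scale, table)
            for obs in observed:
                delta = obs.value - theo
                if abs(delta) <= tol:
                    assignments.append(
                        VariantAssignment(cleavage_after, core, n, theo, obs, delta)
                    )
                    hit_obs.add(id(obs))
    assignments.sort(key=lambda a: (a.abs_delta, a.n_dehydr, -a.cleavage_after))
    unmatched = tuple(o for o in observed if id(o) not in hit_obs)
    return MatchResult(tuple(assignments), unmatched)


def apply_nterm_constraint(
    assignments: Sequence[VariantAssignment], nterm: str
) -> list[VariantAssignment]:
    """Keep only assignments whose core starts with the Edman-read N-terminus."""
    if not nterm:
        raise ValueError("nterm must be non-empty")
    return [a for a in assignments if a.core_seq.startswith(nterm)]


def ladder_infer(
    masses: Sequence[float],
    tol: float = 1.0,
    scale: str = "average",
    table: ResidueMassTable = STANDARD_TABLE,
) -> list[LadderStep]:
    """Explain adjacent mass differences in a product family as residues.

    Masses are sorted ascending; each adjacent pair becomes a
    :class:`LadderStep` whose candidate set holds every residue within
    ``tol`` Da of the difference (Leu/Ile co-reported). Steps no single
    residue explains are retained with an empty candidate set. Only
    adjacent pairs are linked; multi-residue gaps are never decomposed.
    """
    if len(masses) < 2:
        raise ValueError("ladder_infer requires at least two masses")
    ordered = sorted(masses)
    steps = []
    for lo, hi in zip(ordered, ordered[1:]):
        delta = hi - lo
        cands = (
            residue_from_delta(delta, tol, scale, table)
            if delta > 0
            else frozenset()
        )
        steps.append(LadderStep(lo, hi, delta, cands))
    return steps


def processing_routes(
    assignments: Sequence[VariantAssignment], pre: Prepeptide
) -> RouteReport:
    """Test a product family against the two leader-removal mechanisms.

    Route (a), independent cleavage, is consistent whenever the assignments
    sit at distinct sites of the one precursor. Route (b), a single distal
    cut followed by stepwise single-residue N-terminal trimming, requires
    the cleavage sites to be consecutive integers (each consecutive pair of
    cores differs by exactly one leading residue). Both can hold at once;
    one assignment is indeterminate.
    """
    for a in assignments:
        if pre.core_after(a.cleavage_after) != a.core_seq:
            raise ValueError(
                f"assignment at site {a.cleavage_after} is not a suffix of "
                "the given precursor"
            )
    if len(assignments) < 2:
        return RouteReport(False, False, status="indeterminate")
    sites = sorted({a.cleavage_after for a in assignments})
    independent = len(sites) == len(assignments)
    sequential = all(b - a == 1 for a, b in zip(sites, sites[1:]))
    return RouteReport(independent, sequential)
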