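"""High-level stage glue: FASTA/signals in, clusters/assignments out.

These functions are what the CLI subcommands call; they are equally usable
from Python and keep the CLI itself a thin argument-parsing layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .masses import ChargeSignal, NeutralMass, consensus_mass
from .matching import (
    MatchResult,
    Prepeptide,
    RouteReport,
    VariantAssignment,
    apply_nterm_constraint,
    default_cleavage_window,
    enumerate_variants,
    match_masses,
    processing_routes,
)
from .mining import GeneCluster, Orf, assemble_cluster, classify_role, find_orfs

__all__ = ["MineOutput", "MatchOutput", "build_prepeptide", "deconvolute_signals", "mine_dna", "match_precursor"]


@dataclass(frozen=True)
class MineOutput:
    orfs: tuple[Orf, ...]
    roles: dict[Orf, str]
    clusters: tuple[GeneCluster, ...]


@dataclass(frozen=True)
class MatchOutput:
    """Best assignment per product plus everything the matcher saw."""

    best: tuple[tuple[str, VariantAssignment], ...]
    all_assignments: tuple[tuple[str, VariantAssignment], ...]
    unmatched: tuple[str, ...]
    route: RouteReport


def build_prepeptide(seq: str) -> Prepeptide:
    """Wrap a precursor sequence, locating its FDL[DN] leader motif if any.

    The first motif occurrence wholly inside the N-terminal half counts as
    the leader motif; core-side occurrences are ignored.
    """
    from .mining import scan_motifs

    hits = [
        h
        for h in scan_motifs(seq, ["leader_FDLX"])
        if h.end_1based <= len(seq) // 2
    ]
    return Prepeptide(full_seq=seq, leader_motif_hit=hits[0] if hits else None)


def deconvolute_signals(
    rows: Sequence[tuple[str, ChargeSignal]],
    scale: str = "average",
    consistency_window: float = 3.0,
) -> dict[str, NeutralMass]:
    """Group signals by peptide id and deconvolve each group to one mass."""
    grouped: dict[str, list[ChargeSignal]] = {}
    for pid, sig in rows:
        grouped.setdefault(pid, []).append(sig)
    return {
        pid: consensus_mass(sigs, scale=scale, consistency_window=consistency_window)
        for pid, sigs in grouped.items()
    }


def mine_dna(
    dna: str,
    contig_id: str = "contig",
    min_aa: int = 25,
    starts: Sequence[str] = ("ATG", "GTG", "TTG"),
    max_gap_bp: int = 2000,
) -> MineOutput:
    """ORF-call one contig, classify roles, assemble lanthipeptide clusters."""
    orfs = find_orfs(dna, min_aa=min_aa, starts=starts, contig_id=contig_id)
    roles = {o: classify_role(o) for o in orfs}
    clusters = assemble_cluster(orfs, roles, max_gap_bp=max_gap_bp)
    return MineOutput(tuple(orfs), roles, tuple(clusters))


def match_precursor(
    precursor: Prepeptide | str,
    observed: Mapping[str, NeutralMass],
    nterm: str | None = None,
    tol: float = 1.0,
    scale: str = "average",
    max_dehydr: int | None = None,
    window: tuple[int, int] | None = None,
) -> MatchOutput:
    """Assign each observed neutral mass to a (cleavage, dehydration) variant.

    The cleavage window defaults to ten positions around the end of the
    leader motif (full sequence if the precursor has none). An optional
    Edman N-terminal read filters candidate cores before ranking. ``best``
    holds the top-ranked surviving assignment for each product that has one.
    """
    pre = build_prepeptide(precursor) if isinstance(precursor, str) else precursor
    if window is None:
        window = default_cleavage_window(pre)
    variants = enumerate_variants(pre, window)
    result: MatchResult = match_masses(
        variants, list(observed.values()), max_dehydr=max_dehydr, tol=tol, scale=scale
    )
    assignments = list(result.assignments)
    if nterm:
        assignments = apply_nterm_constraint(assignments, nterm)

    mass_to_pid = {id(m): pid for pid, m in observed.items()}
    all_rows = tuple((mass_to_pid[id(a.observed)], a) for a in assignments)
    best: dict[str, VariantAssignment] = {}
    for pid, a in all_rows:  # sorted best-first by match_masses
        best.setdefault(pid, a)
    best_rows = tuple(
        (pid, best[pid]) for pid in observed if pid in best
    )
    unmatched = tuple(pid for pid in observed if pid not in best)
    route = processing_routes([a for _, a in best_rows], pre) if len(
        best_rows
    ) >= 2 else RouteReport(False, False, status="indeterminate")
    return MatchOutput(best_rows, all_rows, unmatched, route)
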