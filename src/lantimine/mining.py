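"""ORF calling, conserved-motif scanning and lanthipeptide cluster assembly.

A type AI lanthipeptide locus is recognisable from sequence alone: a LanC-like
cyclase carrying the GxxHG / WCxG / CHG motifs (invariant His and Cys), a very
large LanB-like dehydratase, ABC-transporter genes with Walker-A boxes, and a
short precursor whose leader contains the FDL[DN] motif. This module finds
ORFs in all six frames, scans their translations for those motifs, assigns
heuristic biosynthetic roles and groups neighbouring role-carrying ORFs into
clusters anchored on a cyclase.

ORF coordinates are 0-based half-open on the forward strand of the contig
(the interval includes the stop codon). Motif hits are reported 1-based
inclusive, matching how protein positions are quoted in the literature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "Orf",
    "MotifHit",
    "GeneCluster",
    "MOTIF_PATTERNS",
    "DEFAULT_START_CODONS",
    "find_orfs",
    "scan_motifs",
    "classify_role",
    "assemble_cluster",
]

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_DNA_OK = set("ACGTN")


@dataclass(frozen=True, order=True)
class Orf:
    """A called open reading frame.

    ``start``/``end`` are 0-based half-open forward-strand coordinates and
    include the stop codon; ``aa_seq`` is the translation without the stop,
    with the initiator codon rendered as Met regardless of which start codon
    was used (ORF-finder convention).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ORF end must exceed start")
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if "*" in self.aa_seq:
            raise ValueError("aa_seq must not contain stop characters")
        if len(self.aa_seq) != self.length_aa:
            raise ValueError("aa_seq length inconsistent with coordinates")

    @property
    def length_aa(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass(frozen=True)
class MotifHit:
    """A conserved-motif match, 1-based inclusive protein coordinates."""

    pattern_id: str
    start_1based: int
    end_1based: int
    matched: str

    def __post_init__(self) -> None:
        if self.end_1based - self.start_1based + 1 != len(self.matched):
            raise ValueError("motif hit span inconsistent with matched string")


@dataclass(frozen=True)
class GeneCluster:
    """An ordered, stranded group of role-annotated ORFs.

    ``roles`` is aligned with ``orfs``; ``overlaps`` records every pair of
    member ORFs whose genomic intervals genuinely intersect, as
    ``(index_i, index_j, bp)`` with ``bp > 0``.
    """

    orfs: tuple[Orf, ...]
    roles: tuple[str, ...]
    overlaps: tuple[tuple[int, int, int], ...]

    def role_of(self, role: str) -> list[Orf]:
        return [o for o, r in zip(self.orfs, self.roles) if r == role]

    @property
    def strand_pattern(self) -> str:
        return "".join(o.strand for o in self.orfs)


# Conserved patterns. The cyclase motifs require only the residues that are
# strictly conserved across LanC-family enzymes (His in GxxHG, Cys in WCxG,
# Cys+His in CHG): literal third-position patterns would reject genuine
# instances such as GVSHG.
MOTIF_PATTERNS: dict[str, str] = {
    "leader_FDLX": r"FDL[DN]",
    "cyclase_GxxHG": r"G..HG",
    "cyclase_WCxG": r"WC.G",
    "cyclase_CHG": r"CHG",
}

_WALKER_A = re.compile(r"G..G.GK[ST]")


def _validate_dna(dna: str) -> str:
    dna = dna.upper()
    for i, c in enumerate(dna):
        if c not in _DNA_OK:
            raise ValueError(f"non-IUPAC nucleotide {c!r} at position {i + 1}")
    return dna


def _translate(codon_seq: str) -> str:
    aa = str(Seq(codon_seq).translate(table=1))
    return "M" + aa[1:]  # initiator codon reported as Met


def _orfs_one_strand(
    dna: str, contig_id: str, strand: str, min_aa: int, starts: frozenset[str]
) -> list[Orf]:
    """Maximal start-to-stop ORFs on one strand of ``dna``.

    ``dna`` is already the strand to read; minus-strand coordinates are
    reflected back onto the forward strand by the caller.
    """
    n = len(dna)
    out = []
    for frame in range(3):
        pending_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = dna[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending_start is not None:
                    s, e = pending_start, pos + 3
                    if (e - s) // 3 - 1 >= min_aa:
                        if strand == "+":
                            fs, fe = s, e
                        else:
                            fs, fe = n - e, n - s
                        out.append(
                            Orf(contig_id, fs, fe, strand, _translate(dna[s : e - 3]))
                        )
                    pending_start = None
            elif pending_start is None and codon in starts:
                pending_start = pos
    return out


def find_orfs(
    dna: str,
    min_aa: int = 25,
    starts: Iterable[str] = DEFAULT_START_CODONS,
    contig_id: str = "contig",
) -> list[Orf]:
    """Call all maximal start-to-stop ORFs in all six frames.

    An ORF runs from the first start codon after the previous in-frame stop
    to (and including) the next in-frame stop, and must encode at least
    ``min_aa`` residues. Overlapping ORFs, including same-strand overlaps in
    different frames, are all reported. Results are sorted by forward-strand
    start coordinate.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    dna = _validate_dna(dna)
    starts = frozenset(s.upper() for s in starts)
    rc = str(Seq(dna).reverse_complement())
    orfs = _orfs_one_strand(dna, contig_id, "+", min_aa, starts)
    orfs += _orfs_one_strand(rc, contig_id, "-", min_aa, starts)
    return sorted(orfs, key=lambda o: (o.start, o.end, o.strand))


def scan_motifs(
    protein: str, patterns: Iterable[str] | None = None
) -> list[MotifHit]:
    """Find every (possibly overlapping) conserved-motif match in a protein.

    ``patterns`` selects pattern ids from :data:`MOTIF_PATTERNS`; default all.
    Hits are reported with 1-based inclusive coordinates, sorted by position.
    """
    ids = list(MOTIF_PATTERNS) if patterns is None else list(patterns)
    unknown = [p for p in ids if p not in MOTIF_PATTERNS]
    if unknown:
        raise KeyError(f"unknown pattern ids: {unknown}")
    hits = []
    for pid in ids:
        rx = re.compile(f"(?=({MOTIF_PATTERNS[pid]}))")
        for m in rx.finditer(protein):
            matched = m.group(1)
            hits.append(
                MotifHit(pid, m.start() + 1, m.start() + len(matched), matched)
            )
    return sorted(hits, key=lambda h: (h.start_1based, h.pattern_id))


def _has_cyclase_triad(protein: str) -> bool:
    """True if GxxHG, WCxG and CHG all occur, in that N-to-C order."""
    hits = scan_motifs(protein, ["cyclase_GxxHG", "cyclase_WCxG", "cyclase_CHG"])
    by = lambda pid: [h.start_1based for h in hits if h.pattern_id == pid]
    for g in by("cyclase_GxxHG"):
        for w in by("cyclase_WCxG"):
            if w > g:
                for c in by("cyclase_CHG"):
                    if c > w:
                        return True
    return False


def classify_role(orf: Orf, precursor_max_aa: int = 100) -> str:
    """Heuristic biosynthetic role of an ORF's product.

    Rules, in priority order:

    * ``cyclase_like`` — all three LanC motifs present in N-to-C order;
    * ``precursor`` — at most ``precursor_max_aa`` residues with an FDL[DN]
      leader motif in the N-terminal half;
    * ``dehydratase_like`` — LanB-sized (>= 800 aa) and not a cyclase;
    * ``transporter_like`` — Walker-A box (GxxGxGK[S/T]) and 400-800 aa;
      a sequence heuristic, not a homology call;
    * ``unknown`` otherwise.
    """
    aa = orf.aa_seq
    if _has_cyclase_triad(aa):
        return "cyclase_like"
    if orf.length_aa <= precursor_max_aa:
        half = len(aa) // 2
        leader_hits = [
            h
            for h in scan_motifs(aa, ["leader_FDLX"])
            if h.end_1based <= half
        ]
        if leader_hits:
            return "precursor"
    if orf.length_aa >= 800:
        return "dehydratase_like"
    if 400 <= orf.length_aa <= 800 and _WALKER_A.search(aa):
        return "transporter_like"
    return "unknown"


def _overlaps(members: Sequence[Orf]) -> tuple[tuple[int, int, int], ...]:
    out = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            bp = min(a.end, b.end) - max(a.start, b.start)
            if bp > 0:
                out.append((i, j, bp))
    return tuple(out)


def assemble_cluster(
    orfs: Sequence[Orf],
    roles: Mapping[Orf, str] | None = None,
    max_gap_bp: int = 2000,
) -> list[GeneCluster]:
    """Group role-carrying ORFs into cyclase-anchored clusters.

    ORFs classified ``unknown`` do not join clusters. Neighbours whose
    pairwise gap is at most ``max_gap_bp`` form one group; a group is
    reported as a cluster only if it contains at least one cyclase_like and
    one precursor ORF. Input order is irrelevant (members are sorted by
    start). Absence of any cyclase anchor yields an empty list, not an error.
    """
    if roles is None:
        roles = {o: classify_role(o) for o in orfs}
    contigs = {o.contig_id for o in orfs}
    if len(contigs) > 1:
        raise ValueError(f"all ORFs must be on one contig, got {sorted(contigs)}")
    annotated = sorted(
        (o for o in orfs if roles[o] != "unknown"), key=lambda o: (o.start, o.end)
    )
    clusters: list[GeneCluster] = []
    group: list[Orf] = []

    def flush() -> None:
        role_set = {roles[o] for o in group}
        if "cyclase_like" in role_set and "precursor" in role_set:
            clusters.append(
                GeneCluster(
                    orfs=tuple(group),
                    roles=tuple(roles[o] for o in group),
                    overlaps=_overlaps(group),
                )
            )

    for orf in annotated:
        if group and orf.start - max(o.end for o in group) > max_gap_bp:
            flush()
            group = []
        group.append(orf)
    if group:
        flush()
    return clusters
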