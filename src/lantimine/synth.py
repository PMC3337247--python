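"""Seeded generators of lanthipeptide loci, product ladders and ESI signals.

Every pipeline stage needs inputs with known ground truth: a gene cluster
whose ORF layout, strands and overlaps are planted; a precursor whose leader
motif, cleavage sites and dehydration counts are chosen up front; and picked
(m/z, z) signal lists derived from those products, optionally with Gaussian
m/z noise. All generators are deterministic functions of their seed.

The emulated locus follows the canonical type AI organisation: two
ABC-transporter genes, a LanC-like cyclase, a very large LanB-like
dehydratase overlapping its upstream neighbour by 4 bp on the same strand,
and a short precursor gene; the first transporter is transcribed on the
opposite strand.

The cluster generator *guarantees* its layout is recoverable: each candidate
contig is checked with the package's own ORF caller and role classifier, and
redrawn from a derived subseed if random sequence happens to create a
spurious role-carrying ORF or an ORF-boundary artifact (for example an
upstream in-frame start codon that would absorb the overlapping gene).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .masses import dehydrated_mass, mz_from_mass, ChargeSignal
from .matching import Prepeptide
from .mining import (
    MotifHit,
    Orf,
    assemble_cluster,
    classify_role,
    find_orfs,
)

__all__ = [
    "SyntheticTruth",
    "gen_precursor",
    "gen_cluster_dna",
    "gen_product_ladder",
    "gen_signals",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# Residues safe to substitute when erasing accidental motif matches: none of
# them can complete a cyclase (G/H/C/W) pattern.
_SCRUB_SAFE = "AEQRPK"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()
_STOPS = ("TAA", "TAG", "TGA")

# Stop codons in all six frames, no start codons in any frame: safe
# intergenic punctuation that pins every gene's called boundaries.
_SPACER = "CTAG" * 5

_CYCLASE_RX = [re.compile(p) for p in (r"G..HG", r"WC.G", r"CHG")]

_CLUSTER_ROLES = (
    "transporter_like",
    "cyclase_like",
    "transporter_like",
    "dehydratase_like",
    "precursor",
)
_CLUSTER_LENGTHS = (596, 454, 625, 1037, 64)
_CLUSTER_STRANDS = ("-", "+", "+", "+", "+")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying generated data."""

    seed: int
    precursor: Prepeptide | None = None
    leader_len: int | None = None
    cleavage_sites: list[int] = field(default_factory=list)
    n_dehydr: int | None = None
    #: per ORF in genomic order: (role, length_aa, strand, overlap_next_bp)
    cluster_layout: list[tuple[str, int, str, int]] = field(default_factory=list)
    #: per ORF in genomic order: forward-strand (start, end, strand)
    orf_coords: list[tuple[int, int, str]] = field(default_factory=list)


def _rand_protein(rng: np.random.Generator, n: int) -> list[str]:
    return [_AA[i] for i in rng.integers(0, len(_AA), n)]


def gen_precursor(
    seed: int, leader_len: int = 21, core_len: int = 43
) -> tuple[Prepeptide, SyntheticTruth]:
    """Random precursor with an FDL[DN] leader and a Ser/Thr/Cys-rich core.

    The peptide starts with Met, carries the FDL[DN] box late in the leader
    (protease sites cluster just C-terminal of it), and its core holds at
    least 8 Ser/Thr and 2 Cys — enough substrate for eight dehydrations and
    two thioether rings. Default dimensions give the canonical 64-residue
    precursor. The recorded cleavage sites bracket the leader/core boundary:
    ``leader_len - 1 .. leader_len + 2``.
    """
    if leader_len < 6:
        raise ValueError("leader_len must be >= 6 to host the FDL[DN] motif")
    if core_len < 10:
        raise ValueError("core_len must be >= 10 to host Ser/Thr/Cys content")
    rng = np.random.default_rng([seed, 11])
    leader = _rand_protein(rng, leader_len)
    leader[0] = "M"
    m0 = max(2, leader_len - 6)  # 1-based start of the planted motif
    motif = "FDL" + ("D" if rng.integers(0, 2) == 0 else "N")
    leader[m0 - 1 : m0 + 3] = list(motif)

    core = _rand_protein(rng, core_len)
    # Plant S/T and C deep enough that N-terminal trimming at the recorded
    # sites (up to 3 residues into the core) never removes them.
    depth = 4
    special = rng.choice(np.arange(depth, core_len), size=10, replace=False)
    for idx in special[:8]:
        core[idx] = "ST"[rng.integers(0, 2)]
    for idx in special[8:]:
        core[idx] = "C"

    full = "".join(leader) + "".join(core)
    hit = MotifHit("leader_FDLX", m0, m0 + 3, motif)
    assert full[m0 - 1 : m0 + 3] == motif
    pre = Prepeptide(full_seq=full, leader_motif_hit=hit)
    truth = SyntheticTruth(
        seed=seed,
        precursor=pre,
        leader_len=leader_len,
        cleavage_sites=[leader_len - 1, leader_len, leader_len + 1, leader_len + 2],
    )
    return pre, truth


def _scrub_motifs(
    protein: list[str],
    rng: np.random.Generator,
    protected: list[tuple[int, int]],
    max_rounds: int = 500,
) -> None:
    """Erase accidental cyclase-motif matches in place (0-based spans kept)."""

    def is_protected(i: int) -> bool:
        return any(a <= i < b for a, b in protected)

    seq = "".join(protein)
    for _ in range(max_rounds):
        hit = None
        for rx in _CYCLASE_RX:
            m = rx.search(seq)
            if m:
                hit = m
                break
        if hit is None:
            return
        free = [i for i in range(hit.start(), hit.end()) if not is_protected(i)]
        if not free:  # cannot happen: protected spans contain no full motif
            raise RuntimeError("motif fully inside protected span")
        pos = free[rng.integers(0, len(free))]
        protein[pos] = _SCRUB_SAFE[rng.integers(0, len(_SCRUB_SAFE))]
        seq = "".join(protein)
    raise RuntimeError("motif scrubbing did not converge")


def _plant_walker_a(protein: list[str], rng: np.random.Generator, pos: int) -> tuple[int, int]:
    """Plant a Walker-A box G-x-x-G-x-G-K-[ST] at 0-based ``pos``."""
    x = lambda: _SCRUB_SAFE[rng.integers(0, len(_SCRUB_SAFE))]
    box = ["G", x(), x(), "G", x(), "G", "K", "ST"[rng.integers(0, 2)]]
    protein[pos : pos + 8] = box
    return (pos, pos + 8)


def _backtranslate(
    protein: str, rng: np.random.Generator, forced: dict[int, str] | None = None
) -> str:
    """Back-translate with uniformly random synonymous codons (seeded)."""
    forced = forced or {}
    codons = []
    for i, aa in enumerate(protein):
        if i in forced:
            codons.append(forced[i])
        else:
            opts = _CODONS_FOR[aa]
            codons.append(opts[rng.integers(0, len(opts))])
    return "".join(codons)


def _build_cluster_attempt(
    seed: int, attempt: int
) -> tuple[str, SyntheticTruth]:
    rng = np.random.default_rng([seed, attempt, 23])

    # Proteins, genomic order: T1(-), cyclase(+), T2(+), dehydratase(+), A(+)
    t1 = _rand_protein(rng, _CLUSTER_LENGTHS[0])
    t1[0] = "M"
    wa1 = _plant_walker_a(t1, rng, 40)
    _scrub_motifs(t1, rng, [wa1])

    cy = _rand_protein(rng, _CLUSTER_LENGTHS[1])
    cy[0] = "M"
    cy[243:248] = list("GVSHG")  # 1-based 244-248
    cy[315:319] = list("WCYG")  # 1-based 316-319
    cy[365:368] = list("CHG")  # 1-based 366-368

    t2 = _rand_protein(rng, _CLUSTER_LENGTHS[2])
    t2[0] = "M"
    t2[-1] = "K"  # codon AAA: gene then ends AAA+TGA, giving the ATGA overlap
    wa2 = _plant_walker_a(t2, rng, 40)
    _scrub_motifs(t2, rng, [wa2, (len(t2) - 1, len(t2))])

    de = _rand_protein(rng, _CLUSTER_LENGTHS[3])
    de[0] = "M"
    de[1] = "K"  # codon AAA: gene starts ATG AAA, matching the ATGA overlap
    _scrub_motifs(de, rng, [(0, 2)])

    pre, pre_truth = gen_precursor(seed)

    t1_dna = _backtranslate("".join(t1), rng) + _STOPS[rng.integers(0, 3)]
    cy_dna = _backtranslate("".join(cy), rng) + _STOPS[rng.integers(0, 3)]
    t2_dna = _backtranslate("".join(t2), rng, forced={len(t2) - 1: "AAA"}) + "TGA"
    de_dna = _backtranslate("".join(de), rng, forced={1: "AAA"}) + _STOPS[
        rng.integers(0, 3)
    ]
    a_dna = _backtranslate(pre.full_seq, rng) + _STOPS[rng.integers(0, 3)]
    assert t2_dna[-4:] == "ATGA" and de_dna[:4] == "ATGA"

    parts = []
    coords: list[tuple[int, int, str]] = []
    pos = 0

    def put(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    put(_SPACER)
    coords.append((pos, pos + len(t1_dna), "-"))
    put(str(Seq(t1_dna).reverse_complement()))
    put(_SPACER)
    coords.append((pos, pos + len(cy_dna), "+"))
    put(cy_dna)
    put(_SPACER)
    coords.append((pos, pos + len(t2_dna), "+"))
    put(t2_dna)
    # 4-bp same-strand overlap: the dehydratase gene starts 4 bp before the
    # end of the upstream transporter gene.
    coords.append((pos - 4, pos - 4 + len(de_dna), "+"))
    put(de_dna[4:])
    put(_SPACER)
    coords.append((pos, pos + len(a_dna), "+"))
    put(a_dna)
    put(_SPACER)

    contig = "".join(parts)
    truth = SyntheticTruth(
        seed=seed,
        precursor=pre,
        leader_len=pre_truth.leader_len,
        cleavage_sites=pre_truth.cleavage_sites,
        cluster_layout=[
            (role, length, strand, 4 if i == 2 else 0)
            for i, (role, length, strand) in enumerate(
                zip(_CLUSTER_ROLES, _CLUSTER_LENGTHS, _CLUSTER_STRANDS)
            )
        ],
        orf_coords=coords,
    )
    return contig, truth


def _attempt_is_recoverable(contig: str, truth: SyntheticTruth) -> bool:
    """Mine the candidate contig and demand exact planted-layout recovery."""
    orfs = find_orfs(contig, min_aa=25)
    roles = {o: classify_role(o) for o in orfs}
    clusters = assemble_cluster(orfs, roles)
    if len(clusters) != 1:
        return False
    cl = clusters[0]
    if len(cl.orfs) != 5 or cl.roles != _CLUSTER_ROLES:
        return False
    found = [(o.start, o.end, o.strand) for o in cl.orfs]
    if found != truth.orf_coords:
        return False
    if cl.overlaps != ((2, 3, 4),):
        return False
    assert truth.precursor is not None
    return cl.orfs[4].aa_seq == truth.precursor.full_seq


def gen_cluster_dna(seed: int, max_attempts: int = 64) -> tuple[str, SyntheticTruth]:
    """One contig encoding the five-gene locus, with planted ground truth.

    Returns the contig sequence and a :class:`SyntheticTruth` whose
    ``orf_coords``/``cluster_layout`` describe the planted genes in genomic
    order (transporter on the minus strand, cyclase, transporter,
    dehydratase overlapping it by exactly 4 bp, 64-aa precursor). The
    returned contig always mines back to exactly this layout.
    """
    for attempt in range(max_attempts):
        contig, truth = _build_cluster_attempt(seed, attempt)
        if _attempt_is_recoverable(contig, truth):
            return contig, truth
    raise RuntimeError(
        f"no recoverable cluster in {max_attempts} attempts for seed {seed}"
    )


def gen_product_ladder(
    pre: Prepeptide,
    sites: list[int],
    n_dehydr: int,
    scale: str = "average",
) -> list[tuple[str, float]]:
    """Truncation-ladder products from consecutive cleavage sites.

    One product per site, each dehydrated ``n_dehydr`` times; adjacent
    products differ by exactly one leading residue. Sites must be
    consecutive ascending integers.
    """
    if len(sites) < 1:
        raise ValueError("at least one cleavage site required")
    if any(b - a != 1 for a, b in zip(sites, sites[1:])):
        raise ValueError(f"cleavage sites must be consecutive, got {sites}")
    out = []
    for site in sites:
        core = pre.core_after(site)
        out.append((core, dehydrated_mass(core, n_dehydr, scale)))
    return out


def gen_signals(
    masses: list[float],
    charges: tuple[int, ...] = (3, 4),
    noise_sd: float = 0.0,
    seed: int = 0,
    ids: list[str] | None = None,
) -> list[tuple[str, ChargeSignal]]:
    """Picked (m/z, z) signals for each neutral mass at each charge state.

    Noise is Gaussian in m/z space (instrument-like), standard deviation
    ``noise_sd`` Thomson; ``noise_sd=0`` gives exact theoretical positions.
    Rows are ``(peptide_id, ChargeSignal)``, deterministic in ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if ids is None:
        ids = [f"p{i + 1}" for i in range(len(masses))]
    if len(ids) != len(masses):
        raise ValueError("ids and masses must have equal length")
    rng = np.random.default_rng([seed, 37])
    rows = []
    for pid, m in zip(ids, masses):
        for z in sorted(charges):
            mz = mz_from_mass(m, z) + float(rng.normal(0.0, noise_sd or 0.0))
            rows.append((pid, ChargeSignal(mz=mz, z=int(z))))
    return rows
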