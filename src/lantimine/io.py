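"""Readers, writers and run configuration.

Formats are deliberately boring: multi-record FASTA for sequences
(Biopython-backed), headered TSV for picked signals and for variant
assignments (tab-separated to keep sequences comma-free), GFF3 for cluster
annotation, and a flat key-value sidecar for synthetic ground truth. All
text is UTF-8 with Unix newlines; masses are written with 4 decimals so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masses import ChargeSignal
from .matching import RouteReport, VariantAssignment
from .mining import GeneCluster
from .synth import SyntheticTruth
from .matching import Prepeptide

logger = logging.getLogger("lantimine")

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_signals",
    "write_signals",
    "write_gff",
    "write_cluster_summary",
    "write_assignments",
    "read_assignments",
    "write_truth",
    "read_truth",
]

_DNA_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

SIGNAL_COLUMNS = ("peptide_id", "mz", "z")
ASSIGNMENT_COLUMNS = (
    "product_id",
    "cleavage_after",
    "core_seq",
    "n_dehydr",
    "theoretical_mass",
    "observed_mass",
    "delta",
    "route_independent_cleavage",
    "route_sequential_trimming",
)


@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline parameters; logged at the start of every run."""

    scale: str = "average"
    tol_da: float = 1.0
    max_dehydr: int | str = "auto"
    min_aa: int = 25
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG")
    max_gap_bp: int = 2000
    seed: int = 0
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.scale not in ("average", "monoisotopic"):
            raise ValueError(f"invalid scale {self.scale!r}")
        if self.tol_da <= 0:
            raise ValueError("tol_da must be positive")
        if self.max_dehydr != "auto" and (
            not isinstance(self.max_dehydr, int) or self.max_dehydr < 0
        ):
            raise ValueError("max_dehydr must be 'auto' or a non-negative integer")
        if self.min_aa < 1:
            raise ValueError("min_aa must be positive")
        if self.max_gap_bp < 1:
            raise ValueError("max_gap_bp must be positive")
        if self.log_level not in ("debug", "info", "warn"):
            raise ValueError(f"invalid log_level {self.log_level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Strict config load: unknown keys are fatal, never ignored."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "start_codons" in raw:
            raw["start_codons"] = tuple(str(c).upper() for c in raw["start_codons"])
        return cls(**raw)

    def log(self) -> None:
        logger.info("run config: %s", dataclasses.asdict(self))


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[tuple[str, str]]:
    """Read a multi-record FASTA as ``[(id, SEQUENCE), ...]``.

    Sequences are uppercased; the ID is the first whitespace-delimited
    header token. Empty files, duplicate IDs and (when ``alphabet`` is
    ``"dna"`` or ``"protein"``) illegal characters are distinct errors.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [i for i, _ in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"duplicate FASTA ids in {path}: {dups}")
    if alphabet is not None:
        allowed = {"dna": _DNA_ALPHABET, "protein": _PROTEIN_ALPHABET}[alphabet]
        for rid, seq in records:
            bad = sorted(set(seq) - allowed)
            if bad:
                raise ValueError(
                    f"illegal {alphabet} characters {bad} in record {rid!r} of {path}"
                )
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w", newline="\n") as fh:
        for rec in seqrecs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_signals(path: str | Path) -> list[tuple[str, ChargeSignal]]:
    """Read a headered signal TSV (columns ``peptide_id  mz  z``).

    Malformed rows are reported with their 1-based line numbers; a file
    with a valid header but no valid rows is an error.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty signal file {path}")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != SIGNAL_COLUMNS:
        raise ValueError(
            f"bad signal header in {path}: expected {SIGNAL_COLUMNS}, got {header}"
        )
    rows: list[tuple[str, ChargeSignal]] = []
    bad: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            if len(parts) != 3:
                raise ValueError("expected 3 tab-separated fields")
            pid, mz_s, z_s = parts
            rows.append((pid, ChargeSignal(mz=float(mz_s), z=int(z_s))))
        except ValueError as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ValueError(f"malformed signal rows in {path}: " + "; ".join(bad))
    if not rows:
        raise ValueError(f"no signal rows in {path}")
    return rows


def write_signals(rows: Iterable[tuple[str, ChargeSignal]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(SIGNAL_COLUMNS) + "\n")
        for pid, sig in rows:
            fh.write(f"{pid}\t{sig.mz:.4f}\t{sig.z}\n")


def _gff_attrs(idx: int, role: str, orf_len: int) -> str:
    attrs = f"ID=orf_{idx};role={role};length_aa={orf_len}"
    if role == "transporter_like":
        attrs += ";note=walker_a_heuristic"
    return attrs


def write_gff(clusters: Sequence[GeneCluster], path: str | Path, source: str = "lantimine") -> None:
    """Write clusters as GFF3 (1-based inclusive coordinates, role attrs)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        n = 0
        for ci, cl in enumerate(clusters, start=1):
            for orf, role in zip(cl.orfs, cl.roles):
                n += 1
                fh.write(
                    "\t".join(
                        [
                            orf.contig_id,
                            source,
                            "gene",
                            str(orf.start + 1),
                            str(orf.end),
                            ".",
                            orf.strand,
                            ".",
                            _gff_attrs(n, role, orf.length_aa) + f";cluster=c{ci}",
                        ]
                    )
                    + "\n"
                )


def write_cluster_summary(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("cluster_id\tmember\tstart\tend\tstrand\tlength_aa\trole\toverlap_bp\n")
        for ci, cl in enumerate(clusters, start=1):
            over = {(i, j): bp for i, j, bp in cl.overlaps}
            for k, (orf, role) in enumerate(zip(cl.orfs, cl.roles)):
                bp = over.get((k, k + 1), 0)
                fh.write(
                    f"c{ci}\t{k + 1}\t{orf.start}\t{orf.end}\t{orf.strand}"
                    f"\t{orf.length_aa}\t{role}\t{bp}\n"
                )


def write_assignments(
    rows: Iterable[tuple[str, VariantAssignment]],
    path: str | Path,
    route: RouteReport | None = None,
) -> None:
    """Write matched variants as TSV, one row per (product, assignment)."""
    ri = "" if route is None else str(route.independent_cleavage)
    rs = "" if route is None else str(route.sequential_trimming)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for pid, a in rows:
            fh.write(
                f"{pid}\t{a.cleavage_after}\t{a.core_seq}\t{a.n_dehydr}"
                f"\t{a.theoretical_mass:.4f}\t{a.observed.value:.4f}"
                f"\t{a.delta:.4f}\t{ri}\t{rs}\n"
            )


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != ASSIGNMENT_COLUMNS:
        raise ValueError(f"bad assignment columns in {path}: {tuple(df.columns)}")
    return df


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Ground-truth sidecar: one ``key = value`` per line."""
    lines = ["# lantimine ground truth v1", f"seed = {truth.seed}"]
    if truth.precursor is not None:
        lines.append(f"precursor = {truth.precursor.full_seq}")
        hit = truth.precursor.leader_motif_hit
        if hit is not None:
            lines.append(
                f"leader_motif = {hit.matched},{hit.start_1based},{hit.end_1based}"
            )
    if truth.leader_len is not None:
        lines.append(f"leader_len = {truth.leader_len}")
    if truth.cleavage_sites:
        lines.append(
            "cleavage_sites = " + ",".join(str(s) for s in truth.cleavage_sites)
        )
    if truth.n_dehydr is not None:
        lines.append(f"n_dehydr = {truth.n_dehydr}")
    for (role, length, strand, over), (s, e, _) in zip(
        truth.cluster_layout, truth.orf_coords
    ):
        lines.append(f"orf = {role},{length},{strand},{over},{s},{e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    from .mining import MotifHit

    kv: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(" = ")
        kv.append((key, value))
    d = dict(kv)
    hit = None
    if "leader_motif" in d:
        matched, s, e = d["leader_motif"].split(",")
        hit = MotifHit("leader_FDLX", int(s), int(e), matched)
    pre = (
        Prepeptide(d["precursor"], leader_motif_hit=hit)
        if "precursor" in d
        else None
    )
    truth = SyntheticTruth(seed=int(d["seed"]), precursor=pre)
    if "leader_len" in d:
        truth.leader_len = int(d["leader_len"])
    if "cleavage_sites" in d:
        truth.cleavage_sites = [int(x) for x in d["cleavage_sites"].split(",")]
    if "n_dehydr" in d:
        truth.n_dehydr = int(d["n_dehydr"])
    for key, value in kv:
        if key == "orf":
            role, length, strand, over, s, e = value.split(",")
            truth.cluster_layout.append((role, int(length), strand, int(over)))
            truth.orf_coords.append((int(s), int(e), strand))
    return truth
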