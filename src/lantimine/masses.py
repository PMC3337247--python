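"""Peptide mass arithmetic and ESI charge-state deconvolution.

Everything downstream of the mass spectrometer lives here: average and
monoisotopic peptide masses, [M+zH]z+ deconvolution, consensus neutral
masses across charge states, dehydration-count inference from mass
deficits, and single-residue explanations of inter-peptide mass deltas.

Large (~4.5 kDa) peptides measured on an ion trap at two-decimal m/z
precision are resolved on the *average* mass scale, so ``average`` is the
default everywhere; monoisotopic mode is provided for high-resolution data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ResidueMassTable",
    "STANDARD_TABLE",
    "ChargeSignal",
    "NeutralMass",
    "DehydrationEstimate",
    "ConsensusConflictError",
    "peptide_mass",
    "dehydrated_mass",
    "mass_from_mz",
    "mz_from_mass",
    "consensus_mass",
    "infer_dehydration_count",
    "residue_from_delta",
]

#: Mass of a proton in Da (charge carrier in positive-mode ESI).
PROTON_MASS = 1.007276

_SCALES = ("average", "monoisotopic")

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _check_scale(scale: str) -> None:
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue mono/average masses plus water and proton constants.

    ``residues`` maps one-letter codes to ``(mono, average)`` residue masses
    in Da (residue = amino acid minus one water). A free peptide's mass is
    the sum of its residue masses plus one water.
    """

    residues: dict[str, tuple[float, float]]
    water_mono: float
    water_avg: float
    proton: float = PROTON_MASS

    def residue_mass(self, aa: str, scale: str = "average") -> float:
        _check_scale(scale)
        try:
            mono, avg = self.residues[aa]
        except KeyError:
            raise KeyError(f"unknown residue {aa!r}") from None
        return avg if scale == "average" else mono

    def water(self, scale: str = "average") -> float:
        _check_scale(scale)
        return self.water_avg if scale == "average" else self.water_mono


def _build_standard_table() -> ResidueMassTable:
    residues = {}
    for aa in STANDARD_RESIDUES:
        comp = _pmass.std_aa_comp[aa]
        residues[aa] = (comp.mass(), comp.mass(average=True))
    water = _pmass.Composition(formula="H2O")
    return ResidueMassTable(
        residues=residues,
        water_mono=water.mass(),
        water_avg=water.mass(average=True),
    )


#: The standard 20-residue table used by every default code path.
STANDARD_TABLE = _build_standard_table()


@dataclass(frozen=True)
class ChargeSignal:
    """One picked ESI signal: m/z (Thomson) and positive charge z."""

    mz: float
    z: int

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if not isinstance(self.z, int) or self.z < 1:
            raise ValueError(f"charge must be a positive integer, got {self.z}")


@dataclass(frozen=True)
class NeutralMass:
    """Deconvolved neutral mass with provenance.

    ``value`` is the full-precision consensus (mean over source signals);
    ``integer_report`` is the truncated mass derived from the highest
    charge state, which is how low-resolution instruments' integer-Da
    reports behave in practice.
    """

    value: float
    integer_report: int
    source_signals: tuple[ChargeSignal, ...] = ()
    scale: str = "average"


@dataclass(frozen=True)
class DehydrationEstimate:
    """Number of water losses explaining a mass deficit, with residual."""

    n: int
    residual: float
    low_confidence: bool


class ConsensusConflictError(ValueError):
    """Charge states deconvolve to masses too far apart to be one species."""


def peptide_mass(
    seq: str, scale: str = "average", table: ResidueMassTable = STANDARD_TABLE
) -> float:
    """Mass in Da of a free linear peptide (sum of residues + one water).

    The empty sequence is a free water molecule. Raises ``ValueError``
    naming the first offending position for non-standard letters.
    """
    _check_scale(scale)
    total = table.water(scale)
    for i, aa in enumerate(seq):
        if aa not in table.residues:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1} of sequence"
            )
        total += table.residue_mass(aa, scale)
    return total


def dehydrated_mass(
    seq: str,
    n_dehydr: int,
    scale: str = "average",
    table: ResidueMassTable = STANDARD_TABLE,
) -> float:
    """Peptide mass after ``n_dehydr`` water losses (Ser/Thr -> Dha/Dhb).

    Each dehydration removes exactly one water; at most one per Ser or Thr,
    so ``n_dehydr`` may not exceed the sequence's Ser+Thr count.
    """
    if n_dehydr < 0:
        raise ValueError(f"n_dehydr must be non-negative, got {n_dehydr}")
    n_st = sum(seq.count(a) for a in "ST")
    if n_dehydr > n_st:
        raise ValueError(
            f"n_dehydr={n_dehydr} exceeds Ser+Thr count {n_st} of sequence"
        )
    return peptide_mass(seq, scale, table) - n_dehydr * table.water(scale)


def mass_from_mz(signal: ChargeSignal, proton: float = PROTON_MASS) -> float:
    """Neutral mass M of an [M+zH]z+ ion: ``z * (m/z - proton)``."""
    return signal.z * (signal.mz - proton)


def mz_from_mass(mass: float, z: int, proton: float = PROTON_MASS) -> float:
    """m/z of the [M+zH]z+ ion of a neutral mass; inverse of mass_from_mz."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if not isinstance(z, int) or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass + z * proton) / z


def consensus_mass(
    signals: Sequence[ChargeSignal],
    scale: str = "average",
    consistency_window: float = 3.0,
    proton: float = PROTON_MASS,
) -> NeutralMass:
    """Combine charge states of one species into a consensus neutral mass.

    All deconvolved masses must agree within ``consistency_window`` Da
    (default 3 Da: adjacent charge states of one ~4.5 kDa species read on a
    low-resolution instrument can disagree by ~2 Da); otherwise the set is
    rejected as conflicting. ``value`` is the mean deconvolved mass;
    ``integer_report`` truncates the mass derived from the highest charge
    state, the convention that matches integer-Da instrument reports.
    """
    _check_scale(scale)
    if not signals:
        raise ValueError("consensus_mass requires at least one signal")
    masses = [mass_from_mz(s, proton) for s in signals]
    spread = max(masses) - min(masses)
    if spread > consistency_window:
        raise ConsensusConflictError(
            f"deconvolved masses span {spread:.3f} Da, beyond the "
            f"{consistency_window:.3f} Da consistency window: "
            + ", ".join(f"{m:.3f}" for m in sorted(masses))
        )
    z_max = max(s.z for s in signals)
    top = [m for s, m in zip(signals, masses) if s.z == z_max]
    return NeutralMass(
        value=sum(masses) / len(masses),
        integer_report=math.floor(sum(top) / len(top)),
        source_signals=tuple(signals),
        scale=scale,
    )


def infer_dehydration_count(
    deficit: float,
    scale: str = "average",
    residual_threshold: float = 2.0,
    table: ResidueMassTable = STANDARD_TABLE,
) -> DehydrationEstimate:
    """How many water losses explain an observed-vs-calculated mass deficit.

    Returns the nearest integer multiple of the water mass, the residual
    ``|deficit - n * water|`` (quality control), and a low-confidence flag
    when the residual exceeds ``residual_threshold`` Da.
    """
    if deficit < 0:
        raise ValueError(f"deficit must be non-negative, got {deficit}")
    water = table.water(scale)
    n = round(deficit / water)
    residual = abs(deficit - n * water)
    return DehydrationEstimate(
        n=n, residual=residual, low_confidence=residual > residual_threshold
    )


# Residue pairs indistinguishable (or nearly so) at typical tolerances.
_ISOBARIC = {"L": "I", "I": "L"}


def residue_from_delta(
    delta: float,
    tol: float = 1.0,
    scale: str = "average",
    table: ResidueMassTable = STANDARD_TABLE,
) -> frozenset[str]:
    """Residues whose residue mass lies within ``tol`` Da of ``delta``.

    Leu and Ile are strictly isobaric and always co-reported. Near-isobars
    (e.g. Gln/Lys, 0.04 Da apart on the average scale) are co-reported
    whenever both fall inside the tolerance: no winner is picked that the
    measurement cannot support. An empty set means "no single-residue
    explanation"; that is a result, not an error.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    hits = {
        aa
        for aa in table.residues
        if abs(table.residue_mass(aa, scale) - delta) <= tol
    }
    for aa in list(hits):
        if aa in _ISOBARIC:
            hits.add(_ISOBARIC[aa])
    return frozenset(hits)
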