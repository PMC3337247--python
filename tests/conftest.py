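from pathlib import Path

import pytest

from lantimine import ChargeSignal

DATA_DIR = Path(__file__).resolve().parent.parent / "data"

# Synthetic 64-aa stand-in precursors (the deposited sequence is deliberately
# not a dependency). Both carry Met1, an FDLD leader box at 15-18 and a
# Ser/Thr/Cys-rich core deep enough that trimming at sites 20-23 never
# removes dehydration substrate.
#
# ELGA_STANDIN_FRAGMENT reproduces the published A20-Y25 fragment (ADLGDY,
# Asp at 21). ELGA_STANDIN_MASS_MATCHED instead places Asn at 21 (the
# reading consistent with the 114 Da ladder step) and its tail is
# composition-tuned so that the four trimmed cores, each dehydrated eight
# times, land within 1 Da of the four deconvolved product masses.
_TAIL = "TTSCHKSSTAVCGNTSWKQPLVMQRKNLWAYHQPVREAG"
ELGA_STANDIN_FRAGMENT = "MKQSELNALIGGSK" + "FDLD" + "A" + "ADLGDY" + _TAIL
ELGA_STANDIN_MASS_MATCHED = "MKQSELNALIGGSK" + "FDLD" + "A" + "ANLGDY" + _TAIL

# Published multi-charge product signals: (peptide, m/z, z).
ELGICIN_SIGNALS = {
    "elgicin_AI": [(1512.89, 3), (1135.07, 4)],
    "elgicin_AII": [(1532.58, 3), (1149.31, 4)],
    "elgicin_B": [(1569.89, 3), (1177.72, 4)],
    "elgicin_C": [(1608.30, 3), (1206.14, 4)],
}

ELGICIN_PRINTED_MASSES = {
    "elgicin_AI": 4536,
    "elgicin_AII": 4593,
    "elgicin_B": 4706,
    "elgicin_C": 4820,
}


@pytest.fixture
def elgicin_signal_groups() -> dict[str, list[ChargeSignal]]:
    return {
        pid: [ChargeSignal(mz, z) for mz, z in sigs]
        for pid, sigs in ELGICIN_SIGNALS.items()
    }


@pytest.fixture
def standin_fragment() -> str:
    return ELGA_STANDIN_FRAGMENT


@pytest.fixture
def standin_mass_matched() -> str:
    return ELGA_STANDIN_MASS_MATCHED
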