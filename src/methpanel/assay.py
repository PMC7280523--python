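"""Binary methylation calls from paired digested/mock MSRE-PCR reactions.

Each sample is run as a pair of reactions — one digested with the
methylation-sensitive enzyme, one mock-digested — and two internal controls
guard the readout: a digestion control (DC, a constitutively unmethylated
locus whose product must *disappear* after digestion, proving the enzyme
worked) and a positive control (PC, an enzyme-site-free locus that must
always amplify, proving the PCR worked). Control failure invalidates the
whole reaction, i.e. every locus of that sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import INVALID, METHYLATED, UNMETHYLATED

CALL_LABELS = {METHYLATED: "M", UNMETHYLATED: "U", INVALID: "NA"}


@dataclass
class LaneReading:
    """Band presences for one sample's paired reactions."""

    digested_bands: dict[str, bool]
    mock_bands: dict[str, bool]
    dc_digested: bool  # DC band present in the digested reaction (bad)
    pc_present: bool  # PC band present (required)


def call_locus(reading: LaneReading, locus: str) -> int:
    """One locus call: methylated, unmethylated or invalid.

    Precedence of failure modes: PC absent (amplification failure) and DC
    surviving digestion (incomplete digestion) invalidate the reaction; a
    missing mock band invalidates that locus (its PCR failed). Otherwise the
    digested-lane band decides: present = methylated (template protected),
    absent = unmethylated (template cleaved).
    """
    if not reading.pc_present:
        return INVALID
    if reading.dc_digested:
        return INVALID
    if not reading.mock_bands.get(locus, False):
        return INVALID
    return METHYLATED if reading.digested_bands.get(locus, False) else UNMETHYLATED


@dataclass
class QcReport:
    invalid_samples: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)


def call_matrix(readings: dict[str, LaneReading]) -> tuple[pd.DataFrame, QcReport]:
    """Apply :func:`call_locus` cell-wise over a cohort of lane readings.

    All samples must report the same locus set. Samples whose controls
    invalidate every locus are listed in the QC report with the reason.
    """
    if not readings:
        raise ValueError("no readings supplied")
    samples = list(readings)
    loci = sorted(readings[samples[0]].mock_bands)
    for s in samples:
        if sorted(readings[s].mock_bands) != loci or sorted(readings[s].digested_bands) != loci:
            raise ValueError(f"sample {s}: locus set differs from the rest of the cohort")
    qc = QcReport()
    data = {}
    for s in samples:
        r = readings[s]
        data[s] = [call_locus(r, locus) for locus in loci]
        if not r.pc_present:
            qc.invalid_samples.append(s)
            qc.reasons[s] = "positive control absent (amplification failure)"
        elif r.dc_digested:
            qc.invalid_samples.append(s)
            qc.reasons[s] = "digestion control survived (incomplete digestion)"
    calls = pd.DataFrame(data, index=pd.Index(loci, name="locus"), dtype="int8")
    return calls, qc
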