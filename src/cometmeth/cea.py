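"""Cytosine extension assay (CEA) calculations.

The CEA quantifies global CCGG methylation from radiolabel incorporation:
[3H]dCTP is added by a polymerase at the 5' overhangs left by HpaII or
MspI digestion, so scintillation counts (dpm) are proportional to cut
sites.  MspI cuts every accessible site while HpaII cuts only unmethylated
(and, slowly, hemimethylated) ones, so after background subtraction and
normalisation to 0.5 mg DNA the incorporation ratio gives

    %CpG = 100 * (1 - H / M),

with H and M the background-subtracted, mass-normalised HpaII and MspI
counts.  The assay serves as an independent cross-check of the comet-based
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import DomainError, UndefinedRatioError
from .simulate import CEASample

__all__ = [
    "relative_incorporation",
    "cea_methylation",
    "percent_change_from_control",
    "CEAResult",
]

#: Reference DNA mass (mg) that incorporation is expressed per.
REFERENCE_MASS_MG = 0.5


def relative_incorporation(dpm: float, dna_mass_mg: float) -> float:
    """Rescale a dpm count to the 0.5 mg DNA reference mass."""
    if dpm < 0:
        raise DomainError(f"dpm must be >= 0, got {dpm!r}")
    if dna_mass_mg <= 0:
        raise DomainError(f"dna_mass_mg must be > 0, got {dna_mass_mg!r}")
    return dpm * (REFERENCE_MASS_MG / dna_mass_mg)


def cea_methylation(sample: CEASample) -> float:
    """% CpG methylation from one CEA reaction's counts.

    Background counts are subtracted from both enzyme reactions;
    counting noise can push the HpaII signal below background, in which
    case it is floored at zero (with a warning) — incorporation cannot be
    negative.  Both signals are normalised to the reference DNA mass
    (a no-op for the ratio when both come from the same reaction mass).
    """
    h_net = sample.dpm_hpaii - sample.dpm_background
    m_net = sample.dpm_mspi - sample.dpm_background
    if m_net <= 0:
        raise UndefinedRatioError(
            "background-subtracted MspI counts are <= 0; the incorporation "
            "ratio is undefined (failed MspI digestion or mislabelled tubes?)"
        )
    if h_net < 0:
        warnings.warn(
            "HpaII counts below background; flooring net incorporation at 0",
            stacklevel=2,
        )
        h_net = 0.0
    h = relative_incorporation(h_net, sample.dna_mass_mg)
    m = relative_incorporation(m_net, sample.dna_mass_mg)
    return 100.0 * (1.0 - h / m)


def percent_change_from_control(value_treated: float,
                                value_control: float) -> float:
    """Percentage change of a treated value relative to its control."""
    if value_control == 0:
        raise DomainError("control value must be non-zero")
    return 100.0 * (value_treated - value_control) / value_control


@dataclass
class CEAResult:
    """CEA methylation estimate for one sample."""

    sample_id: str
    condition: str
    pct_methylation: float
    hpaii_incorporation: float
    mspi_incorporation: float

    @classmethod
    def from_sample(cls, sample: CEASample) -> "CEAResult":
        pct = cea_methylation(sample)
        h_net = max(sample.dpm_hpaii - sample.dpm_background, 0.0)
        m_net = sample.dpm_mspi - sample.dpm_background
        return cls(
            sample_id=sample.sample_id,
            condition=sample.condition,
            pct_methylation=pct,
            hpaii_incorporation=relative_incorporation(h_net, sample.dna_mass_mg),
            mspi_incorporation=relative_incorporation(m_net, sample.dna_mass_mg),
        )
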