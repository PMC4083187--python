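"""Forward simulator for methylation-sensitive comet assay data.

The assay exploits the isoschizomers HpaII and MspI, which both cut
5'-CCGG-3' but differ in methylation sensitivity: HpaII is blocked when
either cytosine is methylated (and cuts hemimethylated sites at a reduced
rate), while MspI tolerates internal-cytosine methylation but is blocked by
external-cytosine methylation.  Agarose-embedded nucleoids digested with
each enzyme are electrophoresed; the per-cell *tail intensity* (% of DNA
fluorescence in the comet tail) rises with the number of strand breaks, so
the HpaII/MspI tail ratio reflects the fraction of unmethylated CCGG sites.

The simulator draws per-cell break counts from that enzyme model and maps
breaks to tail intensity through a saturating exponential dose response,

    tail(B) = 100 * (1 - exp(-B / kappa)),

which is monotone, bounded in [0, 100), and linear for B << kappa — the
regime in which the downstream ratio statistic is unbiased.  Ground truth
(the methylated fraction ``m`` and friends) is known exactly, so every
downstream estimator can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "TREATMENTS",
    "SimulationParams",
    "CometMeasurement",
    "CEASample",
    "expected_tail_intensity",
    "simulate_cell_population",
    "simulate_cea_counts",
]

#: Canonical treatment labels, in canonical order.
TREATMENTS = ("control", "HpaII", "MspI")


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth and nuisance parameters of the forward model.

    Parameters
    ----------
    m : float
        Fraction of CCGG sites methylated at the internal cytosine
        (blocks HpaII, not MspI).  The quantity the assay estimates,
        on the 0-1 scale.
    h : float
        Fraction of sites hemimethylated; HpaII cuts these at rate
        ``d * d_hemi_factor``.
    e : float
        Fraction of sites methylated at the *external* cytosine
        (5'-mCCGG-3'), which blocks both enzymes (MspI included).
    S : int
        Effective CCGG site count per nucleoid.  An abstract, scaled
        genome — not a literal genomic site count.
    d : float
        Per-site digestion probability for a susceptible site during the
        incubation.
    d_hemi_factor : float
        Multiplier on ``d`` for HpaII at hemimethylated sites.
    lambda0 : float
        Mean pre-existing strand breaks per cell (Poisson rate), shared by
        all three treatment groups of a sample — the damage the control
        subtraction compensates for.
    kappa : float
        Saturation constant of the breaks -> tail-intensity response, in
        breaks.  ``kappa >= 100 * S * d`` keeps the response effectively
        linear over the simulated break range.
    sigma : float
        SD of additive Gaussian measurement noise on the tail-intensity
        scale (percentage points), applied per cell before clipping.
    n_cells : int
        Comets per treatment group per well (the assay scores 50-100).
    n_wells : int
        Replicate wells per sample (the 12-well format uses >= 9).
    seed : int or None
        Seed for the simulation RNG; identical seeds give identical output.

    Notes
    -----
    Defaults emulate a typical untreated cultured-cell sample: ~60%
    global CCGG methylation, visible baseline damage in the control, a
    strong MspI tail and an intermediate HpaII tail.
    """

    m: float = 0.6
    h: float = 0.0
    e: float = 0.0
    S: int = 200
    d: float = 0.9
    d_hemi_factor: float = 0.5
    lambda0: float = 10.0
    kappa: float = 150.0
    sigma: float = 5.0
    n_cells: int = 50
    n_wells: int = 9
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("m", "h", "e", "d", "d_hemi_factor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if self.m + self.h + self.e > 1.0 + 1e-12:
            raise ParameterError(
                f"m + h + e must not exceed 1, got {self.m + self.h + self.e!r}"
            )
        if int(self.S) != self.S or self.S < 1:
            raise ParameterError(f"S must be a positive integer, got {self.S!r}")
        if self.kappa <= 0:
            raise ParameterError(f"kappa must be > 0, got {self.kappa!r}")
        if self.lambda0 < 0:
            raise ParameterError(f"lambda0 must be >= 0, got {self.lambda0!r}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma!r}")
        for name in ("n_cells", "n_wells"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")

    @classmethod
    def linear_regime(cls, m: float, *, S: int = 1000, d: float = 0.1,
                      n_cells: int = 50, n_wells: int = 9,
                      seed: int | None = None, **overrides) -> "SimulationParams":
        """Noise-free parameters in the linear response regime.

        Sets ``kappa = 100 * S * d`` (the linearity threshold),
        ``lambda0 = sigma = h = e = 0`` and a *partial* digestion
        efficiency ``d``.  Partial digestion keeps per-comet binomial
        variability large relative to the O(S*d/kappa) curvature bias of
        the ratio statistic, and the large site count keeps break counts
        fine-grained, so Thompson-Tau trimming of the near-normal break
        distribution stays symmetric and the estimator is unbiased for
        100*m.  The regime every estimator-validation scenario uses.
        """
        base = dict(m=m, h=0.0, e=0.0, S=S, d=d, lambda0=0.0,
                    kappa=100.0 * S * d, sigma=0.0,
                    n_cells=n_cells, n_wells=n_wells, seed=seed)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CometMeasurement:
    """One scored comet: the atomic observation of the assay."""

    sample_id: str
    well: int
    treatment: str
    tail_intensity: float
    cell_id: int
    condition: str = "untreated"

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ParameterError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if not (0.0 <= self.tail_intensity <= 100.0):
            raise ParameterError(
                f"tail_intensity must lie in [0, 100], got {self.tail_intensity!r}"
            )


@dataclass(frozen=True)
class CEASample:
    """Scintillation counts for one cytosine-extension-assay reaction.

    [3H]dCTP is incorporated at enzyme-cut CCGG overhangs, so counts
    (disintegrations per minute, dpm) are proportional to cut sites.
    """

    dpm_hpaii: float
    dpm_mspi: float
    dpm_background: float = 0.0
    dna_mass_mg: float = 0.5
    sample_id: str = "sample"
    condition: str = "untreated"

    def __post_init__(self) -> None:
        for name in ("dpm_hpaii", "dpm_mspi", "dpm_background"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.dna_mass_mg <= 0:
            raise ParameterError(
                f"dna_mass_mg must be > 0, got {self.dna_mass_mg!r}"
            )


def expected_tail_intensity(breaks, kappa: float):
    """Mean tail intensity (%) produced by ``breaks`` strand breaks.

    The saturating exponential dose response
    ``100 * (1 - exp(-breaks / kappa))``: zero at zero breaks, strictly
    increasing, asymptoting to 100 as breaks grow.  Vectorised over
    ``breaks``.
    """
    if kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa!r}")
    b = np.asarray(breaks, dtype=float)
    if np.any(b < 0):
        raise ParameterError("breaks must be non-negative")
    out = 100.0 * (-np.expm1(-b / kappa))
    return float(out) if np.isscalar(breaks) else out


def _site_counts(p: SimulationParams) -> tuple[int, int, int]:
    """Integer site counts (HpaII-susceptible, hemimethylated, MspI-susceptible)."""
    n_unmeth = int(round(p.S * (1.0 - p.m - p.e - p.h)))
    n_hemi = int(round(p.S * p.h))
    n_mspi = int(round(p.S * (1.0 - p.e)))
    return n_unmeth, n_hemi, n_mspi


def _draw_breaks(p: SimulationParams, treatment: str, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    n_unmeth, n_hemi, n_mspi = _site_counts(p)
    breaks = rng.poisson(p.lambda0, size=size)
    if treatment == "MspI":
        breaks = breaks + rng.binomial(n_mspi, p.d, size=size)
    elif treatment == "HpaII":
        breaks = breaks + rng.binomial(n_unmeth, p.d, size=size)
        if n_hemi > 0:
            breaks = breaks + rng.binomial(n_hemi, p.d * p.d_hemi_factor, size=size)
    return breaks


def simulate_cell_population(params: SimulationParams, sample_id: str,
                             condition: str = "untreated") -> pd.DataFrame:
    """Simulate every comet of one sample: three treatments across all wells.

    For each cell, baseline breaks ``B0 ~ Poisson(lambda0)`` are drawn;
    enzyme treatments add binomial digestion breaks per the HpaII/MspI
    methylation-sensitivity model; tail intensity is the dose response of
    the total plus Gaussian noise, clipped to [0, 100].

    Returns
    -------
    pandas.DataFrame
        One row per comet, ``3 * n_cells * n_wells`` rows, with columns
        ``sample_id, condition, well, cell_id, treatment, tail_intensity``.
        Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for well in range(1, params.n_wells + 1):
        for treatment in TREATMENTS:
            breaks = _draw_breaks(params, treatment, params.n_cells, rng)
            tail = expected_tail_intensity(breaks, params.kappa)
            if params.sigma > 0:
                tail = tail + rng.normal(0.0, params.sigma, size=params.n_cells)
            tail = np.clip(tail, 0.0, 100.0)
            frames.append(pd.DataFrame({
                "sample_id": sample_id,
                "condition": condition,
                "well": well,
                "cell_id": np.arange(1, params.n_cells + 1),
                "treatment": treatment,
                "tail_intensity": tail,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_cea_counts(params: SimulationParams, scale_dpm: float,
                        background_dpm: float = 0.0,
                        seed: int | None = None,
                        sample_id: str = "sample",
                        condition: str = "untreated") -> CEASample:
    """Simulate cytosine-extension-assay scintillation counts.

    Label incorporation is proportional to cut CCGG ends, so the Poisson
    means mirror the comet model's expected digestion breaks per nucleoid
    scaled by ``scale_dpm``; the background count is added to both
    reactions.  DNA mass defaults to the 0.5 mg reference.
    """
    if scale_dpm <= 0:
        raise ParameterError(f"scale_dpm must be > 0, got {scale_dpm!r}")
    if background_dpm < 0:
        raise ParameterError(f"background_dpm must be >= 0, got {background_dpm!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p = params
    mean_mspi = scale_dpm * p.S * (1.0 - p.e) * p.d
    mean_hpaii = scale_dpm * p.S * (1.0 - p.m - p.e - p.h
                                    + p.h * p.d_hemi_factor) * p.d
    return CEASample(
        dpm_hpaii=background_dpm + float(rng.poisson(max(mean_hpaii, 0.0))),
        dpm_mspi=background_dpm + float(rng.poisson(mean_mspi)),
        dpm_background=background_dpm,
        dna_mass_mg=0.5,
        sample_id=sample_id,
        condition=condition,
    )
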