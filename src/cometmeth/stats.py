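"""Statistical core: outlier rejection, the % CpG methylation statistic,
and bootstrap inference.

Global CpG methylation is estimated from three groups of per-comet tail
intensities — undigested control, HpaII-digested and MspI-digested
nucleoids — as

    %CpG = (100 - 100 * HpaII / MspI) - control,

where HpaII, MspI and control are group mean tail intensities after
modified-Thompson-Tau outlier removal.  MspI cuts every accessible CCGG
site, so its tail represents total digestible sites; the HpaII/MspI ratio
is the unmethylated fraction; the control term removes pre-existing damage
common to all groups.  Uncertainty comes from a percentile bootstrap that
resamples comets within each group.

The model/results split follows the usual statsmodels idiom:
:class:`MethylationModel` holds the data, its :meth:`~MethylationModel.fit`
returns a :class:`MethylationResults` with the estimate, interval,
diagnostics, bootstrap replicates and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ConfigurationError,
    DomainError,
    InferenceError,
    ParameterError,
    UndefinedRatioError,
)

__all__ = [
    "TreatmentGroups",
    "MethylationModel",
    "MethylationResults",
    "ConditionComparison",
    "thompson_tau_filter",
    "tau_critical",
    "pct_cpg_methylation",
    "estimate_methylation",
    "compare_conditions",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TreatmentGroups:
    """Per-comet tail intensities of one sample, split by treatment."""

    control: list
    hpaii: list
    mspi: list
    sample_id: str = "sample"
    condition: str = "untreated"

    def validate(self) -> None:
        for name in ("control", "hpaii", "mspi"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size == 0:
                raise ParameterError(f"group {name!r} is empty")
            if np.any((vals < 0) | (vals > 100)):
                raise ParameterError(
                    f"group {name!r} has tail intensities outside [0, 100]"
                )


# ---------------------------------------------------------------------------
# modified Thompson Tau outlier rejection
# ---------------------------------------------------------------------------

def tau_critical(n: int, alpha: float) -> float:
    """Modified Thompson Tau threshold multiplier for sample size ``n``.

    ``tau = t * (n - 1) / (sqrt(n) * sqrt(n - 2 + t^2))`` with ``t`` the
    two-sided Student-t critical value at level ``alpha`` on ``n - 2``
    degrees of freedom.  A point is an outlier when its absolute deviation
    from the sample mean exceeds ``tau * SD``.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha!r}")
    if n < 3:
        raise ParameterError("tau is undefined for n < 3")
    t = sps.t.ppf(1.0 - alpha / 2.0, n - 2)
    return t * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t * t))


def thompson_tau_filter(values, alpha: float = 0.05):
    """Iteratively remove outliers by the modified Thompson Tau rule.

    Each pass removes at most the single most deviant point (largest
    ``|value - mean|``) if it exceeds ``tau * SD``, then recomputes mean,
    SD and tau; it stops when the extreme point survives, the SD is zero,
    or fewer than 3 points remain.

    Parameters
    ----------
    values : array-like of float
    alpha : float
        Two-sided significance level of the underlying t test (default
        0.05, mirroring the assay's 95% convention).

    Returns
    -------
    retained : ndarray
        Surviving values in their original order.
    removed : list of int
        Indices (into the input) of removed points, in removal order.

    Notes
    -----
    When the minimum and maximum are exactly equidistant from the mean,
    the maximum is removed (a deterministic tie-break; ties only arise
    with discrete-valued data).
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha!r}")
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ParameterError("values must be one-dimensional")
    if vals.size < 3:
        warnings.warn(
            "Thompson Tau needs n >= 3 (SD-based test undefined); "
            "no outliers removed.",
            stacklevel=2,
        )
        return vals.copy(), []

    keep = np.ones(vals.size, dtype=bool)
    removed: list[int] = []
    while keep.sum() >= 3:
        idx = np.flatnonzero(keep)
        cur = vals[idx]
        mean = cur.mean()
        sd = cur.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(cur - mean)
        dmax = dev.max()
        cand = np.flatnonzero(dev == dmax)
        j = int(cand[np.argmax(cur[cand])])  # tie-break: drop the largest
        if dmax > tau_critical(cur.size, alpha) * sd:
            keep[idx[j]] = False
            removed.append(int(idx[j]))
        else:
            break
    return vals[keep], removed


def _tau_crit_table(n_max: int, alpha: float) -> np.ndarray:
    """tau thresholds for every window size 3..n_max (index by size)."""
    out = np.zeros(n_max + 1)
    if n_max >= 3:
        n = np.arange(3, n_max + 1)
        t = sps.t.ppf(1.0 - alpha / 2.0, n - 2)
        out[3:] = t * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t * t))
    return out


def _tau_filtered_mean(sorted_vals: list, total: float, total_sq: float,
                       taus: np.ndarray) -> float:
    """Mean after Thompson-Tau filtering, on pre-sorted data.

    Equivalent to :func:`thompson_tau_filter` followed by a mean (the most
    deviant point is always the current minimum or maximum, so trimming
    walks inward from the sorted ends; the same drop-the-largest
    tie-break applies).  O(n) after the sort, used in the bootstrap inner
    loop where the full filter would dominate runtime.
    """
    i, j = 0, len(sorted_vals) - 1
    count = j + 1
    s, s2 = total, total_sq
    while count >= 3:
        mean = s / count
        var = (s2 - count * mean * mean) / (count - 1)
        if var <= 0.0:
            break
        sd = var ** 0.5
        d_lo = mean - sorted_vals[i]
        d_hi = sorted_vals[j] - mean
        d = d_hi if d_hi >= d_lo else d_lo
        if d > taus[count] * sd:
            if d_hi >= d_lo:
                v = sorted_vals[j]
                j -= 1
            else:
                v = sorted_vals[i]
                i += 1
            s -= v
            s2 -= v * v
            count -= 1
        else:
            break
    return s / count


# ---------------------------------------------------------------------------
# the methylation statistic
# ---------------------------------------------------------------------------

def pct_cpg_methylation(hpaii_mean: float, mspi_mean: float,
                        control_mean: float) -> float:
    """% CpG methylation from group mean tail intensities.

    ``(100 - 100 * hpaii_mean / mspi_mean) - control_mean``.  Not clipped:
    negative values are legal and signal control damage exceeding the
    digestion contrast.
    """
    if hpaii_mean < 0 or mspi_mean < 0 or control_mean < 0:
        raise DomainError("mean tail intensities must be non-negative")
    if mspi_mean == 0:
        raise UndefinedRatioError(
            "MspI mean tail intensity is zero - the HpaII/MspI ratio is "
            "undefined (failed MspI digestion?)"
        )
    return (100.0 - 100.0 * hpaii_mean / mspi_mean) - control_mean


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class MethylationModel:
    """Global-CpG-methylation model for one sample's three treatment groups.

    Parameters
    ----------
    groups : TreatmentGroups
        Control, HpaII and MspI per-comet tail intensities (%, in [0, 100]).

    Examples
    --------
    >>> g = TreatmentGroups(control=[2, 3], hpaii=[40, 42], mspi=[80, 78])
    >>> res = MethylationModel(g).fit(n_boot=1000, seed=0)
    >>> round(res.pct_methylation, 1)
    45.6
    """

    def __init__(self, groups: TreatmentGroups):
        groups.validate()
        self.groups = groups

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str | None = None,
                       condition: str | None = None) -> "MethylationModel":
        """Build a model from a per-comet table.

        The frame needs ``treatment`` and ``tail_intensity`` columns (the
        io-module comet schema); optional ``sample_id``/``condition``
        filters select one sample from a multi-sample table.
        """
        sub = df
        if sample_id is not None:
            sub = sub[sub["sample_id"] == sample_id]
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        by = {t: sub.loc[sub["treatment"] == t, "tail_intensity"].tolist()
              for t in ("control", "HpaII", "MspI")}
        groups = TreatmentGroups(
            control=by["control"], hpaii=by["HpaII"], mspi=by["MspI"],
            sample_id=sample_id if sample_id is not None
            else (str(sub["sample_id"].iloc[0]) if len(sub) else "sample"),
            condition=condition if condition is not None
            else (str(sub["condition"].iloc[0])
                  if "condition" in sub and len(sub) else "untreated"),
        )
        return cls(groups)

    def fit(self, alpha_tau: float = 0.05, n_boot: int = 10_000,
            ci_level: float = 0.95, seed: int | None = None,
            ) -> "MethylationResults":
        """Estimate % CpG methylation with a percentile-bootstrap interval.

        Outliers are removed independently per group (modified Thompson
        Tau at ``alpha_tau``); the point estimate is the statistic of the
        filtered group means.  Each of the ``n_boot`` bootstrap replicates
        resamples comets with replacement within each original group and
        re-applies the outlier filter before recomputing the statistic, so
        the interval reflects the sampling variability of the *whole*
        estimator, filtering included.  Replicates whose filtered MspI
        mean is zero are discarded and counted; more than 1% discarded
        aborts inference.
        """
        if n_boot < 1:
            raise ParameterError(f"n_boot must be >= 1, got {n_boot!r}")
        if not (0.0 < ci_level < 1.0):
            raise ParameterError(f"ci_level must lie in (0, 1), got {ci_level!r}")

        filtered: dict[str, np.ndarray] = {}
        n_removed: dict[str, int] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny groups: n<3 guard is fine here
            for name, vals in (("control", self.groups.control),
                               ("hpaii", self.groups.hpaii),
                               ("mspi", self.groups.mspi)):
                kept, removed = thompson_tau_filter(vals, alpha_tau)
                filtered[name] = kept
                n_removed[name] = len(removed)

        point = pct_cpg_methylation(filtered["hpaii"].mean(),
                                    filtered["mspi"].mean(),
                                    filtered["control"].mean())

        raw = {"control": np.asarray(self.groups.control, dtype=float),
               "hpaii": np.asarray(self.groups.hpaii, dtype=float),
               "mspi": np.asarray(self.groups.mspi, dtype=float)}
        rng = np.random.default_rng(seed)
        reps = _bootstrap_statistic(raw, n_boot, rng, alpha_tau)
        n_discarded = int(np.isnan(reps).sum())
        if n_discarded > 0.01 * n_boot:
            raise InferenceError(
                f"{n_discarded}/{n_boot} bootstrap replicates had a zero "
                "resampled MspI mean; the interval is unreliable"
            )
        reps = reps[~np.isnan(reps)]
        lo = (1.0 - ci_level) / 2.0
        ci_low, ci_high = np.quantile(reps, [lo, 1.0 - lo])

        return MethylationResults(
            sample_id=self.groups.sample_id,
            condition=self.groups.condition,
            pct_methylation=float(point),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            n_control=int(filtered["control"].size),
            n_hpaii=int(filtered["hpaii"].size),
            n_mspi=int(filtered["mspi"].size),
            n_removed=n_removed,
            n_boot=int(n_boot),
            n_boot_discarded=n_discarded,
            ci_level=float(ci_level),
            alpha_tau=float(alpha_tau),
            seed=seed,
            bootstrap_replicates=reps,
        )


def _bootstrap_statistic(raw: dict[str, np.ndarray], n_boot: int,
                         rng: np.random.Generator,
                         alpha_tau: float) -> np.ndarray:
    """Bootstrap replicates of the filter+statistic estimator.

    Each replicate resamples every group with replacement at its original
    size, re-applies Thompson-Tau filtering (via the sorted fast path —
    a sorted resample filters identically to an unsorted one) and
    recomputes the statistic.  NaN marks a replicate discarded for a zero
    filtered MspI mean.
    """
    sizes = {k: v.size for k, v in raw.items()}
    taus = {k: _tau_crit_table(n, alpha_tau) if n >= 3 else None
            for k, n in sizes.items()}
    out = np.empty(n_boot)
    for b in range(n_boot):
        means = {}
        for name, vals in raw.items():
            pick = vals[rng.integers(0, vals.size, size=vals.size)]
            if taus[name] is None:
                means[name] = float(pick.mean())
            else:
                pick.sort()
                means[name] = _tau_filtered_mean(
                    pick.tolist(), float(pick.sum()),
                    float(np.square(pick).sum()), taus[name])
        if means["mspi"] == 0.0:
            out[b] = np.nan
        else:
            out[b] = (100.0 - 100.0 * means["hpaii"] / means["mspi"]
                      ) - means["control"]
    return out


@dataclass
class MethylationResults:
    """Fitted % CpG methylation for one sample, with bootstrap inference.

    ``pct_methylation`` is reported unclipped; values below 0 or above 100
    are legal and flagged in :meth:`summary`.
    """

    sample_id: str
    condition: str
    pct_methylation: float
    ci_low: float
    ci_high: float
    n_control: int
    n_hpaii: int
    n_mspi: int
    n_removed: dict
    n_boot: int
    ci_level: float
    alpha_tau: float = 0.05
    seed: int | None = None
    n_boot_discarded: int = 0
    bootstrap_replicates: np.ndarray | None = field(default=None, repr=False)

    def conf_int(self) -> tuple[float, float]:
        """Percentile bootstrap confidence interval (lower, upper)."""
        return self.ci_low, self.ci_high

    @property
    def n_removed_total(self) -> int:
        return int(sum(self.n_removed.values()))

    def to_dict(self) -> dict:
        """Serializable field mapping (excludes the replicate array)."""
        return {
            "sample_id": self.sample_id,
            "condition": self.condition,
            "pct_methylation": self.pct_methylation,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_control": self.n_control,
            "n_hpaii": self.n_hpaii,
            "n_mspi": self.n_mspi,
            "n_removed_control": self.n_removed.get("control", 0),
            "n_removed_hpaii": self.n_removed.get("hpaii", 0),
            "n_removed_mspi": self.n_removed.get("mspi", 0),
            "n_boot": self.n_boot,
            "n_boot_discarded": self.n_boot_discarded,
            "ci_level": self.ci_level,
            "alpha_tau": self.alpha_tau,
            "seed": self.seed,
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        pct = 100.0 * self.ci_level
        lines = [
            "Methylation-sensitive comet assay: % CpG methylation",
            "=" * 56,
            f"sample:            {self.sample_id} ({self.condition})",
            f"pct methylation:   {self.pct_methylation:10.3f}",
            f"{pct:.0f}% bootstrap CI:  [{self.ci_low:8.3f}, {self.ci_high:8.3f}]"
            f"   ({self.n_boot} replicates)",
            f"group n (kept):    control={self.n_control}  "
            f"HpaII={self.n_hpaii}  MspI={self.n_mspi}",
            f"outliers removed:  control={self.n_removed.get('control', 0)}  "
            f"HpaII={self.n_removed.get('hpaii', 0)}  "
            f"MspI={self.n_removed.get('mspi', 0)}"
            f"   (Thompson Tau, alpha={self.alpha_tau})",
        ]
        if self.n_boot_discarded:
            lines.append(f"replicates discarded: {self.n_boot_discarded}")
        if not (0.0 <= self.pct_methylation <= 100.0):
            lines.append(
                "NOTE: estimate outside [0, 100] - control damage exceeds "
                "the digestion contrast; interpret with care."
            )
        lines.append("=" * 56)
        return "\n".join(lines)


def estimate_methylation(groups: TreatmentGroups, alpha_tau: float = 0.05,
                         n_boot: int = 10_000, ci_level: float = 0.95,
                         seed: int | None = None) -> MethylationResults:
    """Convenience wrapper: ``MethylationModel(groups).fit(...)``."""
    return MethylationModel(groups).fit(alpha_tau=alpha_tau, n_boot=n_boot,
                                        ci_level=ci_level, seed=seed)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

@dataclass
class ConditionComparison:
    """Decrease in % CpG methylation between two conditions."""

    difference: float
    ci_low: float | None
    ci_high: float | None
    ci_level: float | None

    def summary(self) -> str:
        s = f"decrease: {self.difference:.3f} percentage points"
        if self.ci_low is not None:
            s += (f"  ({100 * self.ci_level:.0f}% CI "
                  f"[{self.ci_low:.3f}, {self.ci_high:.3f}])")
        return s


def compare_conditions(est_untreated, est_treated) -> ConditionComparison:
    """Difference (untreated − treated) in % CpG methylation.

    Accepts two fitted :class:`MethylationResults` — in which case the CI
    of the difference is the percentile interval of the paired difference
    of their (independent) bootstrap replicate streams — or two plain
    numbers (e.g. published point estimates), in which case only the
    difference is returned.
    """
    a_val, a_reps, a_lvl = _point_reps(est_untreated)
    b_val, b_reps, b_lvl = _point_reps(est_treated)
    if a_lvl is not None and b_lvl is not None and a_lvl != b_lvl:
        raise ConfigurationError(
            f"estimates built at different ci_level ({a_lvl} vs {b_lvl})"
        )
    diff = a_val - b_val
    if a_reps is None or b_reps is None:
        return ConditionComparison(diff, None, None, a_lvl or b_lvl)
    if a_reps.size != b_reps.size:
        raise ConfigurationError(
            "bootstrap replicate streams have different lengths "
            f"({a_reps.size} vs {b_reps.size}); refit with equal n_boot"
        )
    level = a_lvl if a_lvl is not None else 0.95
    lo = (1.0 - level) / 2.0
    d = a_reps - b_reps
    ci_low, ci_high = np.quantile(d, [lo, 1.0 - lo])
    return ConditionComparison(float(diff), float(ci_low), float(ci_high), level)


def _point_reps(est):
    if isinstance(est, MethylationResults):
        return est.pct_methylation, est.bootstrap_replicates, est.ci_level
    return float(est), None, None
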