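"""Readers and writers for the pipeline's tables and config files.

The per-comet CSV schema emulates the per-comet export of commercial
comet-scoring software: one row per scored comet with
``sample_id, condition, well, cell_id, treatment, tail_intensity``.
Comma-separated, UTF-8, header row required, ``.`` decimal separator.
Treatment labels are case-insensitive on read and canonicalised to
``control`` / ``HpaII`` / ``MspI`` on write.  Line numbers in errors are
1-based with the header as line 1.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from .cea import CEAResult
from .exceptions import SchemaError
from .simulate import CEASample, SimulationParams, TREATMENTS
from .stats import MethylationResults, TreatmentGroups

__all__ = [
    "COMET_COLUMNS",
    "read_comet_table",
    "read_comet_csv",
    "write_comet_csv",
    "write_results",
    "read_results",
    "read_cea_csv",
    "write_cea_results",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "load_sim_config",
]

COMET_COLUMNS = ["sample_id", "condition", "well", "cell_id",
                 "treatment", "tail_intensity"]

_CANONICAL_TREATMENT = {t.lower(): t for t in TREATMENTS}

_RESULT_COLUMNS = [
    "sample_id", "condition", "pct_methylation", "ci_low", "ci_high",
    "n_control", "n_hpaii", "n_mspi",
    "n_removed_control", "n_removed_hpaii", "n_removed_mspi",
    "n_boot", "n_boot_discarded", "ci_level", "alpha_tau", "seed",
]

_CEA_ENZYMES = {"hpaii": "HpaII", "mspi": "MspI", "background": "background"}


def read_comet_table(path) -> pd.DataFrame:
    """Read and validate a per-comet CSV into a DataFrame.

    Raises :class:`SchemaError` naming the offending lines when any row
    has a missing cell, an unknown treatment label, a non-integer well or
    cell id, or a tail intensity outside [0, 100].
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "condition": str,
                                  "treatment": str})
    missing = [c for c in COMET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[COMET_COLUMNS]

    def _lines(mask) -> list[int]:
        return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))]

    bad = df.isna().any(axis=1)
    if bad.any():
        raise SchemaError("rows with missing cells", _lines(bad))

    canon = df["treatment"].str.lower().map(_CANONICAL_TREATMENT)
    if canon.isna().any():
        raise SchemaError(
            f"unknown treatment labels (expected one of {TREATMENTS}, "
            "case-insensitive)", _lines(canon.isna()))
    df["treatment"] = canon

    for col in ("well", "cell_id"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise SchemaError(f"non-integer {col} values", _lines(bad))
        df[col] = vals.astype(int)
    bad = (df["well"] < 1) | (df["well"] > 12)
    if bad.any():
        raise SchemaError("well index outside 1-12", _lines(bad))

    ti = pd.to_numeric(df["tail_intensity"], errors="coerce")
    bad = ti.isna() | (ti < 0) | (ti > 100)
    if bad.any():
        raise SchemaError("tail_intensity missing or outside [0, 100]",
                          _lines(bad))
    df["tail_intensity"] = ti.astype(float)
    return df


def read_comet_csv(path) -> dict[tuple[str, str], TreatmentGroups]:
    """Read a per-comet CSV grouped by (sample_id, condition).

    Returns a mapping from ``(sample_id, condition)`` to
    :class:`~cometmeth.stats.TreatmentGroups` ready for model fitting.
    """
    df = read_comet_table(path)
    out: dict[tuple[str, str], TreatmentGroups] = {}
    for (sample, cond), sub in df.groupby(["sample_id", "condition"],
                                          sort=True):
        by = {t: sub.loc[sub["treatment"] == t, "tail_intensity"].tolist()
              for t in TREATMENTS}
        out[(sample, cond)] = TreatmentGroups(
            control=by["control"], hpaii=by["HpaII"], mspi=by["MspI"],
            sample_id=str(sample), condition=str(cond))
    return out


def write_comet_csv(df: pd.DataFrame, path) -> None:
    """Write a per-comet table in the canonical schema and column order."""
    out = df[COMET_COLUMNS].copy()
    out["treatment"] = out["treatment"].str.lower().map(_CANONICAL_TREATMENT)
    out.to_csv(path, index=False)


def write_results(estimates, path) -> None:
    """Write fitted methylation results to CSV, one row per sample.

    All fields round-trip at full precision; an empty list yields a
    header-only file; estimates are never clipped on write.
    """
    rows = [est.to_dict() for est in estimates]
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)


def read_results(path) -> list[MethylationResults]:
    """Read back a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"sample_id": str, "condition": str})
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing result columns: {missing}")
    out = []
    for _, row in df.iterrows():
        seed = row["seed"]
        out.append(MethylationResults(
            sample_id=str(row["sample_id"]),
            condition=str(row["condition"]),
            pct_methylation=float(row["pct_methylation"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            n_control=int(row["n_control"]),
            n_hpaii=int(row["n_hpaii"]),
            n_mspi=int(row["n_mspi"]),
            n_removed={"control": int(row["n_removed_control"]),
                       "hpaii": int(row["n_removed_hpaii"]),
                       "mspi": int(row["n_removed_mspi"])},
            n_boot=int(row["n_boot"]),
            n_boot_discarded=int(row["n_boot_discarded"]),
            ci_level=float(row["ci_level"]),
            alpha_tau=float(row["alpha_tau"]),
            seed=None if pd.isna(seed) else int(seed),
        ))
    return out


def read_cea_csv(path) -> list[CEASample]:
    """Read a CEA counts CSV into per-sample :class:`CEASample` records.

    Schema: ``sample_id, condition, enzyme, dpm, dna_mass_mg`` with enzyme
    in {HpaII, MspI, background} (case-insensitive).  Replicate rows for
    the same (sample, condition, enzyme) — e.g. duplicate scintillation
    readings — are averaged before analysis.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "condition": str,
                                  "enzyme": str})
    required = ["sample_id", "condition", "enzyme", "dpm", "dna_mass_mg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    canon = df["enzyme"].str.lower().map(_CEA_ENZYMES)
    if canon.isna().any():
        lines = [int(i) + 2 for i in np.flatnonzero(canon.isna().to_numpy())]
        raise SchemaError("unknown enzyme labels "
                          "(expected HpaII, MspI or background)", lines)
    df["enzyme"] = canon
    bad = pd.to_numeric(df["dpm"], errors="coerce").isna() | (df["dpm"] < 0)
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise SchemaError("dpm missing or negative", lines)

    samples = []
    for (sample, cond), sub in df.groupby(["sample_id", "condition"],
                                          sort=True):
        by = sub.groupby("enzyme")["dpm"].mean()
        for enz in ("HpaII", "MspI"):
            if enz not in by:
                raise SchemaError(
                    f"sample {sample!r} ({cond}) lacks {enz} counts")
        samples.append(CEASample(
            dpm_hpaii=float(by["HpaII"]),
            dpm_mspi=float(by["MspI"]),
            dpm_background=float(by.get("background", 0.0)),
            dna_mass_mg=float(sub["dna_mass_mg"].mean()),
            sample_id=str(sample), condition=str(cond)))
    return samples


def write_cea_results(results: list[CEAResult], path) -> None:
    """Write per-sample CEA estimates, with % change vs matched control.

    The change column compares each ``aza_treated`` (or any non-control
    condition) estimate to the untreated estimate of the same sample
    lineage when present.
    """
    rows = []
    untreated = {r.sample_id: r.pct_methylation for r in results
                 if r.condition == "untreated"}
    by_cond: dict[str, float] = {}
    if len({r.condition for r in results}) == 2 and untreated:
        # single pair of conditions: also allow cross-sample matching
        by_cond = {r.condition: r.pct_methylation for r in results}
    for r in results:
        change = np.nan
        ref = untreated.get(r.sample_id)
        if ref is None and r.condition != "untreated":
            ref = by_cond.get("untreated")
        if ref is not None and r.condition != "untreated" and ref != 0:
            change = 100.0 * (r.pct_methylation - ref) / ref
        rows.append({
            "sample_id": r.sample_id,
            "condition": r.condition,
            "pct_methylation": r.pct_methylation,
            "hpaii_incorporation_per_half_mg": r.hpaii_incorporation,
            "mspi_incorporation_per_half_mg": r.mspi_incorporation,
            "pct_change_from_control": change,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth_sidecar(params: SimulationParams, path) -> None:
    """Write the simulator's ground truth as key=value lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in params.to_dict().items():
            fh.write(f"{key}={val}\n")


def read_truth_sidecar(path) -> SimulationParams:
    """Read a ground-truth sidecar back into :class:`SimulationParams`."""
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    types = {f.name: f.type for f in dc_fields(SimulationParams)}
    parsed = {}
    for key, val in kv.items():
        if key not in types:
            raise SchemaError(f"unknown truth-sidecar key {key!r}")
        if val == "None":
            parsed[key] = None
        elif key in ("S", "n_cells", "n_wells", "seed"):
            parsed[key] = int(val)
        else:
            parsed[key] = float(val)
    return SimulationParams(**parsed)


def load_sim_config(path) -> SimulationParams:
    """Load simulation parameters from a YAML mapping."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("simulation config must be a YAML mapping")
    known = {f.name for f in dc_fields(SimulationParams)}
    unknown = set(cfg) - known
    if unknown:
        raise SchemaError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimulationParams(**cfg)
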