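"""Cohort file I/O and declarative model configuration.

The cohort schema is a long-format CSV with header
``subject_id,phase,time,value,t_trt``: one row per observation, phase
``pre`` (time in years from seroconversion, strictly before ``t_trt``) or
``post`` (time in years from treatment initiation, strictly positive --
time zero belongs to the latent baseline, never to data).  ``t_trt`` is
constant within subject.  The package operates on the analysis scale
throughout; ``sqrt_transform=True`` square-root-transforms raw counts on
read (and predictions are squared on output), matching the usual handling
of CD4 counts.  All validation problems are collected and reported in a
single pass with row numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .data import SubjectRecord
from .links import LinkSpec
from .modelspec import ModelSpec, QuadratureConfig, preset

__all__ = ["CohortValidationError", "read_cohort", "write_cohort", "read_model_spec"]

_COLUMNS = ["subject_id", "phase", "time", "value", "t_trt"]


class CohortValidationError(ValueError):
    """All schema violations found in one validation pass."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid cohort file:\n" + "\n".join(problems))


def read_cohort(path, sqrt_transform: bool = False) -> list[SubjectRecord]:
    """Read and validate a cohort CSV into per-subject sorted records."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    problems: list[str] = []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing column(s): {', '.join(missing)}"])
    bad_phase = ~df["phase"].isin(["pre", "post"])
    for i in df.index[bad_phase]:
        problems.append(f"row {i + 2}: unknown phase {df.at[i, 'phase']!r}")
    for col in ("time", "value", "t_trt"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna()]:
            problems.append(f"row {i + 2}: non-numeric {col}")
        df[col] = vals

    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        t_trt_vals = grp["t_trt"].dropna().unique()
        if len(t_trt_vals) > 1:
            problems.append(f"subject {sid}: inconsistent t_trt values {sorted(t_trt_vals)}")
            continue
        if len(t_trt_vals) == 0:
            problems.append(f"subject {sid}: missing t_trt")
            continue
        t_trt = float(t_trt_vals[0])
        pre = grp[grp["phase"] == "pre"]
        post = grp[grp["phase"] == "post"]
        for i in pre.index[pre["time"] >= t_trt]:
            problems.append(f"row {i + 2}: pre observation at time >= t_trt for subject {sid}")
        for i in post.index[post["time"] <= 0]:
            problems.append(f"row {i + 2}: post observation at time <= 0 for subject {sid}")
        if len(post) == 0:
            problems.append(f"subject {sid}: no post-treatment observations")
        values_pre = pre["value"].to_numpy(dtype=float)
        values_post = post["value"].to_numpy(dtype=float)
        if sqrt_transform:
            if np.any(values_pre < 0) or np.any(values_post < 0):
                problems.append(f"subject {sid}: negative values cannot be sqrt-transformed")
            values_pre = np.sqrt(np.maximum(values_pre, 0.0))
            values_post = np.sqrt(np.maximum(values_post, 0.0))
        records.append(
            SubjectRecord(
                str(sid),
                pre["time"].to_numpy(dtype=float),
                values_pre,
                post["time"].to_numpy(dtype=float),
                values_post,
                t_trt,
            )
        )
    if problems:
        raise CohortValidationError(problems)
    return records


def write_cohort(subjects: list[SubjectRecord], path) -> None:
    """Write records in the cohort CSV schema (inverse of :func:`read_cohort`)."""
    rows = []
    for rec in subjects:
        for t, v in zip(rec.t_pre, rec.y_pre):
            rows.append((rec.subject_id, "pre", t, v, rec.t_trt))
        for t, v in zip(rec.t_post, rec.y_post):
            rows.append((rec.subject_id, "post", t, v, rec.t_trt))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_model_spec(path) -> ModelSpec:
    """Read a model configuration (YAML).

    Either ``preset: model1 .. model6``, or explicit keys ``phi1`` /
    ``phi2`` (each with ``form``, optional ``stratified``, ``knots``,
    ``stratum_bounds``), ``heavy_tails`` and ``n_quad``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "preset" in cfg:
        overrides = {}
        if "n_quad" in cfg:
            overrides["quadrature"] = QuadratureConfig(int(cfg["n_quad"]))
        return preset(cfg["preset"], **overrides)

    def link_spec(d) -> LinkSpec:
        if d is None:
            return LinkSpec()
        form = d.get("form", "constant")
        if isinstance(form, list):
            form = tuple(form)
        kwargs = {"form": form, "stratified": bool(d.get("stratified", False))}
        if "knots" in d:
            kwargs["knots"] = tuple(float(k) for k in d["knots"])
        if "stratum_bounds" in d:
            kwargs["stratum_bounds"] = tuple(float(b) for b in d["stratum_bounds"])
        return LinkSpec(**kwargs)

    try:
        return ModelSpec(
            phi1_spec=link_spec(cfg.get("phi1")),
            phi2_spec=link_spec(cfg.get("phi2")),
            heavy_tails=bool(cfg.get("heavy_tails", False)),
            quadrature=QuadratureConfig(int(cfg.get("n_quad", 15))),
            name=str(cfg.get("name", "")),
        )
    except (ValueError, TypeError) as err:
        raise ValueError(f"invalid model configuration {path}: {err}") from err
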