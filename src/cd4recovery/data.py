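"""Subject-level data containers and validation.

A :class:`SubjectRecord` is the unit of independence in the model: one
subject's pre-treatment series (times in years from seroconversion, values
on the analysis scale), post-treatment series (times in years from
treatment initiation, strictly positive) and the time from seroconversion
to treatment initiation ``t_trt``.  Time zero of the post phase belongs to
the latent baseline ``u``, never to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubjectRecord", "validate_subject"]


@dataclass
class SubjectRecord:
    subject_id: str
    t_pre: np.ndarray
    y_pre: np.ndarray
    t_post: np.ndarray
    y_post: np.ndarray
    t_trt: float
    latents: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t_pre = np.atleast_1d(np.asarray(self.t_pre, dtype=float))
        self.y_pre = np.atleast_1d(np.asarray(self.y_pre, dtype=float))
        self.t_post = np.atleast_1d(np.asarray(self.t_post, dtype=float))
        self.y_post = np.atleast_1d(np.asarray(self.y_post, dtype=float))
        if self.t_pre.size:
            order = np.argsort(self.t_pre, kind="stable")
            self.t_pre, self.y_pre = self.t_pre[order], self.y_pre[order]
        if self.t_post.size:
            order = np.argsort(self.t_post, kind="stable")
            self.t_post, self.y_post = self.t_post[order], self.y_post[order]
        self.t_trt = float(self.t_trt)

    @property
    def n_pre(self) -> int:
        return int(self.t_pre.size)

    @property
    def n_post(self) -> int:
        return int(self.t_post.size)


def validate_subject(rec: SubjectRecord, require_post: bool = True) -> list[str]:
    """Return a list of human-readable violations (empty if valid).

    The invariants mirror the cohort schema: pre times strictly before
    ``t_trt``, post times strictly positive, at least one post observation,
    all values finite.
    """
    problems: list[str] = []
    sid = rec.subject_id
    if rec.t_pre.size != rec.y_pre.size:
        problems.append(f"{sid}: pre time/value length mismatch")
    if rec.t_post.size != rec.y_post.size:
        problems.append(f"{sid}: post time/value length mismatch")
    if not np.isfinite(rec.t_trt) or rec.t_trt < 0:
        problems.append(f"{sid}: t_trt must be finite and >= 0, got {rec.t_trt}")
    for name, arr in (("pre times", rec.t_pre), ("pre values", rec.y_pre),
                      ("post times", rec.t_post), ("post values", rec.y_post)):
        if not np.all(np.isfinite(arr)):
            problems.append(f"{sid}: non-finite {name}")
    if rec.t_pre.size and np.any(rec.t_pre < 0):
        problems.append(f"{sid}: negative pre-treatment times")
    if rec.t_pre.size and np.any(rec.t_pre >= rec.t_trt):
        problems.append(f"{sid}: pre-treatment observation at or after t_trt")
    if rec.t_post.size and np.any(rec.t_post <= 0):
        problems.append(f"{sid}: post-treatment observation at time <= 0")
    if require_post and rec.t_post.size == 0:
        problems.append(f"{sid}: no post-treatment observations")
    return problems
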