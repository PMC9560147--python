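"""Synthetic per-subject condition-level activity and behavior.

Real inputs to this analysis are per-subject, per-ROI GLM beta estimates
for the 12 task conditions plus behavioral error rates.  The generator
emulates exactly that interface: condition-level activity is a link
function of the model-predicted information costs (I1, I2) plus
independent homoscedastic Gaussian noise — the assumption under which
ordinary least squares and the nested F-test are exact — and the error
rate is a binomial realization of the model's predicted error
probability 1 - E[U] over the session's trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .information import Hypothesis
from .links import LINKS


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth generative parameters of one simulated subject."""

    subject_id: str
    hypothesis: Hypothesis
    beta1: float
    beta2: float
    alpha0: float = 0.0
    alpha1: float = 1.0
    alpha2: float = 1.0
    link: str = "linear"
    noise_sd: float = 0.0
    n_trials: int = 120
    seed: int = 0
    roi_label: str = "synthetic-roi"

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("alpha1 and alpha2 must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")


@dataclass
class SubjectConditionBetas:
    """One subject's regression target: 12 condition-level activity
    estimates (canonical condition order) and a behavioral error rate."""

    subject_id: str
    roi_label: str
    conditions: tuple
    betas: np.ndarray
    error_rate: float


def noiseless_betas(spec, profile):
    """Mean activity per condition under the spec's link and coefficients."""
    f = LINKS[spec.link]
    return (spec.alpha0
            + spec.alpha1 * f(profile.I1_by_condition)
            + spec.alpha2 * f(profile.I2_by_condition))


def generate_subject(spec, grid):
    """Draw one subject's condition betas and behavioral error rate."""
    profile = grid.get(spec.hypothesis, spec.beta1, spec.beta2)
    rng = np.random.default_rng(spec.seed)
    mean = noiseless_betas(spec, profile)
    betas = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    p_err = min(max(1.0 - profile.EU, 0.0), 1.0)
    error_rate = rng.binomial(spec.n_trials, p_err) / spec.n_trials
    return SubjectConditionBetas(
        subject_id=spec.subject_id, roi_label=spec.roi_label,
        conditions=profile.conditions, betas=betas,
        error_rate=float(error_rate))


def generate_cohort(specs, grid):
    """Generate one record per spec plus a ground-truth manifest."""
    if not specs:
        raise ValueError("cohort must contain at least one subject")
    ids = [s.subject_id for s in specs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate subject ids: {sorted(dupes)}")
    records = [generate_subject(s, grid) for s in specs]
    manifest = {"subjects": []}
    for s in specs:
        d = asdict(s)
        d["hypothesis"] = s.hypothesis.value
        manifest["subjects"].append(d)
    return records, manifest


def cohort_to_frame(records):
    """Tidy table: one row per subject x condition, plus error rate."""
    import pandas as pd
    rows = []
    for r in records:
        for (cT, cS), b in zip(r.conditions, r.betas):
            rows.append({"subject_id": r.subject_id, "roi_label": r.roi_label,
                         "cT": cT, "cS": cS, "beta": b,
                         "error_rate": r.error_rate})
    return pd.DataFrame(rows)


def cohort_from_frame(frame):
    """Inverse of :func:`cohort_to_frame` (condition order preserved)."""
    records = []
    for sid, g in frame.groupby("subject_id", sort=False):
        records.append(SubjectConditionBetas(
            subject_id=str(sid), roi_label=str(g["roi_label"].iloc[0]),
            conditions=tuple(zip(g["cT"].astype(str), g["cS"].astype(int))),
            betas=g["beta"].to_numpy(dtype=float),
            error_rate=float(g["error_rate"].iloc[0])))
    return records


def write_cohort(records, manifest, csv_path, manifest_path):
    cohort_to_frame(records).to_csv(csv_path, index=False)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
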