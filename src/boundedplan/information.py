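"""Condition-wise information costs under the two planning hypotheses.

Both hypotheses share the memory-formation cost

    I1(c) = E_{s1|c} KL( p(m|s1) || p(m) ),

but differ in how the delay phase reduces action uncertainty:

* delayed planning (H0): only the memory-conditioned action marginal is
  formed during the delay,
  I2(c) = E_{s1|c} E_{m|s1} KL( p(a|m) || p(a) );

* concurrent prospective planning (H1): an action plan is prepared for
  every go-signal the cue makes possible,
  I2(c) = N_TS(c) * E_{s1|c} E_{m|s1} E_{s2|s1} KL( p(a|m,s2) || p(a) ),
  with multipliers N_TS = 1, 4, 4, 16 for target conditions
  '1', '11', '2', '4' (the squared number of potential targets).

All quantities are reported in bits; expectations over conditions use
the uniform 1/n_conditions design weights.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path

import numpy as np

from .solver import (LOG_FLOOR, SolverOptions, _policy_joint_ms2, _safelog,
                     mutual_informations, solve)
from .solver import expected_utility as _policy_expected_utility
from .task import geometry_signature

LN2 = math.log(2)

#: H1 plan-count multipliers per target condition (squared target count).
NTS_BY_TARGET_CONDITION = {"1": 1, "11": 4, "2": 4, "4": 16}


class Hypothesis(Enum):
    H0_DELAYED = "H0_delayed"
    H1_PROSPECTIVE = "H1_prospective"


@dataclass
class InformationProfile:
    """Per-condition information costs of one hypothesis at one capacity."""

    hypothesis: Hypothesis
    beta1: float
    beta2: float
    conditions: tuple                # (target_condition, sequence_length) pairs
    I1_by_condition: np.ndarray      # bits
    I2_by_condition: np.ndarray      # bits
    NTS_by_condition: np.ndarray     # plan multipliers (all 1 for H0)
    EI1: float                       # bits, uniform condition average
    EI2: float                       # bits
    EU: float
    converged: bool = True

    def as_dict(self):
        d = asdict(self)
        d["hypothesis"] = self.hypothesis.value
        for k in ("I1_by_condition", "I2_by_condition", "NTS_by_condition"):
            d[k] = np.asarray(d[k]).tolist()
        d["conditions"] = [list(c) for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["hypothesis"] = Hypothesis(d["hypothesis"])
        d["conditions"] = tuple(tuple(c) for c in d["conditions"])
        for k in ("I1_by_condition", "I2_by_condition", "NTS_by_condition"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def expected_utility(policy, task):
    """E[U] of the policy on the task (equals 1 - predicted error rate)."""
    return _policy_expected_utility(policy, task)


def condition_information(policy, task, hypothesis):
    """Evaluate one hypothesis's information profile for a solved policy."""
    if policy.p_m_given_s1.shape != (task.n_m, task.n_s1):
        raise ValueError("policy and task dimensions do not match")
    n_cond = task.n_conditions
    P_ms1, p_m = policy.p_m_given_s1, policy.p_m
    P_a, p_a = policy.p_a_given_ms2, policy.p_a

    # memory cost per cue, then averaged within condition
    kl_mem = (P_ms1 * (_safelog(P_ms1) - _safelog(p_m)[:, None])).sum(axis=0)
    I1 = np.array([kl_mem[task.cond_of_s1 == ci].mean()
                   for ci in range(n_cond)])

    if hypothesis is Hypothesis.H0_DELAYED:
        # action marginal given memory: p(a|m) = sum_s2 p(s2|m) p(a|m,s2)
        q_ms2 = _policy_joint_ms2(task, P_ms1)
        ps2_m = q_ms2 / np.maximum(p_m[:, None], LOG_FLOOR)
        p_am = np.einsum("ams,ms->am", P_a, ps2_m)
        kl_am = (p_am * (_safelog(p_am) - _safelog(p_a)[:, None])).sum(axis=0)
        I2 = np.array([kl_am @ P_ms1[:, task.cond_of_s1 == ci].mean(axis=1)
                       for ci in range(n_cond)])
        nts = np.ones(n_cond)
    elif hypothesis is Hypothesis.H1_PROSPECTIVE:
        kl_ms2 = np.einsum("ams,ams->ms", P_a,
                           _safelog(P_a) - _safelog(p_a)[:, None, None])
        per_entry = (P_ms1[:, task.e_s1] * kl_ms2[:, task.e_s2]).sum(axis=0)
        per_s1 = np.zeros(task.n_s1)
        np.add.at(per_s1, task.e_s1, task.e_pr * per_entry)
        nts = np.array([NTS_BY_TARGET_CONDITION[c.target_condition]
                        for c in task.conditions], dtype=float)
        I2 = nts * np.array([per_s1[task.cond_of_s1 == ci].mean()
                             for ci in range(n_cond)])
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")

    I1 = np.clip(I1, 0.0, None) / LN2
    I2 = np.clip(I2, 0.0, None) / LN2
    return InformationProfile(
        hypothesis=hypothesis, beta1=policy.beta1, beta2=policy.beta2,
        conditions=tuple((c.target_condition, c.sequence_length)
                         for c in task.conditions),
        I1_by_condition=I1, I2_by_condition=I2, NTS_by_condition=nts,
        EI1=float(I1.mean()), EI2=float(I2.mean()),
        EU=expected_utility(policy, task), converged=policy.converged,
    )


def averaging_residuals(policy, task, profiles):
    """Gap (bits) between condition-averaged costs and the global mutual
    informations computed independently from the policy joint.

    Returns a dict with the three identities: mean I1 vs I(M;S1), mean
    H0 I2 vs I(A;M), and mean H1 I2 / N_TS vs I(A;M) + I(A;S2|M).
    """
    i_ms1, i_am, i_ams2 = (x / LN2 for x in mutual_informations(policy, task))
    h0 = profiles[Hypothesis.H0_DELAYED]
    h1 = profiles[Hypothesis.H1_PROSPECTIVE]
    return {
        "I1_vs_I(M;S1)": float(h0.I1_by_condition.mean() - i_ms1),
        "I2_H0_vs_I(A;M)": float(h0.I2_by_condition.mean() - i_am),
        "I2_H1_vs_I(A;MS2)": float(
            (h1.I2_by_condition / h1.NTS_by_condition).mean() - i_ams2),
    }


@dataclass
class CapacityGrid:
    """Information profiles on a (beta1, beta2) grid, both hypotheses."""

    beta1_values: tuple
    beta2_values: tuple
    profiles: dict                   # (Hypothesis, beta1, beta2) -> profile

    def get(self, hypothesis, beta1, beta2):
        key = (hypothesis, float(beta1), float(beta2))
        if key not in self.profiles:
            pts = sorted({(b1, b2) for (_, b1, b2) in self.profiles})
            near = sorted(pts, key=lambda p: (p[0] - beta1) ** 2
                          + (p[1] - beta2) ** 2)[:3]
            raise KeyError(
                f"no profile at (beta1={beta1}, beta2={beta2}); "
                f"nearest available grid points: {near}")
        return self.profiles[key]

    def points(self):
        return [(b1, b2) for b1 in self.beta1_values
                for b2 in self.beta2_values]

    def to_frame(self):
        """Tidy table: hypothesis, beta1, beta2, cT, cS, I1, I2, NTS, EU."""
        import pandas as pd
        rows = []
        for (hyp, b1, b2), pr in sorted(
                self.profiles.items(), key=lambda kv: (kv[0][0].value,
                                                       kv[0][1], kv[0][2])):
            for i, (cT, cS) in enumerate(pr.conditions):
                rows.append({
                    "hypothesis": hyp.value, "beta1": b1, "beta2": b2,
                    "cT": cT, "cS": cS,
                    "I1_bits": pr.I1_by_condition[i],
                    "I2_bits": pr.I2_by_condition[i],
                    "NTS": pr.NTS_by_condition[i], "EU": pr.EU,
                    "converged": pr.converged,
                })
        return pd.DataFrame(rows)


def _cache_key(task, beta1, beta2, opts):
    payload = {
        "geometry": repr(geometry_signature(task.geometry)),
        "beta1": float(beta1), "beta2": float(beta2),
        "opts": {"max_iter": opts.max_iter, "tol": opts.tol,
                 "init": opts.init, "seed": opts.seed,
                 "damping": opts.damping, "identity_eps": opts.identity_eps},
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:24]


def capacity_grid(task, beta1_values, beta2_values,
                  hypotheses=(Hypothesis.H0_DELAYED, Hypothesis.H1_PROSPECTIVE),
                  opts=None, cache_dir=None):
    """Solve once per grid point and account both hypotheses per solution.

    With ``cache_dir`` set, profiles are persisted as JSON keyed by a
    content hash of (task geometry, beta pair, solver options); a rerun
    with identical configuration reloads bit-identical profiles.
    """
    if not len(beta1_values) or not len(beta2_values):
        raise ValueError("beta grids must be non-empty")
    opts = opts or SolverOptions()
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    profiles = {}
    for b1 in beta1_values:
        for b2 in beta2_values:
            entry = None
            key = _cache_key(task, b1, b2, opts) if cache else None
            if cache and (cache / f"{key}.json").exists():
                entry = json.loads((cache / f"{key}.json").read_text())
            if entry is None:
                policy = solve(task, b1, b2, opts)
                entry = {h.value: condition_information(policy, task, h).as_dict()
                         for h in hypotheses}
                if cache:
                    (cache / f"{key}.json").write_text(
                        json.dumps(entry, sort_keys=True))
            for h in hypotheses:
                profiles[(h, float(b1), float(b2))] = \
                    InformationProfile.from_dict(entry[h.value])
    return CapacityGrid(beta1_values=tuple(float(b) for b in beta1_values),
                        beta2_values=tuple(float(b) for b in beta2_values),
                        profiles=profiles)
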