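"""Fixed-point solver for the two-channel bounded-rational policy.

The agent maximizes expected utility subject to information costs on two
channels: memory formation (cue ``s1`` -> memory ``m``, inverse
temperature ``beta1``) and action selection (``(m, s2)`` -> sequence
``a``, inverse temperature ``beta2``),

    max  E[U] - (1/beta1) I(M;S1) - (1/beta2) (I(A;M) + I(A;S2|M)),

over ``p(m|s1)`` and ``p(a|m,s2)``, with the joint factorized through the
task tables.  The optimum satisfies a self-consistent system of softmax /
marginal equations which this module iterates to convergence (a
Blahut--Arimoto-style alternating maximization).  All exponentials use
natural log internally; information is converted to bits only at
reporting boundaries.

A note on initialization: the exactly uniform memory channel is an
invariant point of the update map (an uninformative memory makes the
target posterior, and hence the free-energy gain, independent of ``m``),
so iterating from a uniform ``p(m|s1)`` never leaves the information-free
policy.  The default is therefore a deterministic near-identity
initialization on the M = S1 index space, which breaks the symmetry and,
of all initializations we provide, attains the best variational objective
at high capacity.  Uniform and seeded random initializations remain
available for basin exploration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

LOG_FLOOR = 1e-300
logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverOptions:
    max_iter: int = 10_000
    tol: float = 1e-10
    init: str = "identity"          # identity | uniform | random
    seed: int | None = None         # used only for random init
    damping: float = 0.0            # 0 = plain updates
    identity_eps: float = 1e-6      # off-diagonal mass of the identity init
    track_history: bool = False     # record objective/EU per sweep

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.init not in ("identity", "uniform", "random"):
            raise ValueError(f"unknown init {self.init!r}")
        if not 0.0 <= self.damping < 1.0:
            raise ValueError("damping must lie in [0, 1)")


@dataclass
class AgentPolicy:
    """Solution distributions of the two-channel trade-off at (beta1, beta2).

    Conditionals are stored with the outcome axis first:
    ``p_m_given_s1[m, s1]``, ``p_a_given_ms2[a, m, s2]``,
    ``p_w_given_ms2[w, m, s2]``.
    """

    beta1: float
    beta2: float
    p_m_given_s1: np.ndarray
    p_m: np.ndarray
    p_a_given_ms2: np.ndarray
    p_a: np.ndarray
    p_w_given_ms2: np.ndarray
    converged: bool
    n_iter: int
    objective_value: float = np.nan
    residual: float = np.nan
    objective_history: list = field(default_factory=list, repr=False)


def _safelog(x):
    return np.log(np.maximum(x, LOG_FLOOR))


def _softmax_over_axis0(log_weights):
    log_weights = log_weights - log_weights.max(axis=0, keepdims=True)
    p = np.exp(log_weights)
    p /= p.sum(axis=0, keepdims=True)
    return p


class _TaskArrays:
    """Per-target index groups that turn the sparse (s1, s2) support into
    dense matrix operations (the support has one entry per cued target)."""

    def __init__(self, task):
        self.task = task
        self.U = task.utility_matrix().astype(float)
        # entry weights: p(s1) * p(s2|s1) for each support entry
        joint = task.p_s1[task.e_s1] * task.e_pr
        self.groups = []  # per target w: (s2, s1 indices, joint wts, pr wts)
        for w in range(task.n_w):
            sel = task.e_w == w
            self.groups.append((
                int(task.frame_of_w[w]),
                task.e_s1[sel],
                joint[sel],
                task.e_pr[sel],
            ))

    def posterior_and_joint(self, P_ms1, pw_s2_prior):
        """p(w|m,s2) from the joint, plus p(m,s2).

        Degenerate (m, s2) pairs with zero mass get the s2-conditioned
        prior over targets (they carry no weight downstream).
        """
        task = self.task
        num = np.zeros((task.n_w, task.n_m, task.n_s2))
        for w, (s2, idx, wts, _) in enumerate(self.groups):
            num[w, :, s2] = P_ms1[:, idx] @ wts
        q_ms2 = num.sum(axis=0)                      # p(m, s2)
        mass = np.maximum(q_ms2, LOG_FLOOR)
        Pw = num / mass[None, :, :]
        degenerate = q_ms2 <= 0
        if degenerate.any():
            Pw[:, degenerate] = pw_s2_prior[:, np.nonzero(degenerate)[1]]
        return Pw, q_ms2

    def delta_free_energy_table(self, hit, kl_ms2, inv_beta2):
        """dF[m, s1] accumulated over each cue's go-signal support."""
        task = self.task
        dF = np.zeros((task.n_m, task.n_s1))
        for w, (s2, idx, _, pr) in enumerate(self.groups):
            dF[:, idx] += (hit[w, :, s2] - inv_beta2 * kl_ms2[:, s2])[:, None] \
                * pr[None, :]
        return dF


def _initial_memory(task, opts):
    n_m, n_s1 = task.n_m, task.n_s1
    if opts.init == "uniform":
        P = np.full((n_m, n_s1), 1.0 / n_m)
    elif opts.init == "identity":
        P = np.full((n_m, n_s1), opts.identity_eps)
        P[np.arange(n_s1), np.arange(n_s1)] = 1.0
        P /= P.sum(axis=0, keepdims=True)
    else:
        rng = np.random.default_rng(opts.seed)
        P = rng.random((n_m, n_s1))
        P /= P.sum(axis=0, keepdims=True)
    return P


def solve(task, beta1, beta2, opts=None):
    """Iterate the self-consistent equations to a fixed point.

    Returns an :class:`AgentPolicy`; ``converged`` is False (with a
    logged warning) if the maximum absolute change of any distribution
    still exceeds ``opts.tol`` after ``opts.max_iter`` sweeps.
    ``beta = 0`` on a channel forces that channel to its prior (the
    softmax weights collapse), which is the information-free limit.
    """
    if beta1 < 0 or beta2 < 0:
        raise ValueError("inverse temperatures must be nonnegative")
    opts = opts or SolverOptions()
    arrays = _TaskArrays(task)
    toa = task.target_of_action
    inv_b2 = 0.0 if beta2 == 0 else 1.0 / beta2

    # s2-conditioned target prior (fallback for zero-mass memory states)
    pw_s2 = np.zeros((task.n_w, task.n_s2))
    joint = task.p_s1[task.e_s1] * task.e_pr
    np.add.at(pw_s2, (task.e_w, task.e_s2), joint)
    pw_s2 /= np.maximum(pw_s2.sum(axis=0, keepdims=True), LOG_FLOOR)

    P_ms1 = _initial_memory(task, opts)
    p_m = P_ms1 @ task.p_s1
    P_a = np.full((task.n_a, task.n_m, task.n_s2), 1.0 / task.n_a)
    p_a = np.full(task.n_a, 1.0 / task.n_a)

    history = []
    converged = False
    delta = np.inf
    lam = opts.damping
    for sweep in range(opts.max_iter):
        Pw, q_ms2 = arrays.posterior_and_joint(P_ms1, pw_s2)
        # action channel: p(a|m,s2) ~ p(a) exp(beta2 * p(w_a|m,s2))
        P_a_new = _softmax_over_axis0(
            _safelog(p_a)[:, None, None] + beta2 * Pw[toa])
        if lam:
            P_a_new = (1 - lam) * P_a_new + lam * P_a
        p_a_new = np.einsum("ams,ms->a", P_a_new, q_ms2)
        # free-energy gain of each (m, s1)
        kl_ms2 = np.einsum("ams,ams->ms", P_a_new,
                           _safelog(P_a_new) - _safelog(p_a_new)[:, None, None])
        hit = P_a_new.reshape(task.n_w, 2, task.n_m, task.n_s2).sum(axis=1)
        dF = arrays.delta_free_energy_table(hit, kl_ms2, inv_b2)
        # memory channel: p(m|s1) ~ p(m) exp(beta1 * dF)
        P_ms1_new = _softmax_over_axis0(_safelog(p_m)[:, None] + beta1 * dF)
        if lam:
            P_ms1_new = (1 - lam) * P_ms1_new + lam * P_ms1
        p_m_new = P_ms1_new @ task.p_s1

        delta = max(np.abs(P_a_new - P_a).max(), np.abs(p_a_new - p_a).max(),
                    np.abs(P_ms1_new - P_ms1).max(), np.abs(p_m_new - p_m).max())
        P_a, p_a, P_ms1, p_m = P_a_new, p_a_new, P_ms1_new, p_m_new

        if opts.track_history:
            history.append(_objective_terms(
                task, arrays, P_ms1, p_m, P_a, p_a, beta1, beta2))
        if delta < opts.tol:
            converged = True
            break

    Pw, q_ms2 = arrays.posterior_and_joint(P_ms1, pw_s2)
    policy = AgentPolicy(
        beta1=float(beta1), beta2=float(beta2),
        p_m_given_s1=P_ms1, p_m=p_m, p_a_given_ms2=P_a, p_a=p_a,
        p_w_given_ms2=Pw, converged=converged, n_iter=sweep + 1,
        residual=float(delta), objective_history=history,
    )
    policy.objective_value = variational_objective(policy, task)
    if not converged:
        logger.warning(
            "solver did not converge at (beta1=%g, beta2=%g): residual %.3g "
            "after %d sweeps", beta1, beta2, delta, policy.n_iter)
    return policy


def _policy_joint_ms2(task, P_ms1):
    """p(m, s2) under the current memory channel."""
    q = np.zeros((task.n_m, task.n_s2))
    joint = task.p_s1[task.e_s1] * task.e_pr
    contrib = joint[:, None] * P_ms1[:, task.e_s1].T
    np.add.at(q.T, task.e_s2, contrib)
    return q


def mutual_informations(policy, task):
    """(I(M;S1), I(A;M), I(A;M)+I(A;S2|M)) in nats, from the policy joint."""
    P_ms1, p_m = policy.p_m_given_s1, policy.p_m
    P_a, p_a = policy.p_a_given_ms2, policy.p_a
    i_ms1 = float(
        ((P_ms1 * (_safelog(P_ms1) - _safelog(p_m)[:, None])).sum(axis=0)
         * task.p_s1).sum())
    q_ms2 = _policy_joint_ms2(task, P_ms1)
    ps2_m = q_ms2 / np.maximum(p_m[:, None], LOG_FLOOR)
    p_am = np.einsum("ams,ms->am", P_a, ps2_m)
    i_am = float(
        ((p_am * (_safelog(p_am) - _safelog(p_a)[:, None])).sum(axis=0)
         * p_m).sum())
    kl_ms2 = np.einsum("ams,ams->ms", P_a,
                       _safelog(P_a) - _safelog(p_a)[:, None, None])
    i_ams2 = float((kl_ms2 * q_ms2).sum())
    return i_ms1, i_am, i_ams2


def expected_utility(policy, task):
    """E[U] over the policy-induced joint (equals 1 - error rate)."""
    hit = policy.p_a_given_ms2.reshape(
        task.n_w, 2, task.n_m, task.n_s2).sum(axis=1)
    joint = task.p_s1[task.e_s1] * task.e_pr
    per_entry = (policy.p_m_given_s1[:, task.e_s1]
                 * hit[task.e_w, :, task.e_s2].T).sum(axis=0)
    return float((joint * per_entry).sum())


def _objective_terms(task, arrays, P_ms1, p_m, P_a, p_a, beta1, beta2):
    pol = AgentPolicy(beta1, beta2, P_ms1, p_m, P_a, p_a,
                      p_w_given_ms2=None, converged=False, n_iter=0)
    eu = expected_utility(pol, task)
    i1, _, i2 = mutual_informations(pol, task)
    obj = eu
    if beta1 > 0:
        obj -= i1 / beta1
    if beta2 > 0:
        obj -= i2 / beta2
    return {"expected_utility": eu, "i_ms1_nats": i1, "i_ams2_nats": i2,
            "objective": obj}


def variational_objective(policy, task):
    """E[U] - I(M;S1)/beta1 - (I(A;M)+I(A;S2|M))/beta2, in natural units.

    A zero inverse temperature forces the corresponding channel to its
    prior, whose information is exactly zero, so the penalty term is
    dropped rather than evaluated as 0 * inf.
    """
    eu = expected_utility(policy, task)
    i1, _, i2 = mutual_informations(policy, task)
    obj = eu
    if policy.beta1 > 0:
        obj -= i1 / policy.beta1
    if policy.beta2 > 0:
        obj -= i2 / policy.beta2
    return float(obj)


def delta_free_energy(policy, task, m, s1):
    """Free-energy gain dF(m, s1): expected utility of acting from
    memory ``m`` on cue ``s1``, minus the capacity-weighted action
    information cost, exactly as the memory update uses it."""
    if not 0 <= m < task.n_m:
        raise IndexError(f"memory index {m} out of range")
    if not 0 <= s1 < task.n_s1:
        raise IndexError(f"cue index {s1} out of range")
    inv_b2 = 0.0 if policy.beta2 == 0 else 1.0 / policy.beta2
    sel = task.e_s1 == s1
    total = 0.0
    for s2, w, pr in zip(task.e_s2[sel], task.e_w[sel], task.e_pr[sel]):
        p_act = policy.p_a_given_ms2[:, m, s2]
        util = p_act[task.target_of_action == w].sum()
        kl = float((p_act * (_safelog(p_act) - _safelog(policy.p_a))).sum())
        total += pr * (util - inv_b2 * kl)
    return float(total)


def check_normalization(policy, task, atol=1e-9):
    """Verify the stored conditionals and marginals are consistent."""
    assert np.allclose(policy.p_m_given_s1.sum(axis=0), 1.0, atol=atol)
    assert np.allclose(policy.p_a_given_ms2.sum(axis=0), 1.0, atol=atol)
    assert np.allclose(policy.p_m, policy.p_m_given_s1 @ task.p_s1, atol=atol)
    q = _policy_joint_ms2(task, policy.p_m_given_s1)
    p_a = np.einsum("ams,ms->a", policy.p_a_given_ms2, q)
    assert np.allclose(policy.p_a, p_a, atol=atol)
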