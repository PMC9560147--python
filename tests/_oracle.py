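"""Independent straight-loop reference implementation.

Everything here is written as plain Python loops over explicit
probability tables, with no vectorization and no reuse of the package's
numerics, so it can serve as an oracle for the solver and the
information accounting on small task geometries.
"""

import math

FLOOR = 1e-300


def _tables(task):
    """Task tables as plain Python structures."""
    n_s1, n_s2 = task.n_s1, task.n_s2
    p_s1 = [float(x) for x in task.p_s1]
    supp = {s1: [] for s1 in range(n_s1)}  # s1 -> [(s2, prob, w)]
    for s1, s2, w, pr in zip(task.e_s1, task.e_s2, task.e_w, task.e_pr):
        supp[int(s1)].append((int(s2), float(pr), int(w)))
    actions_of_w = {w: [a for a in range(task.n_a)
                        if task.target_of_action[a] == w]
                    for w in range(task.n_w)}
    return p_s1, supp, actions_of_w


def oracle_solve(task, beta1, beta2, n_sweeps, identity_eps=1e-6):
    """Run the coupled updates for a fixed number of sweeps (loops only)."""
    n_w, n_a, n_s1, n_s2 = task.n_w, task.n_a, task.n_s1, task.n_s2
    n_m = n_s1
    p_s1, supp, actions_of_w = _tables(task)

    # near-identity memory init
    p_m_s1 = [[identity_eps + (1.0 if m == s1 else 0.0) for m in range(n_m)]
              for s1 in range(n_s1)]
    for s1 in range(n_s1):
        z = sum(p_m_s1[s1])
        p_m_s1[s1] = [v / z for v in p_m_s1[s1]]
    p_m = [sum(p_s1[s1] * p_m_s1[s1][m] for s1 in range(n_s1))
           for m in range(n_m)]
    p_a_ms2 = [[[1.0 / n_a] * n_a for _ in range(n_s2)] for _ in range(n_m)]
    p_a = [1.0 / n_a] * n_a

    # s2-conditioned target prior (fallback for zero-mass memory states)
    pw_s2 = [[0.0] * n_w for _ in range(n_s2)]
    for s1 in range(n_s1):
        for (s2, pr, w) in supp[s1]:
            pw_s2[s2][w] += p_s1[s1] * pr
    for s2 in range(n_s2):
        z = sum(pw_s2[s2])
        if z > 0:
            pw_s2[s2] = [v / z for v in pw_s2[s2]]

    inv_b2 = 0.0 if beta2 == 0 else 1.0 / beta2

    def posterior():
        pw = [[[0.0] * n_w for _ in range(n_s2)] for _ in range(n_m)]
        for m in range(n_m):
            for s2 in range(n_s2):
                mass = 0.0
                for s1 in range(n_s1):
                    for (s2b, pr, w) in supp[s1]:
                        if s2b == s2:
                            wgt = p_s1[s1] * pr * p_m_s1[s1][m]
                            pw[m][s2][w] += wgt
                            mass += wgt
                if mass > 0:
                    pw[m][s2] = [v / mass for v in pw[m][s2]]
                else:
                    pw[m][s2] = list(pw_s2[s2])
        return pw

    for _ in range(n_sweeps):
        pw = posterior()
        # action channel
        for m in range(n_m):
            for s2 in range(n_s2):
                logits = [math.log(max(p_a[a], FLOOR))
                          + beta2 * pw[m][s2][task.target_of_action[a]]
                          for a in range(n_a)]
                mx = max(logits)
                ex = [math.exp(v - mx) for v in logits]
                z = sum(ex)
                p_a_ms2[m][s2] = [v / z for v in ex]
        # action prior
        p_a = [0.0] * n_a
        for s1 in range(n_s1):
            for (s2, pr, w) in supp[s1]:
                for m in range(n_m):
                    wgt = p_s1[s1] * pr * p_m_s1[s1][m]
                    for a in range(n_a):
                        p_a[a] += wgt * p_a_ms2[m][s2][a]
        # free-energy gain and memory channel
        dF = [[0.0] * n_m for _ in range(n_s1)]
        for s1 in range(n_s1):
            for m in range(n_m):
                tot = 0.0
                for (s2, pr, w) in supp[s1]:
                    util = sum(p_a_ms2[m][s2][a] for a in actions_of_w[w])
                    kl = sum(p_a_ms2[m][s2][a]
                             * (math.log(max(p_a_ms2[m][s2][a], FLOOR))
                                - math.log(max(p_a[a], FLOOR)))
                             for a in range(n_a))
                    tot += pr * (util - inv_b2 * kl)
                dF[s1][m] = tot
        for s1 in range(n_s1):
            logits = [math.log(max(p_m[m], FLOOR)) + beta1 * dF[s1][m]
                      for m in range(n_m)]
            mx = max(logits)
            ex = [math.exp(v - mx) for v in logits]
            z = sum(ex)
            p_m_s1[s1] = [v / z for v in ex]
        p_m = [sum(p_s1[s1] * p_m_s1[s1][m] for s1 in range(n_s1))
               for m in range(n_m)]

    return {"p_m_s1": p_m_s1, "p_m": p_m, "p_a_ms2": p_a_ms2, "p_a": p_a,
            "p_w_ms2": posterior()}


def oracle_information(task, sol, hypothesis_name):
    """Per-condition I1/I2 (bits) and E[U] by full-joint summation."""
    n_a, n_s1 = task.n_a, task.n_s1
    n_m = n_s1
    p_s1, supp, actions_of_w = _tables(task)
    p_m_s1, p_m = sol["p_m_s1"], sol["p_m"]
    p_a_ms2, p_a = sol["p_a_ms2"], sol["p_a"]
    nts_of = {"1": 1, "11": 4, "2": 4, "4": 16}
    n_cond = task.n_conditions
    members = {ci: [s1 for s1 in range(n_s1) if task.cond_of_s1[s1] == ci]
               for ci in range(n_cond)}

    I1, I2 = [], []
    for ci, cond in enumerate(task.conditions):
        i1 = i2 = 0.0
        for s1 in members[ci]:
            w1 = 1.0 / len(members[ci])
            for m in range(n_m):
                if p_m_s1[s1][m] > 0:
                    i1 += w1 * p_m_s1[s1][m] * math.log(
                        p_m_s1[s1][m] / max(p_m[m], FLOOR))
            if hypothesis_name == "H0":
                for m in range(n_m):
                    # p(a|m) via p(s2|m) = sum_s1 p(s2|s1) p(s1|m)
                    p_am = [0.0] * n_a
                    if p_m[m] <= 0:
                        continue
                    for s1b in range(n_s1):
                        for (s2, pr, w) in supp[s1b]:
                            wgt = p_s1[s1b] * pr * p_m_s1[s1b][m] / p_m[m]
                            for a in range(n_a):
                                p_am[a] += wgt * p_a_ms2[m][s2][a]
                    kl = sum(p_am[a] * math.log(max(p_am[a], FLOOR)
                                                / max(p_a[a], FLOOR))
                             for a in range(n_a) if p_am[a] > 0)
                    i2 += w1 * p_m_s1[s1][m] * kl
            else:
                nts = nts_of[cond.target_condition]
                for m in range(n_m):
                    for (s2, pr, w) in supp[s1]:
                        kl = sum(p_a_ms2[m][s2][a]
                                 * math.log(max(p_a_ms2[m][s2][a], FLOOR)
                                            / max(p_a[a], FLOOR))
                                 for a in range(n_a) if p_a_ms2[m][s2][a] > 0)
                        i2 += w1 * p_m_s1[s1][m] * pr * nts * kl
        I1.append(max(i1, 0.0) / math.log(2))
        I2.append(max(i2, 0.0) / math.log(2))

    eu = 0.0
    for s1 in range(n_s1):
        for (s2, pr, w) in supp[s1]:
            for m in range(n_m):
                eu += p_s1[s1] * pr * p_m_s1[s1][m] * sum(
                    p_a_ms2[m][s2][a] for a in actions_of_w[w])
    return {"I1": I1, "I2": I2, "EU": eu}


def enumerate_mini_cues(n_panels=2):
    """Exhaustive combinatorial enumeration of the mini-task cue sets,
    independent of the package's enumeration code.

    Targets are (panel, half) pairs at distance 2 (one per half).
    """
    import itertools
    targets = [(p, h) for p in range(n_panels) for h in (0, 1)]
    cues = {}
    cues[("1", 2)] = [frozenset([t]) for t in targets]
    cues[("11", 2)] = [frozenset([(p, 0), (p, 1)]) for p in range(n_panels)]
    cues[("2", 2)] = [frozenset([(p1, h1), (p2, h2)])
                      for (p1, p2) in itertools.combinations(range(n_panels), 2)
                      for h1 in (0, 1) for h2 in (0, 1)]
    return cues
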