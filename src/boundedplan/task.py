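"""Generative structure of the delayed-response planning task.

The task presents a cue stimulus ``s1`` (a set of potential target
locations), a delay, and then a go-signal ``s2`` (a half-frame over one
response panel) that disambiguates the hidden target ``w``.  The agent
responds with a button-press movement sequence ``a``.  This module builds
the finite alphabets W (targets), A (movement sequences), S2 (go-signals)
and S1 (cue stimuli) together with every task-defined probability table
and the 0/1 utility matrix, from a small configurable panel geometry.

The default geometry has 4 panels, each split into two halves, with one
distance-2, two distance-3 and two distance-4 targets per half.  This is
the unique half/distance layout compatible with the condition-wise cue
counts of the experimental design (e.g. exactly 4 two-target same-panel
cues at sequence length 2), and it yields |W| = 40, |A| = 80, |S2| = 8 and
|S1| = 820.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

TARGET_CONDITIONS = ("1", "11", "2", "4")
SEQUENCE_LENGTHS = (2, 3, 4)

#: Number of cue stimuli per condition in the default geometry, keyed by
#: (target_condition, sequence_length).
DEFAULT_CUE_COUNTS = {
    ("1", 2): 8, ("1", 3): 16, ("1", 4): 16,
    ("11", 2): 4, ("11", 3): 16, ("11", 4): 16,
    ("2", 2): 24, ("2", 3): 96, ("2", 4): 96,
    ("4", 2): 16, ("4", 3): 256, ("4", 4): 256,
}


class TaskValidationError(ValueError):
    """Raised when a geometry violates a structural constraint.

    The message names the first violated cardinality so configuration
    errors are directly actionable.
    """


@dataclass(frozen=True)
class Condition:
    """One cell of the 4 x 3 experimental design.

    ``target_condition`` encodes the multiplicity and placement of the
    potential targets ('1' one target, '11' two targets in the same
    panel, '2' two targets in different panels, '4' one target in every
    panel); ``sequence_length`` is the button-press distance of all cued
    targets (2, 3 or 4).
    """

    target_condition: str
    sequence_length: int

    def __post_init__(self):
        if self.target_condition not in TARGET_CONDITIONS:
            raise TaskValidationError(
                f"unknown target condition {self.target_condition!r}")
        if self.sequence_length not in SEQUENCE_LENGTHS:
            raise TaskValidationError(
                f"unknown sequence length {self.sequence_length!r}")

    def __str__(self):
        return f"({self.target_condition},{self.sequence_length})"


DEFAULT_CONDITIONS = tuple(
    Condition(cT, cS) for cT in TARGET_CONDITIONS for cS in SEQUENCE_LENGTHS
)

#: Default lattice offsets per half, keyed by distance (L1 norm).  Both
#: coordinates are nonzero so the two extremal monotone button-press
#: sequences (horizontal-first vs vertical-first) are distinct.
DEFAULT_OFFSETS = {2: ((1, 1),), 3: ((1, 2), (2, 1)), 4: ((1, 3), (3, 1))}


@dataclass(frozen=True)
class PanelGeometry:
    """Abstract screen geometry: panels, halves and target slots.

    Only the set relations matter for the model (which targets share a
    panel or a half-frame, and their sequence lengths); the lattice
    offsets serve as stable labels and document the two-path structure of
    the action set.
    """

    n_panels: int = 4
    offsets_per_half: dict = field(
        default_factory=lambda: {d: tuple(v) for d, v in DEFAULT_OFFSETS.items()})
    actions_per_target: int = 2
    conditions: tuple = DEFAULT_CONDITIONS

    def validate(self):
        if self.n_panels < 2:
            raise TaskValidationError("need at least 2 panels")
        if self.actions_per_target != 2:
            raise TaskValidationError(
                "exactly 2 movement sequences per target are supported")
        for d, offs in self.offsets_per_half.items():
            for (dx, dy) in offs:
                if abs(dx) + abs(dy) != d:
                    raise TaskValidationError(
                        f"offset {(dx, dy)} does not have L1 distance {d}")
                if dx == 0 or dy == 0:
                    raise TaskValidationError(
                        f"offset {(dx, dy)} lies on an axis; its two extremal "
                        "monotone paths coincide")
        for c in self.conditions:
            if c.sequence_length not in self.offsets_per_half:
                raise TaskValidationError(
                    f"condition {c} requires distance-{c.sequence_length} targets "
                    "which the geometry does not provide")
            if c.target_condition == "4" and self.n_panels != 4:
                raise TaskValidationError(
                    "condition '4' (one target per panel) requires 4 panels")


MINI_GEOMETRY = PanelGeometry(
    n_panels=2,
    offsets_per_half={2: ((1, 1),)},
    conditions=(Condition("1", 2), Condition("11", 2), Condition("2", 2)),
)


@dataclass
class TaskStructure:
    """All alphabets and probability tables of the task.

    Index spaces are 0-based with a fixed, documented enumeration order:
    targets sorted by (panel, half, distance, offset); actions by
    (target, path variant); go-signals by (panel, half); cue stimuli by
    (condition, sorted target tuple).  The memory alphabet M is
    identified index-for-index with S1.
    """

    geometry: PanelGeometry
    conditions: tuple                  # tuple[Condition]
    targets: list                      # list[(panel, half, dist, offset)]
    frame_of_w: np.ndarray             # (n_w,) go-signal index of each target
    dist_of_w: np.ndarray              # (n_w,) sequence length of each target
    target_of_action: np.ndarray       # (n_a,) target index of each action
    cue_targets: list                  # list[tuple[int]] targets of each s1
    cond_of_s1: np.ndarray             # (n_s1,) condition index
    p_s1: np.ndarray                   # (n_s1,) marginal cue distribution
    # flattened support of p(s2|s1): one entry per (s1, cued target)
    e_s1: np.ndarray
    e_s2: np.ndarray
    e_w: np.ndarray
    e_pr: np.ndarray                   # p(s2|s1) on the support

    # -- derived sizes ----------------------------------------------------
    @property
    def n_w(self):
        return len(self.targets)

    @property
    def n_a(self):
        return len(self.target_of_action)

    @property
    def n_s2(self):
        return 2 * self.geometry.n_panels

    @property
    def n_s1(self):
        return len(self.cue_targets)

    @property
    def n_m(self):
        return self.n_s1

    @property
    def n_conditions(self):
        return len(self.conditions)

    # -- tables -----------------------------------------------------------
    def utility_matrix(self):
        """0/1 utility U(w, a): 1 iff sequence ``a`` reaches target ``w``."""
        U = np.zeros((self.n_w, self.n_a), dtype=np.uint8)
        U[self.target_of_action, np.arange(self.n_a)] = 1
        return U

    def p_s2_given_s1(self):
        """Dense (n_s1, n_s2) go-signal table; rows sum to 1."""
        P = np.zeros((self.n_s1, self.n_s2))
        P[self.e_s1, self.e_s2] = self.e_pr
        return P

    def w_of_s1s2(self):
        """Deterministic (n_s1, n_s2) target map; -1 off the support."""
        W = np.full((self.n_s1, self.n_s2), -1, dtype=np.int64)
        W[self.e_s1, self.e_s2] = self.e_w
        return W

    def p_s1_given_condition(self):
        """(n_conditions, n_s1) uniform-within-condition cue table."""
        P = np.zeros((self.n_conditions, self.n_s1))
        for ci in range(self.n_conditions):
            mask = self.cond_of_s1 == ci
            P[ci, mask] = 1.0 / mask.sum()
        return P

    # -- queries ----------------------------------------------------------
    def condition_index(self, condition):
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise TaskValidationError(f"unknown condition {condition}") from None

    def cue_set(self, condition):
        """Indices of the cue stimuli belonging to one condition."""
        ci = self.condition_index(condition)
        return set(np.flatnonzero(self.cond_of_s1 == ci))

    def go_signal_support(self, s1):
        """Go-signal indices with p(s2|s1) > 0, in index order."""
        if not 0 <= s1 < self.n_s1:
            raise IndexError(f"cue index {s1} out of range")
        return sorted(self.e_s2[self.e_s1 == s1])

    def w_of(self, s1, s2):
        """The unique cued target of ``s1`` inside half-frame ``s2``."""
        hit = (self.e_s1 == s1) & (self.e_s2 == s2)
        if not hit.any():
            raise TaskValidationError(
                f"go-signal {s2} is not in the support of cue {s1}")
        return int(self.e_w[hit][0])

    def cue_counts(self):
        """Observed cue-set size per condition (dict keyed like the design)."""
        return {
            (c.target_condition, c.sequence_length):
                int((self.cond_of_s1 == ci).sum())
            for ci, c in enumerate(self.conditions)
        }

    def describe(self):
        """Cardinalities as a tidy table (one row per named quantity)."""
        import pandas as pd
        rows = [("|W|", self.n_w), ("|A|", self.n_a), ("|S2|", self.n_s2),
                ("|S1|", self.n_s1), ("|M|", self.n_m)]
        rows += [(f"N_{cT},{cS}", n)
                 for (cT, cS), n in sorted(self.cue_counts().items())]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def _enumerate_targets(geometry):
    targets = []
    for p in range(geometry.n_panels):
        for h in (0, 1):
            for d in sorted(geometry.offsets_per_half):
                for off in sorted(geometry.offsets_per_half[d]):
                    targets.append((p, h, d, off))
    return targets


def _enumerate_cues(geometry, targets):
    """All cue stimuli per condition, as sorted target-index tuples."""
    by_panel_half_dist = {}
    for i, (p, h, d, off) in enumerate(targets):
        by_panel_half_dist.setdefault((p, h, d), []).append(i)
    panels = range(geometry.n_panels)
    cues = []
    for ci, cond in enumerate(geometry.conditions):
        cT, d = cond.target_condition, cond.sequence_length
        of_dist = [i for i, t in enumerate(targets) if t[2] == d]
        if cT == "1":
            sets = [(w,) for w in of_dist]
        elif cT == "11":
            # two targets in the same panel must occupy different halves,
            # otherwise the go-signal could not disambiguate them
            sets = []
            for p in panels:
                h0 = by_panel_half_dist.get((p, 0, d), [])
                h1 = by_panel_half_dist.get((p, 1, d), [])
                sets += [tuple(sorted(pair))
                         for pair in itertools.product(h0, h1)]
        elif cT == "2":
            sets = []
            for p1, p2 in itertools.combinations(panels, 2):
                t1 = [w for w in of_dist if targets[w][0] == p1]
                t2 = [w for w in of_dist if targets[w][0] == p2]
                sets += [tuple(sorted(pair))
                         for pair in itertools.product(t1, t2)]
        else:  # '4': one target in every panel
            per_panel = [[w for w in of_dist if targets[w][0] == p]
                         for p in panels]
            sets = [tuple(sorted(c)) for c in itertools.product(*per_panel)]
        sets.sort()
        cues += [(ci, s) for s in sets]
    return cues


def build_task(geometry=None, expected_cue_counts="auto"):
    """Construct the :class:`TaskStructure` for a geometry.

    Parameters
    ----------
    geometry
        A :class:`PanelGeometry`; ``None`` builds the default (full) task.
    expected_cue_counts
        Mapping ``(target_condition, sequence_length) -> size`` to
        validate against, ``"auto"`` to check the printed table when the
        default conditions are used, or ``None`` to skip the check.

    The enumeration is deterministic, so rebuilding with the same
    geometry yields bit-identical index assignments.
    """
    geometry = geometry or PanelGeometry()
    geometry.validate()
    targets = _enumerate_targets(geometry)
    frame_of_w = np.array([2 * p + h for (p, h, d, off) in targets])
    dist_of_w = np.array([d for (p, h, d, off) in targets])
    target_of_action = np.repeat(np.arange(len(targets)), 2)
    cues = _enumerate_cues(geometry, targets)

    cond_of_s1 = np.array([ci for ci, s in cues])
    cue_targets = [s for ci, s in cues]
    n_cond = len(geometry.conditions)
    counts = np.bincount(cond_of_s1, minlength=n_cond)
    if expected_cue_counts == "auto":
        expected_cue_counts = (DEFAULT_CUE_COUNTS
                               if geometry.conditions == DEFAULT_CONDITIONS
                               else None)
    if expected_cue_counts is not None:
        for ci, cond in enumerate(geometry.conditions):
            key = (cond.target_condition, cond.sequence_length)
            want = expected_cue_counts[key]
            if counts[ci] != want:
                raise TaskValidationError(
                    f"cue-set size N_{key[0]},{key[1]} is {counts[ci]}, "
                    f"expected {want}")

    p_s1 = 1.0 / (n_cond * counts[cond_of_s1].astype(float))

    e_s1, e_s2, e_w, e_pr = [], [], [], []
    for i, ws in enumerate(cue_targets):
        frames = [int(frame_of_w[w]) for w in ws]
        if len(set(frames)) != len(frames):
            raise TaskValidationError(
                f"cue {i} has two targets in the same half-frame; the "
                "go-signal would be ambiguous")
        for w in ws:
            e_s1.append(i)
            e_s2.append(int(frame_of_w[w]))
            e_w.append(w)
            e_pr.append(1.0 / len(ws))

    task = TaskStructure(
        geometry=geometry, conditions=tuple(geometry.conditions),
        targets=targets, frame_of_w=frame_of_w, dist_of_w=dist_of_w,
        target_of_action=target_of_action, cue_targets=cue_targets,
        cond_of_s1=cond_of_s1, p_s1=p_s1,
        e_s1=np.array(e_s1), e_s2=np.array(e_s2),
        e_w=np.array(e_w), e_pr=np.array(e_pr),
    )
    assert abs(task.p_s1.sum() - 1.0) < 1e-12
    return task


def geometry_signature(geometry):
    """Stable, hashable description of a geometry (for cache keys)."""
    return (
        geometry.n_panels,
        tuple(sorted((d, tuple(offs))
                     for d, offs in geometry.offsets_per_half.items())),
        tuple((c.target_condition, c.sequence_length)
              for c in geometry.conditions),
    )
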