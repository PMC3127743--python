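"""Independent test oracles, transcribed separately from the package code.

The scale oracles are decision-table transcriptions of the published
scoring grids (pattern rows evaluated top-down), deliberately encoded in a
different style from the package's procedural implementations so that a
transcription error in either encoding shows up as a disagreement.  The
AUC oracle is the O(n^2) all-pairs concordance count, and the rule
interpreter re-evaluates tree conditions naively from their source text.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# ADL hierarchy oracle: pattern table over the recoded (hygiene, toilet,
# locomotion, eating) quadruple.  Recode bands: 0-1 -> 0, 2 -> 1, 3 -> 2,
# 4-5 -> 3, 6 -> 4; "activity did not occur" (8) counts as total dependence.
# Pattern cells: int = exact match, (lo, hi) = inclusive range, None = any.

_R = {0: 0, 1: 0, 2: 1, 3: 2, 4: 3, 5: 3, 6: 4, 8: 4}

ADL_GRID = [
    # (hygiene, toilet, locomotion, eating) -> score
    ((4, 4, 4, 4), 6),          # total dependence in all four
    ((None, None, 4, 4), 5),    # total dependence in locomotion and eating
    ((None, None, (3, 4), None), 4),  # extensive+ in locomotion
    ((None, None, None, (3, 4)), 4),  # extensive+ in eating
    (((3, 4), None, None, None), 3),  # extensive+ in hygiene
    ((None, (3, 4), None, None), 3),  # extensive+ in toilet use
]


def _cell_matches(cell, value) -> bool:
    if cell is None:
        return True
    if isinstance(cell, tuple):
        return cell[0] <= value <= cell[1]
    return value == cell


def adl_hierarchy_oracle(hygiene: int, toilet: int, locomotion: int, eating: int) -> int:
    q = (_R[hygiene], _R[toilet], _R[locomotion], _R[eating])
    for pattern, score in ADL_GRID:
        if all(_cell_matches(c, v) for c, v in zip(pattern, q)):
            return score
    worst = max(q)
    return {0: 0, 1: 1, 2: 2}[worst]


# ---------------------------------------------------------------------------
# CPS oracle: decision list following the published scale's branch order.

def cps_oracle(comatose: int, memory: int, decision: int, understood: int, eating: int) -> int:
    if comatose == 1:
        return 6
    if decision == 3:  # severely impaired decision making
        return 6 if eating in (6, 8) else 5
    impairments = sum([memory == 1, decision in (1, 2), understood in (1, 2, 3)])
    if impairments == 0:
        return 0
    if impairments == 1:
        return 1
    severe = sum([decision == 2, understood in (2, 3)])
    return {0: 2, 1: 3, 2: 4}[severe]


# ---------------------------------------------------------------------------
# AUC oracle: all-pairs concordance with ties counted one half.

def pairwise_auc(scores, outcomes) -> float:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos = s[y]
    neg = s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        total += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Naive rule interpreter: first-match-wins over raw condition strings.

def interpret_tree(rules, default_level, env):
    for condition, level in rules:
        if eval(condition, {"__builtins__": {}}, dict(env)):  # noqa: S307 - test oracle
            return level
    return default_level
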