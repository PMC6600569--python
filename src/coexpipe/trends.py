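"""Expression-trend profiling over a three-point time course.

Each gene's expression series (t0, t1, t2) is reduced to two transitions,
t0->t1 and t1->t2, each labeled down / flat / up by comparing the
pseudocounted log2 change against a flat threshold.  The 3 x 3 grid of
transition pairs, minus the uninformative flat-flat cell, defines eight
trend profiles indexed 0-7:

    0 down-down   1 down-flat   2 down-up    3 flat-down
    4 flat-up     5 up-down     6 up-flat    7 up-up

(The raw index is 3 * first + second with down=0/flat=1/up=2; indices past
the excluded flat-flat cell shift down by one.)  Profile over-representation
is scored by a permutation test that shuffles the time labels independently
within each gene.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProfileAssignment",
    "classify_profile",
    "classify_profiles",
    "profile_significance",
    "PROFILE_OF_STATES",
]

_STATE_CODE = {"down": 0, "flat": 1, "up": 2}

#: fixed bijection from transition-state pairs (minus flat-flat) to 0-7
PROFILE_OF_STATES: dict[tuple[str, str], int] = {}
for _s1, _s2 in itertools.product(("down", "flat", "up"), repeat=2):
    _raw = 3 * _STATE_CODE[_s1] + _STATE_CODE[_s2]
    if _raw == 4:  # flat-flat: no trend
        continue
    PROFILE_OF_STATES[(_s1, _s2)] = _raw if _raw < 4 else _raw - 1


@dataclass(frozen=True)
class ProfileAssignment:
    gene_id: str
    transition_states: tuple[str, str]
    profile_index: int | None
    flat_threshold: float


def _states(series: np.ndarray, flat_threshold: float, pseudocount: float):
    if (series < 0).any():
        raise ValueError("expression series must be non-negative")
    d = np.log2(series[1:] + pseudocount) - np.log2(series[:-1] + pseudocount)
    out = []
    for change in d:
        if change >= flat_threshold:
            out.append("up")
        elif change <= -flat_threshold:
            out.append("down")
        else:
            out.append("flat")
    return tuple(out)


def classify_profile(
    series,
    flat_threshold: float = 1.0,
    gene_id: str = "",
    pseudocount: float = 1.0,
) -> ProfileAssignment:
    """Assign one 3-point expression series to a trend profile.

    A transition counts as up (down) when the pseudocounted log2 change is
    >= flat_threshold (<= -flat_threshold), else flat.  A flat-flat series
    has no profile (index None).
    """
    series = np.asarray(series, dtype=float)
    if series.shape != (3,):
        raise ValueError("series must have exactly 3 time points")
    if flat_threshold < 0:
        raise ValueError("flat_threshold must be >= 0")
    states = _states(series, flat_threshold, pseudocount)
    return ProfileAssignment(
        gene_id=gene_id,
        transition_states=states,
        profile_index=PROFILE_OF_STATES.get(states),
        flat_threshold=flat_threshold,
    )


def classify_profiles(
    expr: np.ndarray,
    gene_ids: list[str],
    flat_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Vectorized profile assignment for a genes x 3 expression matrix."""
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2 or expr.shape[1] != 3:
        raise ValueError("expression matrix must be genes x 3")
    if (expr < 0).any():
        raise ValueError("expression must be non-negative")
    idx = _profile_indices(expr, flat_threshold, pseudocount)
    states = np.array(["down", "flat", "up"])
    d = np.log2(expr + pseudocount)
    s1 = np.select(
        [d[:, 1] - d[:, 0] >= flat_threshold, d[:, 1] - d[:, 0] <= -flat_threshold],
        [2, 0],
        default=1,
    )
    s2 = np.select(
        [d[:, 2] - d[:, 1] >= flat_threshold, d[:, 2] - d[:, 1] <= -flat_threshold],
        [2, 0],
        default=1,
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "profile_index": pd.array(
                [pd.NA if i < 0 else int(i) for i in idx], dtype="Int64"
            ),
            "state1": states[s1],
            "state2": states[s2],
        }
    )


def _profile_indices(
    expr: np.ndarray, flat_threshold: float, pseudocount: float
) -> np.ndarray:
    """Profile index per row; -1 marks flat-flat (unassigned)."""
    d = np.log2(expr + pseudocount)
    t1 = d[:, 1] - d[:, 0]
    t2 = d[:, 2] - d[:, 1]
    s1 = np.select([t1 >= flat_threshold, t1 <= -flat_threshold], [2, 0], default=1)
    s2 = np.select([t2 >= flat_threshold, t2 <= -flat_threshold], [2, 0], default=1)
    raw = 3 * s1 + s2
    idx = np.where(raw < 4, raw, raw - 1)
    idx[raw == 4] = -1
    return idx


def profile_significance(
    expr: np.ndarray,
    flat_threshold: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-value for the over-representation of each profile.

    Time labels are shuffled independently within each gene; a profile's
    p-value is the fraction of permutations whose count for that profile
    reaches the observed count, with the observed arrangement included
    (add-one rule), so p is never exactly zero.

    Returns (observed counts per profile, p per profile), both length 8.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2 or expr.shape[1] != 3:
        raise ValueError("expression matrix must be genes x 3")
    if expr.shape[0] == 0:
        raise ValueError("no expression series given")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")

    observed_idx = _profile_indices(expr, flat_threshold, pseudocount)
    observed = np.bincount(observed_idx[observed_idx >= 0], minlength=8)[:8]

    perms = np.array(list(itertools.permutations(range(3))))  # 6 orderings
    rng = np.random.default_rng(seed)
    n_genes = expr.shape[0]
    exceed = np.zeros(8, dtype=np.int64)
    rows = np.arange(n_genes)[:, None]
    for _ in range(n_permutations):
        choice = rng.integers(0, 6, size=n_genes)
        shuffled = expr[rows, perms[choice]]
        idx = _profile_indices(shuffled, flat_threshold, pseudocount)
        counts = np.bincount(idx[idx >= 0], minlength=8)[:8]
        exceed += counts >= observed
    p = (exceed + 1) / (n_permutations + 1)
    return observed, p


def write_summary(
    assignments: pd.DataFrame,
    path: str | Path,
    pvalues: np.ndarray | None = None,
) -> None:
    counts = [
        int((assignments["profile_index"] == i).sum()) for i in range(8)
    ]
    payload: dict = {
        "profile_counts": counts,
        "assigned": int(sum(counts)),
        "unassigned_flat_flat": int(assignments["profile_index"].isna().sum()),
    }
    if pvalues is not None:
        payload["profile_p"] = [float(v) for v in pvalues]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
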