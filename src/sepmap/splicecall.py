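"""Sepscore-based alternative-splicing event calling.

The separation score (Sepscore) of an alternative event contrasts how its
inclusion-reporting and skip-reporting probes respond between two
conditions:

    S = median over inclusion probes of log2(mean_A / mean_B)
      - median over skip probes of log2(mean_A / mean_B)

Positive S means relatively more inclusion in group A.  The probe-level
medians make the score robust to individual misbehaving probes, and taking
the difference of the two medians cancels any overall expression change of
the host gene.  The same formula serves every event geometry: for intron
retention the intron probes play the "inclusion" role and the spliced
junction probe the "skip" role; alternative 5'/3' events map through their
include/skip probe sets unchanged.

Significance is attached by exhaustive balanced label permutation (see
``sepmap._permutation``): an event is *called* when |S| >= 0.3 and its
permutation q-value is exactly 0, i.e. no permuted score in the whole
dataset reached its threshold.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._permutation import balanced_assignments, qvalues_from_scores

logger = logging.getLogger(__name__)

__all__ = [
    "compute_sepscore",
    "sepscores",
    "permutation_qvalues",
    "call_events",
    "classify_event",
    "classify_events",
    "SEPSCORE_THRESHOLD",
    "BACKGROUND_Q",
    "INTENSITY_FLOOR",
]

#: Call threshold on |Sepscore| and the q bound defining background events.
SEPSCORE_THRESHOLD = 0.3
BACKGROUND_Q = 0.2
#: Linear-scale floor applied before taking logs, to avoid infinite ratios.
INTENSITY_FLOOR = 1.0

CLASS_LABELS = ("induced", "repressed", "background", "unclassified")


def _event_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Inclusion/skip probes of events that carry both roles.

    Events missing one of the two roles are dropped with a logged warning
    rather than raising.
    """
    sub = table[table["role"].isin(["inclusion", "skip"])]
    sub = sub[sub["event_id"].astype(str) != ""]
    roles_per_event = sub.groupby("event_id")["role"].nunique()
    incomplete = roles_per_event.index[roles_per_event < 2]
    if len(incomplete):
        logger.warning(
            "skipping %d event(s) lacking an inclusion or skip probe: %s",
            len(incomplete),
            ", ".join(map(str, incomplete[:5])) + ("..." if len(incomplete) > 5 else ""),
        )
        sub = sub[~sub["event_id"].isin(incomplete)]
    return sub


def _sepscores_for_assignment(
    lin: np.ndarray,
    col_index: dict[str, int],
    group_a: Sequence[str],
    group_b: Sequence[str],
    key: pd.DataFrame,
    floor: float,
) -> pd.Series:
    ia = [col_index[s] for s in group_a]
    ib = [col_index[s] for s in group_b]
    lin = np.maximum(lin, floor)
    ratio = np.log2(lin[:, ia].mean(axis=1)) - np.log2(lin[:, ib].mean(axis=1))
    med = (
        pd.DataFrame({"event_id": key["event_id"], "role": key["role"], "r": ratio})
        .groupby(["event_id", "role"], sort=True)["r"]
        .median()
        .unstack("role")
    )
    return med["inclusion"] - med["skip"]


def sepscores(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    floor: float = INTENSITY_FLOOR,
) -> pd.Series:
    """Sepscore of every event in the table (indexed by event_id)."""
    sub = _event_probes(table)
    lin = sub[list(group_a) + list(group_b)].to_numpy(dtype=float)
    col_index = {s: i for i, s in enumerate(list(group_a) + list(group_b))}
    return _sepscores_for_assignment(
        lin, col_index, list(group_a), list(group_b), sub, floor
    )


def compute_sepscore(
    table: pd.DataFrame,
    event_id: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    floor: float = INTENSITY_FLOOR,
) -> float:
    """Sepscore of one event; see the module docstring for the formula."""
    sub = table[table["event_id"] == event_id]
    if sub.empty:
        raise KeyError(f"unknown event {event_id!r}")
    s = sepscores(sub, group_a, group_b, floor=floor)
    if event_id not in s.index:
        raise ValueError(f"event {event_id!r} lacks an inclusion or skip probe")
    return float(s.loc[event_id])


def permutation_qvalues(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    floor: float = INTENSITY_FLOOR,
    n_perm: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sepscores with exhaustive-permutation q-values.

    Requires at least two samples per group.  At 3 vs 3 the 18 informative
    balanced relabelings are enumerated exhaustively, making the q-values
    deterministic; ``n_perm``/``rng`` only matter for group sizes where
    exhaustive enumeration is infeasible.

    Returns a DataFrame indexed by event_id with columns ``sepscore, q``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    sub = _event_probes(table)
    samples = list(group_a) + list(group_b)
    lin = sub[samples].to_numpy(dtype=float)
    col_index = {s: i for i, s in enumerate(samples)}

    obs = _sepscores_for_assignment(lin, col_index, group_a, group_b, sub, floor)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    assignments = balanced_assignments(group_a, group_b, n_perm=n_perm, rng=rng)
    perm_abs = np.empty((len(assignments), obs.size))
    for i, (pa, pb) in enumerate(assignments):
        perm_abs[i] = (
            _sepscores_for_assignment(lin, col_index, pa, pb, sub, floor)
            .reindex(obs.index)
            .abs()
            .to_numpy()
        )
    q = qvalues_from_scores(obs.abs().to_numpy(), perm_abs)
    return pd.DataFrame({"sepscore": obs, "q": q})


def call_events(
    calls: pd.DataFrame, min_sepscore: float = SEPSCORE_THRESHOLD
) -> pd.DataFrame:
    """Changed events: |Sepscore| >= threshold (boundary included) and q = 0."""
    mask = (calls["sepscore"].abs() >= min_sepscore) & (calls["q"] == 0)
    return calls[mask]


def classify_event(
    sepscore: float,
    q: float,
    min_sepscore: float = SEPSCORE_THRESHOLD,
    bg_q: float = BACKGROUND_Q,
) -> str:
    """Assign an event to the induced / repressed / background classes.

    induced:    S >= +threshold and q = 0 (more inclusion in group A)
    repressed:  S <= -threshold and q = 0 (more skipping in group A)
    background: |S| < threshold and q > bg_q (confidently unchanged)
    unclassified otherwise.
    """
    if q == 0:
        if sepscore >= min_sepscore:
            return "induced"
        if sepscore <= -min_sepscore:
            return "repressed"
    if abs(sepscore) < min_sepscore and q > bg_q:
        return "background"
    return "unclassified"


def classify_events(
    calls: pd.DataFrame,
    min_sepscore: float = SEPSCORE_THRESHOLD,
    bg_q: float = BACKGROUND_Q,
) -> pd.Series:
    """Vectorized ``classify_event`` over a calls table."""
    s = calls["sepscore"].to_numpy(dtype=float)
    q = calls["q"].to_numpy(dtype=float)
    out = np.full(s.size, "unclassified", dtype=object)
    out[(q == 0) & (s >= min_sepscore)] = "induced"
    out[(q == 0) & (s <= -min_sepscore)] = "repressed"
    out[(np.abs(s) < min_sepscore) & (q > bg_q) & (out == "unclassified")] = "background"
    return pd.Series(out, index=calls.index, name="class_label")
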