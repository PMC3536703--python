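"""Shared permutation machinery for Sepscore and SAM q-values.

Both the splicing and the expression arms attach a permutation false
discovery rate to an absolute score: group labels are reassigned in every
balanced way, the score is recomputed, and the FDR at threshold t is the
mean number of permuted scores exceeding t divided by the number of
observed scores exceeding t.

At n = 3 vs 3 there are C(6,3) = 20 balanced reassignments.  Two of them
-- the identity and the full group swap -- reproduce the observed
statistic (the swap only flips its sign), so they carry no information
about the null and are excluded; the remaining 18 are enumerated
exhaustively.  A reported q of exactly 0 therefore means that no permuted
score anywhere in the dataset reached the event's threshold.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["balanced_assignments", "qvalues_from_scores"]


def balanced_assignments(
    group_a: Sequence[str],
    group_b: Sequence[str],
    include_trivial: bool = False,
    max_exhaustive: int = 20000,
    n_perm: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Enumerate balanced relabelings of two sample groups.

    Each assignment keeps the group sizes fixed and reassigns which samples
    belong to "group A".  The identity assignment and (for equal group
    sizes) its mirror are dropped unless ``include_trivial`` is set.

    When the number of distinct assignments exceeds ``max_exhaustive`` a
    seeded random subset of ``n_perm`` assignments is drawn instead; if
    ``n_perm`` is smaller than the exhaustive count the exhaustive set is
    used anyway and a note is logged.
    """
    samples = list(group_a) + list(group_b)
    if len(set(samples)) != len(samples):
        raise ValueError("sample names shared between groups")
    k = len(group_a)
    a_set = frozenset(group_a)
    b_set = frozenset(group_b)

    from math import comb

    total = comb(len(samples), k)
    if total <= max_exhaustive:
        if n_perm is not None and n_perm < total:
            logger.info(
                "n_perm=%d below the %d distinct balanced assignments; "
                "using the exhaustive set",
                n_perm,
                total,
            )
        out = []
        for combo in combinations(samples, k):
            s = frozenset(combo)
            if not include_trivial and (s == a_set or s == b_set):
                continue
            rest = tuple(x for x in samples if x not in s)
            out.append((tuple(combo), rest))
        return out

    if n_perm is None:
        n_perm = 1000
    if rng is None:
        rng = np.random.default_rng()
    seen: set[frozenset] = set()
    out = []
    while len(out) < n_perm:
        perm = rng.permutation(samples)
        s = frozenset(perm[:k])
        if s in seen or (not include_trivial and (s == a_set or s == b_set)):
            continue
        seen.add(s)
        out.append((tuple(perm[:k]), tuple(perm[k:])))
    return out


def qvalues_from_scores(obs_abs: np.ndarray, perm_abs: np.ndarray) -> np.ndarray:
    """Permutation q-values from observed and permuted absolute scores.

    For each observation, with threshold t equal to its own score,

        FDR(t) = (mean over permutations of #{permuted score >= t})
                 / #{observed score >= t}

    clipped to [0, 1].  The q-value is the minimum FDR over all thresholds
    at or below the observation's score, which makes q monotone
    nonincreasing in the score by construction.

    Parameters
    ----------
    obs_abs:
        Observed absolute scores, shape (n,).
    perm_abs:
        Permuted absolute scores, shape (n_perm, n).
    """
    obs_abs = np.asarray(obs_abs, dtype=float)
    perm_abs = np.asarray(perm_abs, dtype=float)
    if perm_abs.ndim != 2:
        raise ValueError("perm_abs must be 2-D (n_perm, n)")
    n_perm = perm_abs.shape[0]
    if n_perm == 0:
        raise ValueError("at least one permutation required")

    all_perm = np.sort(perm_abs.ravel())
    obs_sorted = np.sort(obs_abs)

    order = np.argsort(-obs_abs, kind="stable")
    thresholds = obs_abs[order]

    n_perm_ge = all_perm.size - np.searchsorted(all_perm, thresholds, side="left")
    n_obs_ge = obs_abs.size - np.searchsorted(obs_sorted, thresholds, side="left")
    fdr = np.clip((n_perm_ge / n_perm) / n_obs_ge, 0.0, 1.0)

    # q_i = min FDR over thresholds <= |score_i| (suffix minimum in
    # descending-score order).
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
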