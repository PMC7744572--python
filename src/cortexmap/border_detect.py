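"""Sliding-window multivariate border detection along a profile sequence.

At each position of an ordered sequence of 10-component profile feature
vectors, the Mahalanobis distance D^2 between the mean feature vectors of
the b profiles to the left and the b profiles to the right (pooled
within-block covariance) measures how different the cytoarchitecture is on
the two sides.  Significance of a distance peak follows the two-sample
Hotelling T^2 statistic converted to an F distribution, Bonferroni-corrected
over positions (alpha = 0.05 by default).  A cortical border is confirmed
when the significant global maximum falls at (within +-1 of) the same
position for at least a required fraction of window sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DistanceFunction",
    "BorderResult",
    "sliding_distance",
    "find_borders",
    "border_agreement",
    "DEFAULT_WINDOW_SIZES",
]

# Window sizes bracket the canonical b = 19.  The lower end is held at 15:
# the Hotelling test's second degree of freedom is 2b - p - 1, and with the
# p = 10 profile features windows below ~15 are too underpowered after
# Bonferroni correction to contribute to border confirmation.
DEFAULT_WINDOW_SIZES = tuple(range(15, 25))


@dataclass
class DistanceFunction:
    """Per-position D^2 with significance flags for one window size."""

    positions: np.ndarray  # indices i with b profiles on each side
    d2: np.ndarray
    significant: np.ndarray  # bool, Bonferroni-corrected Hotelling test
    window: int
    alpha: float
    p_values: np.ndarray


@dataclass
class BorderResult:
    """Confirmed borders over a set of window sizes."""

    confirmed: list[int] = field(default_factory=list)  # profile indices
    confirmation_fraction: dict[int, float] = field(default_factory=dict)
    per_window_maxima: dict[int, tuple[int, bool]] = field(default_factory=dict)
    window_sizes: tuple[int, ...] = ()
    tie_broken: bool = False


def _block_stats(x: np.ndarray):
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc  # scatter (n-1 factor applied by caller)
    return mean, cov


def sliding_distance(
    features,
    b: int,
    alpha: float = 0.05,
    shrinkage: float = 0.0,
) -> DistanceFunction:
    """Mahalanobis D^2 between the b-blocks left/right of every position.

    ``features`` is a sequence of ProfileFeatureVector or a (N, p) array.
    ``shrinkage`` in [0, 1) blends the pooled covariance with a scaled
    identity (S <- (1-g) S + g tr(S)/p I) for short, near-singular
    sequences; off by default.
    """
    X = np.asarray(
        [f.as_array() if hasattr(f, "as_array") else np.asarray(f, float) for f in features]
    )
    n, p = X.shape
    if b < 2:
        raise ValueError("window size must be at least 2")
    if n < 2 * b:
        raise ValueError(f"sequence of length {n} too short for window {b}")
    positions = np.arange(b, n - b + 1)
    d2 = np.empty(positions.size)
    pvals = np.empty(positions.size)
    df2 = 2 * b - p - 1
    if df2 < 1:
        raise ValueError(
            f"window {b} too small for {p}-dimensional features "
            f"(needs 2b - p - 1 >= 1)"
        )
    for k, i in enumerate(positions):
        mL, sL = _block_stats(X[i - b : i])
        mR, sR = _block_stats(X[i : i + b])
        S = (sL + sR) / (2 * b - 2)
        if shrinkage > 0:
            S = (1 - shrinkage) * S + shrinkage * (np.trace(S) / p) * np.eye(p)
        diff = mL - mR
        try:
            sol = np.linalg.solve(S, diff)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular pooled covariance at position {i}; consider the "
                f"shrinkage option of sliding_distance"
            ) from exc
        d2[k] = float(diff @ sol)
        t2 = (b * b / (2.0 * b)) * d2[k]
        f_stat = t2 * df2 / (p * (2 * b - 2))
        pvals[k] = stats.f.sf(f_stat, p, df2)
    significant = pvals * positions.size < alpha  # Bonferroni over positions
    return DistanceFunction(
        positions=positions, d2=d2, significant=significant,
        window=b, alpha=alpha, p_values=pvals,
    )


def find_borders(
    features,
    window_sizes=DEFAULT_WINDOW_SIZES,
    confirm_fraction: float = 0.8,
    alpha: float = 0.05,
    shrinkage: float = 0.0,
    vote_tolerance: int = 2,
) -> BorderResult:
    """Confirm borders by agreement of significant global maxima.

    For every window size the significant global maximum of D^2 is located;
    a position is confirmed when at least ``confirm_fraction`` of window
    sizes place their significant maximum within ``vote_tolerance``
    positions of it.  Because consecutive window positions share 2b-2 of
    their 2b profiles, the argmax of D^2 carries an intrinsic jitter of a
    couple of positions even across a strong border, so the default
    tolerance is +-2.  Detection is iterated: each confirmed border masks
    +-max(window_sizes) positions and the search repeats on the remainder,
    so several well-separated borders can all be recovered.  Ties in a
    global maximum break toward the lower index (flagged on the result).
    """
    window_sizes = tuple(sorted(set(int(b) for b in window_sizes)))
    if not window_sizes:
        raise ValueError("empty window set")
    dfs = {b: sliding_distance(features, b, alpha=alpha, shrinkage=shrinkage)
           for b in window_sizes}

    result = BorderResult(window_sizes=window_sizes)
    for b, df in dfs.items():
        order = np.argsort(-df.d2, kind="stable")  # ties -> lower index first
        top = order[0]
        if np.sum(df.d2 == df.d2[top]) > 1:
            result.tie_broken = True
        result.per_window_maxima[b] = (int(df.positions[top]), bool(df.significant[top]))

    masked: set[int] = set()
    mask_radius = max(window_sizes)
    while True:
        votes: dict[int, bool] = {}
        for b, df in dfs.items():
            keep = np.array([p not in masked for p in df.positions])
            if not keep.any():
                continue
            d2m = np.where(keep, df.d2, -np.inf)
            top = int(np.argmax(d2m))
            votes[b] = (int(df.positions[top]), bool(df.significant[top]))
        if not votes:
            break
        sig_votes = sorted(pos for pos, sig in votes.values() if sig)
        if not sig_votes:
            break
        # candidate = any position in the span of the significant votes; the
        # best candidate is the one the most windows agree with, and the
        # confirmed position is the median of its supporting votes
        best_pos, best_support = None, -1
        for cand in range(sig_votes[0], sig_votes[-1] + 1):
            support = sum(1 for p in sig_votes if abs(p - cand) <= vote_tolerance)
            if support > best_support:
                best_pos, best_support = cand, support
        frac = best_support / len(window_sizes)
        if frac >= confirm_fraction:
            supporters = [p for p in sig_votes if abs(p - best_pos) <= vote_tolerance]
            pos = int(np.median(supporters))
            result.confirmed.append(pos)
            result.confirmation_fraction[pos] = frac
            masked.update(range(pos - mask_radius, pos + mask_radius + 1))
        else:
            break
    result.confirmed.sort()
    return result


def border_agreement(
    a_positions,
    b_positions,
    traverse_arclengths_um,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Greedy nearest matching of two border sets along the outer contour.

    Positions are traverse indices; ``traverse_arclengths_um`` maps a
    traverse index to its seed arc-length on the outer contour.  Returns
    (matches, unmatched_a, unmatched_b) where each match is
    (a_index, b_index, arc-length distance in um).
    """
    arc = np.asarray(traverse_arclengths_um, dtype=float)
    a_left = list(a_positions)
    b_left = list(b_positions)
    matches: list[tuple[int, int, float]] = []
    while a_left and b_left:
        pairs = [
            (abs(arc[ai] - arc[bi]), ai, bi) for ai in a_left for bi in b_left
        ]
        dist, ai, bi = min(pairs)
        matches.append((ai, bi, float(dist)))
        a_left.remove(ai)
        b_left.remove(bi)
    return matches, a_left, b_left
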