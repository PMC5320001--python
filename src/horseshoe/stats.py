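"""PERMANOVA and the collinearity impossibility bound.

PERMANOVA (permutational multivariate analysis of variance) partitions the
sum of squared inter-sample distances into between- and within-group
components (Anderson's formulation) and judges the pseudo-F ratio against
a null distribution obtained by permuting group labels.

The collinearity machinery encodes a geometric impossibility: points that
are pairwise separated by at least delta but confined to a ball of radius
r can number at most ``floor(2r/delta) + 1`` on any straight line.  Band
tables put many mutually separated samples inside the saturation ball of
radius sqrt(2/B), so their gradient cannot be a linear trajectory in
feature space — it must curve, and so must its low-dimensional shadow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .exceptions import IdentifierError

__all__ = ["PermanovaResult", "permanova", "max_collinear", "is_collinear"]

#: exhaustive permutation enumeration kicks in at or below this many relabelings
EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    permutations: int
    group_sizes: tuple
    seed: int | None
    method: str  # "monte-carlo" or "exhaustive"

    def __post_init__(self):
        if self.permutations > 0 and self.method == "monte-carlo":
            assert self.p_value >= 1.0 / (self.permutations + 1) - 1e-15


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return math.inf
    return (ss_between / df_between) / (ss_within / df_within)


def _n_distinct_relabelings(counts) -> float:
    n = sum(counts)
    out = math.factorial(n)
    for c in counts:
        out //= math.factorial(c)
    return out


def _multiset_permutations(codes: np.ndarray):
    """All distinct arrangements of the code multiset (lexicographic)."""
    pool = sorted(codes.tolist())
    n = len(pool)

    def rec(remaining, prefix):
        if not remaining:
            yield np.array(prefix, dtype=int)
            return
        seen = set()
        for i, v in enumerate(remaining):
            if v in seen:
                continue
            seen.add(v)
            yield from rec(remaining[:i] + remaining[i + 1 :], prefix + [v])

    yield from rec(pool, [])


def permanova(
    dm: DistanceMatrix,
    grouping,
    permutations: int = 9999,
    seed: int | None = 0,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping.

    ``grouping`` is either a mapping from sample id to label or a sequence
    of labels aligned with ``dm.ids``.  The p-value uses the +1/+1
    convention, ``p = (1 + #{F_perm >= F_obs}) / (1 + permutations)``;
    when the number of distinct relabelings is at most
    ``EXHAUSTIVE_LIMIT``, the null is enumerated exhaustively instead and
    ``p = #{F >= F_obs} / #relabelings`` (the observed labeling included).
    ``exhaustive`` forces (True) or forbids (False) enumeration; the
    default ``None`` auto-selects by the relabeling count.
    """
    ids = list(dm.ids)
    if hasattr(grouping, "get") or isinstance(grouping, dict):
        missing = [s for s in ids if s not in grouping]
        if missing:
            raise IdentifierError(f"samples without group labels: {missing}")
        labels = [grouping[s] for s in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise IdentifierError(
                f"{len(labels)} labels for {len(ids)} samples in the matrix"
            )
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    code_of = {lab: g for g, lab in enumerate(uniq)}
    codes = np.array([code_of[lab] for lab in labels])
    sizes = tuple(int((codes == g).sum()) for g in range(len(uniq)))
    if min(sizes) < 2:
        raise ValueError(f"every group needs >= 2 samples; sizes {sizes}")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq))

    n_relab = _n_distinct_relabelings(sizes)
    use_exhaustive = (
        exhaustive if exhaustive is not None else n_relab <= EXHAUSTIVE_LIMIT
    )
    if use_exhaustive and n_relab > 10 * EXHAUSTIVE_LIMIT:
        raise ValueError(f"{n_relab} relabelings is too many to enumerate")
    if use_exhaustive:
        hits = sum(
            1 for perm in _multiset_permutations(codes)
            if _pseudo_f(d2, perm, len(uniq)) >= f_obs - 1e-12
        )
        return PermanovaResult(
            f_obs, hits / n_relab, int(n_relab), sizes, seed, "exhaustive"
        )

    rng = np.random.default_rng(seed)
    hits = 0
    work = codes.copy()
    for _ in range(permutations):
        rng.shuffle(work)
        if _pseudo_f(d2, work, len(uniq)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PermanovaResult(f_obs, p, permutations, sizes, seed, "monte-carlo")


def max_collinear(min_separation: float, radius: float) -> int:
    """Maximum number of pairwise-separated points on a line inside a ball.

    A chord of a ball of radius r has length at most 2r; points pairwise at
    least ``min_separation`` apart along it are pinned to distinct
    positions at spacing >= min_separation, so at most ``floor(2r/delta) +
    1`` of them fit.  A band table with n_samples exceeding this bound
    therefore cannot have its samples on any straight line.
    """
    if min_separation <= 0 or radius <= 0:
        raise ValueError("min_separation and radius must be positive")
    return int(math.floor(2 * radius / min_separation)) + 1


def is_collinear(points, tolerance: float = 1e-9) -> bool:
    """True when the points lie on one line (second singular value test).

    The points are collinear iff the centered coordinate matrix has rank
    <= 1; numerically, iff its second singular value is at most
    ``tolerance`` times the first.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points as a 2-D array")
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    centered = pts - pts.mean(axis=0, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size < 2 or s[0] == 0:
        return True
    return bool(s[1] <= tolerance * s[0])
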