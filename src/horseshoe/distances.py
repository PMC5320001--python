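"""Beta-diversity distance metrics and saturation diagnostics.

Implements the four metrics compared throughout the package — Euclidean,
chi-squared (the distance induced by correspondence analysis), unweighted
UniFrac, and EMBAD (Earth Mover Band Aware Distance) — together with the
saturation-curve diagnostic and the closed-form band-ball radius.

*Saturation* is the property that a dissimilarity stops increasing once two
communities share no features: all sufficiently distant samples become
equidistant, which bends gradients into horseshoes under ordination.
Euclidean, chi-squared, and UniFrac distances all saturate.  EMBAD does
not: it measures the minimal probability mass that must flow between the
two samples' feature distributions along a gradient-informed feature
ordering (a 1-D Wasserstein-1 distance), so it keeps growing with gradient
separation even between feature-disjoint samples.

Distance matrices are returned as :class:`skbio.DistanceMatrix` (symmetric,
hollow, id-labeled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .exceptions import DegenerateSampleError, IdentifierError
from .tables import FeatureTable

__all__ = [
    "FeatureOrder",
    "euclidean_dm",
    "band_ball_radius",
    "chisq_dm",
    "unifrac_unweighted",
    "embad",
    "SaturationCurve",
    "saturation_curve",
]


@dataclass(frozen=True)
class FeatureOrder:
    """A permutation of a table's feature ids defining the EMBAD ground axis.

    Typically produced by sorting features on their mean niche estimate,
    encoding the prior knowledge about band-table ordering that EMBAD
    requires.  ``positions`` optionally assigns a real coordinate to each
    ordered feature (e.g. its niche optimum); by default features sit at
    unit-spaced ranks 1..D.
    """

    feature_ids: tuple
    ordering_gradient_name: str = "rank"
    positions: tuple | None = None

    def __post_init__(self):
        ids = tuple(str(f) for f in self.feature_ids)
        if len(set(ids)) != len(ids):
            raise IdentifierError("feature order contains duplicate ids")
        object.__setattr__(self, "feature_ids", ids)
        if self.positions is not None:
            pos = tuple(float(p) for p in self.positions)
            if len(pos) != len(ids):
                raise ValueError("positions must match feature_ids in length")
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError("positions must be nondecreasing along the order")
            object.__setattr__(self, "positions", pos)

    def validate_against(self, table: FeatureTable) -> None:
        if set(self.feature_ids) != set(table.feature_ids) or len(
            self.feature_ids
        ) != len(table.feature_ids):
            missing = set(table.feature_ids) - set(self.feature_ids)
            extra = set(self.feature_ids) - set(table.feature_ids)
            raise IdentifierError(
                f"feature order does not cover the table exactly "
                f"(missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]})"
            )


def _dm(condensed: np.ndarray, sample_ids) -> DistanceMatrix:
    square = squareform(condensed, checks=False)
    # guard tiny negative rounding before skbio validation
    np.fill_diagonal(square, 0.0)
    return DistanceMatrix(np.maximum(square, 0.0), list(sample_ids))


def euclidean_dm(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Euclidean distance between sample columns."""
    return _dm(pdist(table.values.T, metric="euclidean"), table.sample_ids)


def band_ball_radius(band_size: int) -> float:
    """Euclidean distance between any two non-overlapping band-table samples.

    With cell value 1/B, two disjoint bands differ in 2B cells by 1/B each:
    ``sqrt(2B / B^2) = sqrt(2/B)``.  Every saturated (band-disjoint) sample
    lies on a sphere of this radius around the reference sample — the
    geometric reason saturated samples are all equidistant.
    """
    if band_size < 1:
        raise ValueError(f"band size must be >= 1, got {band_size}")
    return math.sqrt(2.0 / band_size)


def chisq_dm(table: FeatureTable) -> DistanceMatrix:
    """Chi-squared distance between samples (the metric CA embeds).

    With P the table normalized to grand total 1, sample masses r_i and
    feature masses c_k, ``d(i,j)^2 = sum_k (P_ki/r_i - P_kj/r_j)^2 / c_k``.
    All-zero feature rows are dropped (c_k = 0 is undefined); the distance
    is invariant to each sample's sequencing depth.
    """
    total = table.values.sum()
    if total <= 0:
        raise DegenerateSampleError("table has zero grand total")
    colsums = table.values.sum(axis=0)
    zero_cols = np.nonzero(colsums == 0)[0]
    if zero_cols.size:
        bad = [table.sample_ids[j] for j in zero_cols]
        raise DegenerateSampleError(f"all-zero sample(s): {bad}")
    P = table.values / total
    r = P.sum(axis=0)  # sample masses
    c = P.sum(axis=1)  # feature masses
    keep = c > 0
    profiles = (P[keep] / r) / np.sqrt(c[keep, None])  # rows scaled for chi-sq geometry
    return _dm(pdist(profiles.T, metric="euclidean"), table.sample_ids)


def _branch_presence(table: FeatureTable, tree: TreeNode):
    """Edge lengths and per-sample presence for every branch of the tree."""
    presence = table.values > 0
    row_of = {fid: k for k, fid in enumerate(table.feature_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = [
        fid
        for fid in table.feature_ids
        if presence[row_of[fid]].any() and fid not in tip_names
    ]
    if missing:
        raise IdentifierError(f"feature ids absent from the tree: {missing}")
    n = table.n_samples
    lengths, pres_rows = [], []
    node_pres: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            k = row_of.get(node.name)
            v = presence[k].copy() if k is not None else np.zeros(n, dtype=bool)
        else:
            v = np.zeros(n, dtype=bool)
            for child in node.children:
                v |= node_pres[id(child)]
        node_pres[id(node)] = v
        length = node.length or 0.0
        if length > 0:
            lengths.append(length)
            pres_rows.append(v)
    if not lengths:
        return np.zeros(0), np.zeros((0, n), dtype=bool)
    return np.asarray(lengths, dtype=float), np.asarray(pres_rows)


def unifrac_unweighted(table: FeatureTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted (presence/absence) UniFrac distance between samples.

    A branch is *present* in a sample if any tip below it has nonzero
    abundance there.  ``d(i,j)`` is the branch length present in exactly one
    of the two samples divided by the branch length present in at least
    one; it is bounded in [0, 1] and reaches 1 only for phylogenetically
    disjoint communities.  The root's stem branch (if it has length) counts
    only when present in at least one of the pair, like any other branch.
    """
    lengths, pres = _branch_presence(table, tree)
    A = pres.astype(float)
    W = A * lengths[:, None]
    shared = W.T @ A  # sum of lengths present in both i and j
    totals = W.sum(axis=0)
    union = totals[:, None] + totals[None, :] - shared
    unique = union - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, unique / union, 0.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(np.clip(d, 0.0, 1.0), list(table.sample_ids))


def embad(
    table: FeatureTable,
    order: FeatureOrder,
    use_positions: bool = False,
) -> DistanceMatrix:
    """Earth Mover Band Aware Distance between proportion samples.

    Features are laid out on a line in the order given (unit spacing by
    rank, or at ``order.positions`` when ``use_positions`` is set); each
    sample is a unit of probability mass distributed over that line, and
    ``d(i,j)`` is the minimal total mass-times-distance flow turning sample
    i's distribution into sample j's.  In one dimension this is the L1
    distance between cumulative distributions::

        d(i, j) = sum_k |C_ik - C_jk| * spacing_k

    which never saturates: on a band table it equals exactly ``|i - j|``.

    The table must already hold proportions (call
    :func:`horseshoe.tables.to_proportions` first); this keeps the
    probability-mass interpretation explicit.
    """
    sums = table.values.sum(axis=0)
    if table.n_features and np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(
            "embad requires sample columns that sum to 1; "
            "call to_proportions(table) first"
        )
    order.validate_against(table)
    ridx = [table.feature_ids.index(f) for f in order.feature_ids]
    cum = np.cumsum(table.values[ridx], axis=0)
    if use_positions:
        if order.positions is None:
            raise ValueError("use_positions=True requires order.positions")
        spacing = np.diff(np.asarray(order.positions))
    else:
        spacing = np.ones(table.n_features - 1)
    # the last cumulative row is identically 1 and carries no spacing
    if table.n_features > 1 and table.n_samples > 1:
        condensed = pdist(cum[:-1].T, metric="cityblock", w=spacing)
    else:
        condensed = np.zeros(table.n_samples * (table.n_samples - 1) // 2)
    return _dm(condensed, table.sample_ids)


@dataclass(frozen=True)
class SaturationCurve:
    """Distance from a reference sample to all samples, in gradient order."""

    sample_ids: tuple
    ranks: np.ndarray
    distances: np.ndarray
    plateau_rank: int
    epsilon: float

    def as_pairs(self):
        return list(zip(self.ranks.tolist(), self.distances.tolist()))


def saturation_curve(
    dm: DistanceMatrix,
    reference: str,
    order,
    epsilon: float = 0.01,
) -> SaturationCurve:
    """Distance-versus-gradient-rank curve from one reference sample.

    ``order`` is the full list of sample ids sorted by the gradient.  The
    plateau estimate is the smallest rank r such that every distance at
    rank >= r is at least ``(1 - epsilon) * max``; a strictly growing
    (nonsaturating) curve yields a plateau at the last rank, while a
    saturating metric plateaus at the band size.
    """
    order = [str(s) for s in order]
    ids = set(dm.ids)
    if reference not in ids:
        raise IdentifierError(f"unknown reference sample {reference!r}")
    if sorted(order) != sorted(dm.ids):
        raise IdentifierError("order must be a permutation of the matrix's sample ids")
    others = [s for s in order if s != reference]
    distances = np.array([dm[reference, s] for s in others])
    ranks = np.arange(1, len(others) + 1)
    dmax = distances.max() if distances.size else 0.0
    threshold = (1.0 - epsilon) * dmax
    plateau = len(others)
    for r in range(len(others), 0, -1):
        if distances[r - 1 :].min() >= threshold:
            plateau = r
        else:
            break
    if distances.size == 0 or dmax == 0.0:
        plateau = 1 if distances.size else 0
    return SaturationCurve(tuple(others), ranks, distances, plateau, epsilon)
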