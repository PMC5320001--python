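"""Synthetic generators: band tables, Gaussian-niche gradient tables, and a
molecular-evolution saturation demo.

A *band table* is the idealized picture of niche differentiation along a
gradient: features (OTUs) ordered by niche optimum, samples ordered by
gradient position, and each sample occupied by a contiguous block of B
features shifted one (or more) rows per sample.  Its geometry drives the
horseshoe effect: once two samples' bands stop overlapping, most community
dissimilarities stop growing.

:func:`niche_table` relaxes the hard band into Gaussian niche response
curves with Poisson count noise, emulating the structure of real gradient
studies (soil pH, decomposition time) while keeping the true niche optima
available for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tables import FeatureTable, GradientMetadata

__all__ = [
    "BandSpec",
    "NicheSpec",
    "band_table",
    "niche_table",
    "substitution_saturation",
    "simulate_site_divergence",
]


@dataclass(frozen=True)
class BandSpec:
    """Parameters of the idealized band table.

    ``n_samples`` columns; each column has exactly ``band_size`` nonzero
    cells of value ``value`` (default ``1/band_size`` so columns are
    proportions), starting ``shift`` rows below the previous column's band.
    The table therefore has ``(n_samples - 1) * shift + band_size`` rows.
    """

    n_samples: int = 30
    band_size: int = 10
    shift: int = 1
    value: float | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.band_size < 1:
            raise ValueError("band_size must be >= 1")
        if self.shift < 1:
            raise ValueError("shift must be >= 1")
        if self.value is not None and self.value <= 0:
            raise ValueError("value must be positive")

    @property
    def cell_value(self) -> float:
        return 1.0 / self.band_size if self.value is None else self.value

    @property
    def n_features(self) -> int:
        return (self.n_samples - 1) * self.shift + self.band_size


@dataclass(frozen=True)
class NicheSpec:
    """Parameters of the Gaussian-niche synthetic community generator.

    Each feature f gets a niche optimum mu_f drawn uniformly inside
    ``gradient_range``; the expected count of f in sample i with gradient
    g_i is proportional to ``exp(-(g_i - mu_f)^2 / (2 sigma^2))``, scaled so
    each sample's expected total is ``depth``, then Poisson-sampled.
    """

    n_samples: int = 50
    n_features: int = 100
    gradient_range: tuple[float, float] = (0.0, 10.0)
    sigma: float = 1.0
    depth: float = 10_000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be >= 1")
        lo, hi = self.gradient_range
        if not (hi > lo):
            raise ValueError("gradient_range must be a nonempty interval")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def band_table(spec: BandSpec) -> tuple[FeatureTable, GradientMetadata]:
    """Build the idealized band table and its index gradient.

    Column j holds ``spec.cell_value`` at rows ``j*shift .. j*shift +
    band_size - 1`` and zero elsewhere.  The gradient is simply the sample
    index 0, 1, 2, ... — sample order *is* the gradient here.
    """
    n, b, s = spec.n_samples, spec.band_size, spec.shift
    values = np.zeros((spec.n_features, n))
    for j in range(n):
        values[j * s : j * s + b, j] = spec.cell_value
    feature_ids = [f"F{i:04d}" for i in range(spec.n_features)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    colsum = b * spec.cell_value
    table = FeatureTable(
        values, feature_ids, sample_ids, proportions=abs(colsum - 1.0) < 1e-12
    )
    meta = GradientMetadata(sample_ids, np.arange(n, dtype=float), "sample_index")
    return table, meta


def niche_table(spec: NicheSpec) -> tuple[FeatureTable, GradientMetadata, np.ndarray]:
    """Simulate a count table from Gaussian niche responses along a gradient.

    Returns the count table, the sample gradient metadata (samples evenly
    spaced over ``gradient_range``), and the true niche optima ``mu_f`` per
    feature for parameter-recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gradient_range
    gradients = np.linspace(lo, hi, spec.n_samples)
    optima = rng.uniform(lo, hi, size=spec.n_features)
    # intensity[f, i] = Gaussian niche response of feature f at sample i
    z = (gradients[None, :] - optima[:, None]) / spec.sigma
    intensity = np.exp(-0.5 * z**2)
    colsum = intensity.sum(axis=0)
    colsum[colsum == 0] = 1.0  # unreachable for sigma > 0, guards underflow
    intensity = intensity * (spec.depth / colsum)
    counts = rng.poisson(intensity).astype(float)
    feature_ids = [f"F{i:04d}" for i in range(spec.n_features)]
    sample_ids = [f"S{j:04d}" for j in range(spec.n_samples)]
    table = FeatureTable(counts, feature_ids, sample_ids)
    meta = GradientMetadata(sample_ids, gradients, "gradient")
    return table, meta, optima


def substitution_saturation(t: float | None = None, rate: float = 1.0) -> float:
    """Expected fraction of mismatching sites between two diverging sequences.

    Under an equal-base-frequency (Jukes–Cantor) substitution model, two
    lineages separated for time ``t`` at per-site rate ``rate`` disagree at
    an expected fraction ``0.75 * (1 - exp(-8*rate*t/3))`` of sites.  With
    ``t=None`` (infinite time) the divergence plateaus at exactly 0.75 —
    random sequences still agree at a quarter of sites by chance, the
    sequence-level analogue of a saturating community distance.
    """
    if t is None:
        return 0.75
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    return 0.75 * (1.0 - math.exp(-8.0 * rate * t / 3.0))


def simulate_site_divergence(
    t: float, n_sites: int, rate: float = 1.0, seed: int = 0
) -> float:
    """Monte-Carlo estimate of pairwise site divergence for two lineages.

    Simulates Jukes–Cantor substitution independently along two branches of
    length ``t`` and returns the observed mismatch fraction; serves as the
    stochastic counterpart of :func:`substitution_saturation`.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    rng = np.random.default_rng(seed)
    # P(site differs from ancestor) after time t on one branch:
    p_change = 0.75 * (1.0 - math.exp(-4.0 * rate * t / 3.0))
    ancestor = rng.integers(0, 4, size=n_sites)

    def evolve(anc):
        changed = rng.random(n_sites) < p_change
        # a changed site lands uniformly on one of the three other bases
        offset = rng.integers(1, 4, size=n_sites)
        return np.where(changed, (anc + offset) % 4, anc)

    a, b = evolve(ancestor), evolve(ancestor)
    return float(np.mean(a != b))
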