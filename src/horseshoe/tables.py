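"""Feature tables, gradient metadata, file I/O, and compositional transforms.

The central container is :class:`FeatureTable`, a validated nonnegative
feature-by-sample matrix (OTU/species counts or proportions).  Sample-level
gradient values (pH, days of decomposition, ...) live in
:class:`GradientMetadata`.  Rooted phylogenies are represented with
:class:`skbio.TreeNode` and loaded through :func:`read_tree_newick`.

The centered log-ratio transform follows the compositional-data convention:
a pseudocount is added to the *raw counts* (never to proportions), each
count is logged, and the per-sample mean log count is subtracted, so every
transformed sample sums to zero.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .exceptions import DegenerateSampleError, IdentifierError

__all__ = [
    "FeatureTable",
    "GradientMetadata",
    "read_feature_table",
    "write_feature_table",
    "read_gradient_metadata",
    "write_gradient_metadata",
    "read_tree_newick",
    "to_proportions",
    "clr_transform",
]

#: columns of a proportion table must sum to 1 within this tolerance
PROPORTION_TOL = 1e-9
#: sums off by no more than this are silently renormalized at construction
PROPORTION_RENORM_TOL = 1e-6


def _check_ids(ids, kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise IdentifierError(f"duplicate {kind} identifiers: {sorted(set(dups))}")
    for i in ids:
        if i == "" or "\t" in i or "\n" in i:
            raise IdentifierError(
                f"{kind} identifier {i!r} is empty or contains a tab/newline"
            )
    return ids


@dataclass(frozen=True)
class FeatureTable:
    """Nonnegative feature-by-sample abundance matrix.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
        Counts or proportions; nonnegative and finite.
    feature_ids, sample_ids : sequence of str
        Unique identifiers for the rows and columns.
    proportions : bool
        When True every sample column must sum to 1 (within ``1e-9``;
        deviations up to ``1e-6`` are renormalized, larger ones rejected).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    proportions: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        if not np.all(np.isfinite(values)):
            raise ValueError("table contains non-finite entries")
        if np.any(values < 0):
            raise ValueError("table contains negative entries")
        feature_ids = _check_ids(self.feature_ids, "feature")
        sample_ids = _check_ids(self.sample_ids, "sample")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if self.proportions and values.shape[1]:
            sums = values.sum(axis=0)
            zero = sums == 0
            if np.any(zero):
                bad = [sample_ids[j] for j in np.nonzero(zero)[0]]
                raise DegenerateSampleError(
                    f"all-zero sample(s) in a proportion table: {bad}"
                )
            off = np.abs(sums - 1.0)
            if np.any(off > PROPORTION_RENORM_TOL):
                bad = [sample_ids[j] for j in np.nonzero(off > PROPORTION_RENORM_TOL)[0]]
                raise ValueError(
                    f"columns of a proportion table must sum to 1; offenders: {bad}"
                )
            if np.any(off > PROPORTION_TOL):
                values = values / sums
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self):  # frozen dataclass; identity hash is enough
        return id(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def sample_column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise IdentifierError(f"unknown sample id {sample_id!r}") from None
        return self.values[:, j]

    def reorder(self, feature_ids=None, sample_ids=None) -> "FeatureTable":
        """Return a new table with rows/columns permuted to the given orders."""
        fids = list(feature_ids) if feature_ids is not None else self.feature_ids
        sids = list(sample_ids) if sample_ids is not None else self.sample_ids
        if sorted(fids) != sorted(self.feature_ids):
            raise IdentifierError("feature_ids is not a permutation of the table's features")
        if sorted(sids) != sorted(self.sample_ids):
            raise IdentifierError("sample_ids is not a permutation of the table's samples")
        ridx = [self.feature_ids.index(f) for f in fids]
        cidx = [self.sample_ids.index(s) for s in sids]
        return FeatureTable(
            self.values[np.ix_(ridx, cidx)], fids, sids, proportions=self.proportions
        )


@dataclass(frozen=True)
class GradientMetadata:
    """One finite numeric gradient value per sample (pH, days, ...)."""

    sample_ids: list[str]
    gradient: np.ndarray
    gradient_name: str = "gradient"

    def __post_init__(self):
        sample_ids = _check_ids(self.sample_ids, "sample")
        gradient = np.asarray(self.gradient, dtype=float)
        if gradient.ndim != 1 or gradient.shape[0] != len(sample_ids):
            raise ValueError("need exactly one gradient value per sample id")
        if not np.all(np.isfinite(gradient)):
            raise ValueError("gradient values must be finite")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "gradient", gradient)

    def aligned_to(self, sample_ids) -> np.ndarray:
        """Gradient values in the order of ``sample_ids``."""
        lookup = dict(zip(self.sample_ids, self.gradient))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise IdentifierError(f"samples missing from metadata: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=float)

    def to_series(self) -> pd.Series:
        return pd.Series(self.gradient, index=self.sample_ids, name=self.gradient_name)


# ---------------------------------------------------------------------------
# file I/O — plain TSV; leading '#' lines are provenance comments
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data lines")
    header = lines[0].rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise IdentifierError(f"{path}: duplicate column identifiers: {dups}")
    df = pd.read_csv(
        io.StringIO("".join(lines)), sep="\t", dtype=str, keep_default_na=False,
    )
    df = df.set_index(df.columns[0])  # id column stays verbatim strings
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_feature_table(path, orientation: str = "features_as_rows") -> FeatureTable:
    """Read a delimiter-separated feature table.

    The file is tab-separated with the first column holding feature ids and
    the header row holding sample ids (or the transpose when ``orientation``
    is ``"samples_as_rows"``).  Lines starting with ``#`` are ignored.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "samples_as_rows":
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in table ({exc})") from None
    if values.size and np.any(values < 0):
        raise ValueError(f"{path}: table contains negative entries")
    return FeatureTable(values, list(df.index), list(df.columns))


def write_feature_table(table: FeatureTable, path, header_comment: str | None = None) -> None:
    """Write a table as TSV, re-readable by :func:`read_feature_table`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_dataframe().to_csv(fh, sep="\t", index_label="feature_id")


def read_gradient_metadata(path, gradient_column: str | None = None) -> GradientMetadata:
    """Read sample metadata TSV (first column = sample id) and pick one numeric column."""
    df = _read_tsv(path)
    if gradient_column is None:
        if df.shape[1] != 1:
            raise ValueError(
                f"{path}: metadata has {df.shape[1]} columns; specify gradient_column"
            )
        gradient_column = df.columns[0]
    if gradient_column not in df.columns:
        raise ValueError(f"{path}: no column named {gradient_column!r}")
    values = df[gradient_column].to_numpy(dtype=float)
    return GradientMetadata(list(df.index), values, gradient_column)


def write_gradient_metadata(meta: GradientMetadata, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        meta.to_series().to_frame().to_csv(fh, sep="\t", index_label="sample_id")


def read_tree_newick(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths default to 0.

    Raises
    ------
    IdentifierError
        If tip labels are duplicated.
    ValueError
        If branch lengths are negative or non-finite.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific parse errors
        raise ValueError(f"{path}: could not parse Newick tree ({exc})") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise IdentifierError(f"duplicate tip labels in tree: {dups}")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if not math.isfinite(node.length) or node.length < 0:
            raise ValueError(f"negative or non-finite branch length at {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_proportions(table: FeatureTable) -> FeatureTable:
    """Normalize each sample column to sum to 1 (relative abundances)."""
    sums = table.values.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        bad = [table.sample_ids[j] for j in zero]
        raise DegenerateSampleError(f"cannot normalize all-zero sample(s): {bad}")
    return FeatureTable(
        table.values / sums, table.feature_ids, table.sample_ids, proportions=True
    )


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of a count table.

    Each sample column x is mapped to ``ln(x + pseudocount) - mean(ln(x +
    pseudocount))``, i.e. the log abundances centered by the sample's
    geometric mean; every output column sums to zero.  The pseudocount is
    added to the raw counts before anything else, so zeros stay finite.
    ``pseudocount=0`` is permitted only for strictly positive tables, where
    the transform becomes scale-invariant per sample.

    Returns a features-by-samples real matrix (not a FeatureTable: CLR
    values are signed).
    """
    if pseudocount < 0 or (pseudocount == 0 and np.any(table.values <= 0)):
        raise ValueError(
            "pseudocount must be positive (0 allowed only for strictly "
            f"positive tables); got {pseudocount}"
        )
    logged = np.log(table.values + pseudocount)
    return logged - logged.mean(axis=0, keepdims=True)
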