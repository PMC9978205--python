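"""aCSM-ALL cutoff-scanning structural signatures.

The signature of a peptide is built in two steps: (1) the Euclidean
distance matrix over its typed heavy atoms, and (2) for every unordered
pair of the eight pharmacophore categories and every distance cutoff
``k * cutoff_step`` up to ``cutoff_limit``, the number of unordered atom
pairs within that cutoff in which one atom carries the first category
and the other carries the second.  With the default parameters
(step 0.2 Å, limit 20 Å) this yields 36 category pairs x 100 cutoffs =
3,600 integer features per peptide.

Counting conventions (all configurable only by editing this module —
they define the feature semantics):

* unordered atom pairs ``i < j``; self-pairs excluded;
* closed right bin edge: distance ``d`` is inside cutoff ``k*step``
  when ``d <= k*step``;
* a multi-labelled atom pair contributes to each matching category pair
  at most once, so every feature is bounded by ``n*(n-1)/2``;
* ``cumulative`` mode (default) counts all pairs with ``d <= cutoff``;
  ``interval`` mode counts pairs in ``((k-1)*step, k*step]``.  The two
  are linearly inter-convertible (cumulative = running sum of interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .atom_typing import CATEGORIES, TypedAtomSet

__all__ = [
    "SignatureParams",
    "SignatureVector",
    "CATEGORY_PAIRS",
    "feature_schema",
    "distance_matrix",
    "compute_signature",
    "write_signature_csv",
    "read_signature_csv",
]

#: The 36 unordered category pairs (with repetition), alphabetical outer order.
CATEGORY_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(sorted(CATEGORIES), 2)
)


@dataclass(frozen=True)
class SignatureParams:
    """Parameters of the cutoff scan.

    ``cutoff_limit / cutoff_step`` must be a whole number of bins.
    """

    cutoff_step: float = 0.2
    cutoff_limit: float = 20.0
    mode: Literal["cumulative", "interval"] = "cumulative"
    algorithm: str = "acsm_all"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_step <= self.cutoff_limit:
            raise ValueError("need 0 < cutoff_step <= cutoff_limit")
        if self.mode not in ("cumulative", "interval"):
            raise ValueError(f"unknown mode {self.mode!r}")
        ratio = self.cutoff_limit / self.cutoff_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"cutoff_limit/cutoff_step = {ratio} is not a whole number of bins"
            )

    @property
    def n_bins(self) -> int:
        return int(round(self.cutoff_limit / self.cutoff_step))

    @property
    def cutoffs(self) -> np.ndarray:
        """The scanned cutoffs: step, 2*step, ..., limit."""
        return np.round(self.cutoff_step * np.arange(1, self.n_bins + 1), 9)


@dataclass
class SignatureVector:
    """One peptide's signature: ``peptide_id`` is ``PDBID_CHAIN``."""

    peptide_id: str
    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.schema),):
            raise ValueError("values and schema lengths differ")
        if (self.values < 0).any():
            raise ValueError("signature counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def series(self, cat1: str, cat2: str) -> np.ndarray:
        """The per-cutoff count series of one category pair."""
        pair = tuple(sorted((cat1, cat2)))
        idx = CATEGORY_PAIRS.index(pair)  # raises ValueError if unknown
        n_bins = len(self.values) // len(CATEGORY_PAIRS)
        return self.values[idx * n_bins : (idx + 1) * n_bins]


def feature_schema(params: SignatureParams) -> tuple[str, ...]:
    """Ordered feature names ``CAT1:CAT2@cutoff``.

    Category pair varies in the outer loop (36 unordered pairs over the
    alphabetical category order), cutoff in the inner loop; with default
    parameters the schema has 3,600 names.
    """
    cutoffs = params.cutoffs
    return tuple(
        f"{c1}:{c2}@{cutoff:g}"
        for c1, c2 in CATEGORY_PAIRS
        for cutoff in cutoffs
    )


def distance_matrix(atoms: TypedAtomSet | np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal Euclidean distance matrix in Å."""
    coords = atoms.coords if isinstance(atoms, TypedAtomSet) else np.asarray(atoms)
    if coords.shape[0] == 0:
        raise ValueError("need at least one atom")
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


def compute_signature(
    atoms: TypedAtomSet,
    params: SignatureParams | None = None,
    peptide_id: str = "",
) -> SignatureVector:
    """Compute the aCSM-ALL signature of a typed atom set.

    An empty atom set yields an all-zero vector with a warning (a
    peptide with no typed heavy atoms carries no pair information but is
    still a valid row of a signature dataset).
    """
    if params is None:
        params = SignatureParams()
    schema = feature_schema(params)
    n = len(atoms)
    if n == 0:
        warnings.warn(f"empty atom set for {peptide_id!r}: zero signature")
        return SignatureVector(peptide_id, np.zeros(len(schema), dtype=np.int64), schema)

    n_bins = params.n_bins
    values = np.zeros((len(CATEGORY_PAIRS), n_bins), dtype=np.int64)
    if n >= 2:
        d = pdist(atoms.coords)
        # bin index of each pair: smallest k with d <= k*step (0-based);
        # pairs beyond the limit fall out of range and are dropped
        bin_idx = np.searchsorted(params.cutoffs, d, side="left")
        in_range = bin_idx < n_bins
        masks = atoms.category_masks()
        iu, ju = np.triu_indices(n, k=1)
        for p, (c1, c2) in enumerate(CATEGORY_PAIRS):
            m1, m2 = masks[c1], masks[c2]
            if c1 == c2:
                pair_mask = m1[iu] & m1[ju]
            else:
                pair_mask = (m1[iu] & m2[ju]) | (m2[iu] & m1[ju])
            sel = pair_mask & in_range
            if sel.any():
                values[p] = np.bincount(bin_idx[sel], minlength=n_bins)
        if params.mode == "cumulative":
            values = np.cumsum(values, axis=1)
    return SignatureVector(peptide_id, values.ravel(), schema)


# ---------------------------------------------------------------------------
# dataset serialization — CSV rows of "id, f1, ..., fN"


def write_signature_csv(
    rows: Iterable[SignatureVector], destination: str | Path
) -> None:
    """Write a signature dataset: header ``id`` + feature names, one row
    per peptide, integer cells.  All rows must share one schema."""
    rows = list(rows)
    schema: tuple[str, ...] | None = None
    for r in rows:
        if schema is None:
            schema = r.schema
        elif r.schema != schema:
            raise ValueError("mixed signature schemas cannot share one CSV")
    if schema is None:
        schema = feature_schema(SignatureParams())
    frame = pd.DataFrame(
        [r.values for r in rows],
        index=pd.Index([r.peptide_id for r in rows], name="id"),
        columns=list(schema),
        dtype=np.int64,
    )
    frame.to_csv(destination)


def read_signature_csv(source: str | Path) -> list[SignatureVector]:
    """Read back a dataset written by :func:`write_signature_csv`."""
    frame = pd.read_csv(source, index_col="id")
    schema = tuple(frame.columns)
    return [
        SignatureVector(str(pid), row.to_numpy(dtype=np.int64), schema)
        for pid, row in frame.iterrows()
    ]
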