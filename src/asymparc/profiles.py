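"""Connectivity-profile post-processing.

A *connectivity profile* is the non-negative matrix of connection strengths
from every seed vertex of a region of interest to a set of whole-brain
targets — one matrix per subject and hemisphere.  Raw tractography-derived
values span orders of magnitude, so profiles are log-transformed and
max-normalized before any comparison; group ("population") maps are
across-subject means thresholded to a support, and the union of the left
and mirrored-right supports defines the vertex set on which asymmetry is
tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConnectivityProfile",
    "PopulationMap",
    "normalize_profile",
    "smooth_profile",
    "population_map",
    "group_mask",
]


@dataclass(frozen=True)
class ConnectivityProfile:
    """One subject-hemisphere seed-vertex × target connectivity matrix.

    Parameters
    ----------
    matrix
        Non-negative array of shape ``(n_seeds, n_targets)``; row *i* is the
        connectivity fingerprint of seed vertex *i*.
    subject_id
        Subject identifier.
    hemisphere
        ``"L"`` or ``"R"``.  Left and right profiles of the same subject
        share seed indexing (index *i* on the left corresponds to the
        mirrored index *i* on the right).
    normalized
        Whether :func:`normalize_profile` has been applied; normalized
        entries lie in ``[0, 1]``.
    """

    matrix: np.ndarray
    subject_id: str = ""
    hemisphere: str = "L"
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError(f"profile matrix must be 2-D, got shape {m.shape}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        _check_nonnegative(m)
        object.__setattr__(self, "matrix", m)

    @property
    def n_seeds(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_targets(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PopulationMap:
    """Across-subject mean connectivity map with a thresholded support.

    ``support`` holds exactly the indices whose mean value exceeded the
    threshold (strict ``>``); all other entries of ``values`` are zero.
    ``retained_fraction`` is the fraction of *non-zero* mean entries that
    survived thresholding.
    """

    values: np.ndarray
    threshold: float
    support: np.ndarray = field(default=None)  # type: ignore[assignment]
    retained_fraction: float = float("nan")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.support is None:
            object.__setattr__(self, "support", np.flatnonzero(v > self.threshold))


def _check_nonnegative(matrix: np.ndarray) -> None:
    if np.any(matrix < 0) or not np.all(np.isfinite(matrix)):
        bad = np.argwhere(~(np.isfinite(matrix) & (matrix >= 0)))[0]
        raise ValueError(
            f"connectivity values must be finite and non-negative; "
            f"offending cell (seed={bad[0]}, target={bad[1]}) = "
            f"{matrix[tuple(bad)]!r}"
        )


def normalize_profile(raw: ConnectivityProfile) -> ConnectivityProfile:
    """Log-transform and max-normalize a raw connectivity profile.

    Each entry ``x`` is mapped to ``log(1 + x)`` (so zeros stay zero and
    sparsity is preserved) and the whole matrix is then divided by its
    maximum, yielding values in ``[0, 1]`` with maximum exactly 1.  An
    all-zero matrix is returned unchanged (flagged normalized) with a
    warning.  Idempotent on its own output up to the second max-division,
    which is a no-op once the maximum is small; the ``normalized`` flag
    short-circuits re-application.
    """
    if raw.normalized:
        return raw
    _check_nonnegative(raw.matrix)
    logged = np.log1p(raw.matrix)
    peak = logged.max() if logged.size else 0.0
    if peak == 0.0:
        warnings.warn(
            f"profile {raw.subject_id}/{raw.hemisphere} is all-zero; "
            "returned unchanged",
            stacklevel=2,
        )
        return replace(raw, normalized=True)
    return replace(raw, matrix=logged / peak, normalized=True)


def _smoothing_matrix(adjacency, n_seeds: int) -> np.ndarray:
    """Row-stochastic neighborhood-averaging operator (self-loop included)."""
    if isinstance(adjacency, dict):
        items = adjacency.items()
    else:
        items = enumerate(adjacency)
    w = np.zeros((n_seeds, n_seeds))
    seen = np.zeros(n_seeds, dtype=bool)
    for i, neigh in items:
        if not (0 <= int(i) < n_seeds):
            raise ValueError(f"adjacency references unknown seed index {i}")
        seen[int(i)] = True
        hood = set(int(j) for j in neigh) | {int(i)}
        for j in hood:
            if not (0 <= j < n_seeds):
                raise ValueError(f"adjacency references unknown seed index {j}")
            w[int(i), j] = 1.0
    if not seen.all():
        missing = np.flatnonzero(~seen)
        raise ValueError(f"adjacency does not cover seed indices {missing.tolist()}")
    return w / w.sum(axis=1, keepdims=True)


def smooth_profile(
    profile: ConnectivityProfile, adjacency, rounds: int = 1
) -> ConnectivityProfile:
    """Iterated neighborhood averaging over seed rows.

    ``adjacency`` maps each seed index to its neighbor indices (list of
    lists or dict) and must cover every seed; each round replaces row *i*
    by the uniform mean over ``{i} ∪ neighbors(i)``.  ``rounds=0`` is the
    identity.  This is the geometry-free analogue of metric surface
    smoothing kernels.  For a degree-regular adjacency the operator is
    doubly stochastic, so per-target column sums over seeds are conserved;
    for irregular graphs mass migrates toward low-degree seeds.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if rounds == 0:
        return profile
    w = _smoothing_matrix(adjacency, profile.n_seeds)
    out = profile.matrix
    for _ in range(rounds):
        out = w @ out
    return replace(profile, matrix=out)


def population_map(
    profiles: list[ConnectivityProfile], threshold: float
) -> PopulationMap:
    """Across-subject mean map, thresholded to its support.

    All profiles must be normalized, share a shape and a hemisphere.
    Entries of the element-wise mean that are ``<= threshold`` are zeroed;
    ``support`` records the surviving indices (over the flattened map when
    the input matrices have more than one row).
    """
    if not profiles:
        raise ValueError("population_map requires at least one profile")
    shapes = {p.matrix.shape for p in profiles}
    hemis = {p.hemisphere for p in profiles}
    if len(shapes) > 1:
        raise ValueError(f"profiles have mixed shapes: {sorted(shapes)}")
    if len(hemis) > 1:
        raise ValueError(f"profiles have mixed hemispheres: {sorted(hemis)}")
    if not all(p.normalized for p in profiles):
        raise ValueError("profiles must be normalized before averaging")
    mean = np.mean([p.matrix for p in profiles], axis=0).ravel()
    keep = mean > threshold
    values = np.where(keep, mean, 0.0)
    nonzero = np.count_nonzero(mean)
    retained = float(keep.sum()) / nonzero if nonzero else 0.0
    return PopulationMap(
        values=values,
        threshold=threshold,
        support=np.flatnonzero(keep),
        retained_fraction=retained,
    )


def group_mask(left_pop: PopulationMap, right_pop: PopulationMap) -> np.ndarray:
    """Union of the left and (mirrored) right population-map supports.

    The right map must already be in mirrored, left-indexed space; the
    result is the sorted index set on which vertex-wise asymmetry is
    tested.  Symmetric in its arguments.
    """
    if left_pop.values.shape != right_pop.values.shape:
        raise ValueError(
            f"population maps differ in length: "
            f"{left_pop.values.shape} vs {right_pop.values.shape}"
        )
    return np.union1d(left_pop.support, right_pop.support)
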