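"""Similarity-based spectral parcellation of seed-vertex connectivity.

Seed vertices whose whole-brain connectivity fingerprints correlate are
grouped into subregions: Pearson correlation between seed rows gives an
M×M similarity matrix, subject matrices are averaged into a group matrix,
and spectral clustering of a shifted-to-non-negative affinity partitions
the seeds.  The cluster count k is scanned over a range and chosen as the
largest k whose partitions are consistent (mean pairwise adjusted Rand
index) across groups — hemispheres and species — above a threshold τ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from .profiles import ConnectivityProfile

__all__ = [
    "SimilarityMatrix",
    "Parcellation",
    "LabelMatch",
    "KScanResult",
    "seed_similarity",
    "group_similarity",
    "spectral_parcellate",
    "match_labels",
    "scan_k",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric seed × seed correlation matrix (subject or group level)."""

    matrix: np.ndarray
    level: str = "subject"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.max(np.abs(m - m.T)) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric within 1e-10")
        if np.max(np.abs(np.diag(m) - 1.0)) > 1e-8:
            raise ValueError("similarity matrix diagonal must be 1")
        if m.min() < -1 - 1e-8 or m.max() > 1 + 1e-8:
            raise ValueError("similarity entries must lie in [-1, 1]")
        if self.level not in ("subject", "group"):
            raise ValueError(f"level must be 'subject' or 'group', got {self.level!r}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_seeds(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Parcellation:
    """Integer label (1..k) per seed vertex plus per-cluster fingerprints.

    Labels are canonical: cluster 1 contains the lowest seed index, and
    new labels are assigned in order of first appearance along the seed
    axis, making outputs reproducible and diffable.
    """

    labels: np.ndarray
    k: int
    fingerprints: np.ndarray | None = None  # (k, n_targets) mean profile
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(
                f"labels must use every value in 1..{self.k}, found {present}"
            )
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class LabelMatch:
    """Optimal one-to-one label correspondence between two parcellations."""

    mapping: dict[int, int]  # label in a -> label in b
    pair_dice: dict[int, float]  # keyed by label in a
    overlap: float  # matched co-occurrence / n_seeds


@dataclass(frozen=True)
class KScanResult:
    """Per-k cross-group consistency scores and the selected k.

    ``scores`` holds the selection score per k (minimum matched-pair Dice
    by default); ``ari_scores`` the mean pairwise adjusted Rand index for
    reference.  ``chosen_k`` is the largest k whose selection score
    reaches τ; if none does, the argmax-score k is returned with
    ``reached_tau=False``.
    """

    scores: dict[int, float]
    chosen_k: int
    tau: float
    reached_tau: bool
    ari_scores: dict[int, float] = field(default_factory=dict)
    score_method: str = "min_dice"


def seed_similarity(profile: ConnectivityProfile) -> SimilarityMatrix:
    """Pearson correlation between every pair of seed fingerprint rows.

    The profile must be normalized and have at least two seeds.  Seeds
    whose row is constant (zero variance) have no defined correlation;
    they are assigned 0 against every other seed and 1 on the diagonal,
    with a warning.
    """
    if not profile.normalized:
        raise ValueError("profile must be normalized before computing similarity")
    m = profile.matrix
    if m.shape[0] < 2:
        raise ValueError("need at least 2 seed vertices for a similarity matrix")
    degenerate = np.flatnonzero(np.std(m, axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} constant seed row(s) {degenerate.tolist()} "
            "assigned zero similarity",
            stacklevel=2,
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(matrix=corr, level="subject")


def group_similarity(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean of subject-level similarity matrices."""
    if not mats:
        raise ValueError("group_similarity requires at least one matrix")
    shapes = {m.matrix.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"similarity matrices have mixed shapes: {sorted(shapes)}")
    mean = np.mean([m.matrix for m in mats], axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 1.0)
    return SimilarityMatrix(matrix=mean, level="group")


def _canonicalize(raw_labels: np.ndarray) -> np.ndarray:
    """Relabel so label 1 holds the lowest seed index, ascending by first
    appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw_labels)
    nxt = 1
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def spectral_parcellate(
    sim: SimilarityMatrix,
    k: int,
    seed: int = 0,
    affinity: str = "shift",
    profile: ConnectivityProfile | None = None,
) -> Parcellation:
    """Spectral clustering of the group similarity matrix into k clusters.

    Correlations (possibly negative) are mapped to non-negative affinities
    — ``"shift"`` uses (r+1)/2 (default, monotone over [−1,1]), ``"clip"``
    uses max(r, 0) — then a normalized-Laplacian spectral embedding into k
    dimensions is clustered by k-means with 10 restarts at a fixed seed.
    Labels are canonicalized (see :class:`Parcellation`).  When a
    normalized group-mean ``profile`` is supplied, per-cluster mean
    fingerprints are attached.
    """
    m = sim.n_seeds
    if not (2 <= k <= m):
        raise ValueError(f"k={k} out of range [2, {m}]")
    if sim.level != "group":
        raise ValueError("spectral_parcellate expects a group-level matrix")
    if affinity == "shift":
        aff = (sim.matrix + 1.0) / 2.0
    elif affinity == "clip":
        aff = np.maximum(sim.matrix, 0.0)
    else:
        raise ValueError(f"unknown affinity transform {affinity!r}")
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*graph is not fully connected.*"
        )
        sc = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            random_state=seed,
            n_init=10,
            assign_labels="kmeans",
            eigen_tol=1e-8,
        )
        raw = sc.fit_predict(aff)
    labels = _canonicalize(raw)
    fingerprints = None
    if profile is not None:
        fingerprints = np.vstack(
            [profile.matrix[labels == c].mean(axis=0) for c in range(1, k + 1)]
        )
    return Parcellation(
        labels=labels,
        k=k,
        fingerprints=fingerprints,
        provenance={"k": k, "seed": seed, "affinity": affinity},
    )


def match_labels(a: Parcellation, b: Parcellation) -> LabelMatch:
    """Optimal one-to-one label matching between two equal-k parcellations.

    Builds the k×k co-occurrence (contingency) table and solves the
    assignment problem maximizing total overlap (Hungarian method; the
    solver's deterministic order breaks ties at the lowest label pair).
    Returns the mapping, a Dice coefficient per matched pair, and the
    total matched co-occurrence as a fraction of seeds.
    """
    if a.k != b.k:
        raise ValueError(f"parcellations have different k: {a.k} vs {b.k}")
    if a.labels.shape != b.labels.shape:
        raise ValueError("parcellations cover different numbers of seeds")
    k = a.k
    table = np.zeros((k, k))
    np.add.at(table, (a.labels - 1, b.labels - 1), 1)
    rows, cols = linear_sum_assignment(-table)
    mapping = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    sizes_a = np.bincount(a.labels - 1, minlength=k)
    sizes_b = np.bincount(b.labels - 1, minlength=k)
    dice = {
        int(r) + 1: 2.0 * table[r, c] / (sizes_a[r] + sizes_b[c])
        for r, c in zip(rows, cols)
    }
    overlap = float(table[rows, cols].sum()) / a.labels.size
    return LabelMatch(mapping=mapping, pair_dice=dice, overlap=overlap)


def scan_k(
    group_sims: dict[str, SimilarityMatrix],
    k_range=range(2, 13),
    tau: float = 0.8,
    seed: int = 0,
    affinity: str = "shift",
    score_method: str = "min_dice",
) -> KScanResult:
    """Scan cluster counts and select k by cross-group consistency.

    For each k every group (hemisphere/species) similarity matrix is
    parcellated and two consistency measures are recorded over all group
    pairs: the mean pairwise adjusted Rand index (``ari_scores``; ARI is
    permutation-invariant so index-matched label vectors are compared
    directly) and the minimum Dice coefficient over Hungarian-matched
    cluster pairs.  Selection uses ``score_method`` — default
    ``"min_dice"``, which demands that *every* cluster has a good
    counterpart in every group and therefore rejects cluster counts whose
    extra clusters are noise-driven splits (mean ARI stays high in that
    case because the remaining clusters still agree, which would let the
    max-k rule overshoot the coherent solution).  ``"ari"`` selects on the
    mean pairwise ARI instead.  The chosen k is the largest one whose
    selection score reaches τ; if none does, the argmax-score k is
    returned flagged ``reached_tau=False``.
    """
    if not group_sims:
        raise ValueError("scan_k requires at least one group similarity matrix")
    if len(group_sims) < 2:
        raise ValueError("scan_k needs >= 2 groups to score consistency")
    if score_method not in ("min_dice", "ari"):
        raise ValueError(f"unknown score_method {score_method!r}")
    sizes = {s.n_seeds for s in group_sims.values()}
    if len(sizes) > 1:
        raise ValueError("groups must share a common seed count")
    ks = list(k_range)
    scores: dict[int, float] = {}
    ari_scores: dict[int, float] = {}
    names = sorted(group_sims)
    for k in ks:
        parcs = [
            spectral_parcellate(group_sims[g], k, seed=seed, affinity=affinity)
            for g in names
        ]
        aris, dices = [], []
        for i in range(len(parcs)):
            for j in range(i + 1, len(parcs)):
                aris.append(adjusted_rand_score(parcs[i].labels, parcs[j].labels))
                matched = match_labels(parcs[i], parcs[j])
                dices.append(min(matched.pair_dice.values()))
        ari_scores[k] = float(np.mean(aris))
        scores[k] = float(min(dices)) if score_method == "min_dice" else ari_scores[k]
    reaching = [k for k in ks if scores[k] >= tau]
    if reaching:
        chosen, reached = max(reaching), True
    else:
        chosen, reached = max(ks, key=lambda k: (scores[k], -k)), False
    return KScanResult(
        scores=scores,
        chosen_k=chosen,
        tau=tau,
        reached_tau=reached,
        ari_scores=ari_scores,
        score_method=score_method,
    )
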