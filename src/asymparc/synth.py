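"""Synthetic multi-species connectivity and volume data with known ground truth.

The generator emulates the statistical structure of a cross-species
tractography study of a seeded cortical region: per subject and hemisphere
a block-structured seed × target connectivity matrix (rows of one block
share a cluster fingerprint), species-specific multiplicative connectional
asymmetries planted on the right hemisphere, per-subregion left/right
volumes with a planted volumetric asymmetry index, and power-law
(allometric) scaling of subregion volume against total gray-matter volume.
Three presets mirror the qualitative study conditions: a macaque-like
species with no asymmetries (n=8), and chimpanzee-like (n=27) and
human-like (n=40) species sharing an anterior-leftward / posterior-rightward
volumetric pattern, the human-like species carrying connectional effects on
more targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import ConnectivityProfile

__all__ = [
    "SpeciesSpec",
    "SyntheticDataset",
    "generate_connectivity",
    "generate_volumes",
    "generate_dataset",
    "block_similarity",
    "macaque_like",
    "chimp_like",
    "human_like",
    "preset",
]


@dataclass
class SpeciesSpec:
    """Ground-truth description of one synthetic species.

    Connectivity side: ``n_seeds`` seed vertices per hemisphere are
    partitioned by ``block_assignment`` into ``k_true`` clusters; row *i*
    of a subject-hemisphere matrix is drawn around
    ``cluster_profiles[block_assignment[i]-1]`` with additive Gaussian
    noise rectified at zero, and right-hemisphere rows are multiplied
    element-wise by the cluster's ``asym_effects`` row (1.0 = symmetric,
    >1 plants rightward connectional asymmetry).

    Volume side: per subject a total gray-matter volume (GMV) is drawn
    log-uniformly in ``gmv_range``; subregion *j*'s bilateral mean volume
    follows the power law ``exp(scaling_intercept[j]) * GMV**scaling_exponent[j]``
    and is split left/right so that the asymmetry index 2(R−L)/(R+L)
    equals ``volume_ai[j]`` exactly before per-hemisphere lognormal noise.
    """

    name: str
    n_subjects: int
    n_seeds: int
    n_targets: int
    k_true: int
    block_assignment: np.ndarray  # (n_seeds,) labels in 1..k_true
    cluster_profiles: np.ndarray  # (k_true, n_targets) >= 0
    asym_effects: np.ndarray = None  # (k_true, n_targets), default all 1
    noise_sd: float = 0.0
    scaling_exponent: np.ndarray = None  # (k_true,) > 0
    scaling_intercept: np.ndarray = None  # (k_true,) natural-log scale
    volume_ai: np.ndarray = None  # (k_true,) in (-2, 2)
    gmv_range: tuple[float, float] = (1e5, 2e5)
    volume_noise_sd: float = 0.0
    subregion_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.block_assignment = np.asarray(self.block_assignment, dtype=int)
        self.cluster_profiles = np.asarray(self.cluster_profiles, dtype=float)
        if self.asym_effects is None:
            self.asym_effects = np.ones_like(self.cluster_profiles)
        self.asym_effects = np.asarray(self.asym_effects, dtype=float)
        if self.scaling_exponent is None:
            self.scaling_exponent = np.full(self.k_true, 1.0)
        self.scaling_exponent = np.atleast_1d(
            np.asarray(self.scaling_exponent, dtype=float)
        )
        if self.scaling_intercept is None:
            self.scaling_intercept = np.zeros(self.k_true)
        self.scaling_intercept = np.atleast_1d(
            np.asarray(self.scaling_intercept, dtype=float)
        )
        if self.volume_ai is None:
            self.volume_ai = np.zeros(self.k_true)
        self.volume_ai = np.atleast_1d(np.asarray(self.volume_ai, dtype=float))
        if not self.subregion_names:
            self.subregion_names = tuple(f"C{j + 1}" for j in range(self.k_true))

    def validate(self) -> None:
        if self.k_true > self.n_seeds:
            raise ValueError(
                f"invalid spec: k_true={self.k_true} exceeds n_seeds={self.n_seeds}"
            )
        if self.k_true < 1:
            raise ValueError("invalid spec: k_true must be >= 1")
        if self.noise_sd < 0:
            raise ValueError(f"invalid spec: negative noise_sd {self.noise_sd}")
        if self.volume_noise_sd < 0:
            raise ValueError("invalid spec: negative volume_noise_sd")
        if self.block_assignment.shape != (self.n_seeds,):
            raise ValueError(
                "invalid spec: block_assignment must cover all "
                f"{self.n_seeds} seeds (got shape {self.block_assignment.shape})"
            )
        labels = np.unique(self.block_assignment)
        if labels.min() < 1 or labels.max() > self.k_true:
            raise ValueError(
                f"invalid spec: block labels must lie in 1..{self.k_true}"
            )
        if len(labels) != self.k_true:
            raise ValueError("invalid spec: every cluster label must occur")
        if self.cluster_profiles.shape != (self.k_true, self.n_targets):
            raise ValueError("invalid spec: cluster_profiles shape mismatch")
        if np.any(self.cluster_profiles < 0):
            raise ValueError("invalid spec: cluster_profiles must be non-negative")
        if self.asym_effects.shape != (self.k_true, self.n_targets):
            raise ValueError("invalid spec: asym_effects shape mismatch")
        if np.any(self.asym_effects < 0):
            raise ValueError("invalid spec: asym_effects must be non-negative")
        for arr, what in (
            (self.scaling_exponent, "scaling_exponent"),
            (self.scaling_intercept, "scaling_intercept"),
            (self.volume_ai, "volume_ai"),
        ):
            if arr.shape != (self.k_true,):
                raise ValueError(f"invalid spec: {what} must have length k_true")
        if np.any(self.scaling_exponent <= 0):
            raise ValueError("invalid spec: scaling_exponent must be > 0")
        if np.any(np.abs(self.volume_ai) >= 2):
            raise ValueError(
                "invalid spec: volume_ai must lie strictly inside (-2, 2)"
            )
        lo, hi = self.gmv_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid spec: bad gmv_range {self.gmv_range}")


@dataclass
class SyntheticDataset:
    """One generated species: profiles, volumes and the planted truth.

    ``profiles[(subject_id, hemisphere)]`` holds raw (unnormalized)
    :class:`~asymparc.profiles.ConnectivityProfile` objects; left and right
    share seed indexing.  ``volumes`` is a tidy frame with one row per
    (subject, subregion) holding ``gmv``, ``left_vol`` and ``right_vol``.
    Regeneration from the same (spec, seed) is bit-identical.
    """

    spec: SpeciesSpec
    profiles: dict[tuple[str, str], ConnectivityProfile]
    gmv: np.ndarray
    volumes: pd.DataFrame
    seed: int
    ground_truth: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [f"{self.spec.name}{i:03d}" for i in range(self.spec.n_subjects)]


def _subject_ids(spec: SpeciesSpec) -> list[str]:
    return [f"{spec.name}{i:03d}" for i in range(spec.n_subjects)]


def generate_connectivity(
    spec: SpeciesSpec, seed: int
) -> dict[tuple[str, str], ConnectivityProfile]:
    """Draw per-subject, per-hemisphere connectivity matrices.

    Row *i* is the cluster fingerprint of seed *i* plus rectified Gaussian
    noise of scale ``spec.noise_sd`` (independent between hemispheres);
    right-hemisphere rows are then multiplied element-wise by the cluster's
    ``asym_effects``.  With ``noise_sd=0`` and all effects 1 the two
    hemispheres are identical; a cluster effect of 1.5 makes every right
    row of that cluster exactly 1.5× its left counterpart.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    base = spec.cluster_profiles[spec.block_assignment - 1]  # (M, N)
    effects = spec.asym_effects[spec.block_assignment - 1]
    profiles: dict[tuple[str, str], ConnectivityProfile] = {}
    for sid in _subject_ids(spec):
        for hemi in ("L", "R"):
            mat = base.copy()
            if spec.noise_sd > 0:
                mat = np.maximum(
                    0.0, mat + rng.normal(0.0, spec.noise_sd, size=mat.shape)
                )
            if hemi == "R":
                mat = mat * effects
            profiles[(sid, hemi)] = ConnectivityProfile(
                matrix=mat, subject_id=sid, hemisphere=hemi
            )
    return profiles


def generate_volumes(spec: SpeciesSpec, seed: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw total GMV and per-subregion left/right volumes.

    GMV is log-uniform in ``spec.gmv_range``.  Subregion *j*'s bilateral
    mean follows ``exp(intercept_j) * GMV**exponent_j``; the left/right
    split plants the asymmetry index exactly (L = V̄(1−AI/2),
    R = V̄(1+AI/2)), after which each hemisphere receives independent
    lognormal noise ``exp(N(0, volume_noise_sd))`` so the per-subject AI
    scatters around the planted value (and equals it exactly when
    ``volume_noise_sd=0``).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    lo, hi = spec.gmv_range
    gmv = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_subjects))
    rows = []
    for i, sid in enumerate(_subject_ids(spec)):
        for j, name in enumerate(spec.subregion_names):
            vbar = np.exp(spec.scaling_intercept[j]) * gmv[i] ** spec.scaling_exponent[j]
            left = vbar * (1.0 - spec.volume_ai[j] / 2.0)
            right = vbar * (1.0 + spec.volume_ai[j] / 2.0)
            if spec.volume_noise_sd > 0:
                left *= np.exp(rng.normal(0.0, spec.volume_noise_sd))
                right *= np.exp(rng.normal(0.0, spec.volume_noise_sd))
            rows.append((sid, gmv[i], name, left, right))
    volumes = pd.DataFrame(
        rows, columns=["subject", "gmv", "subregion", "left_vol", "right_vol"]
    )
    return gmv, volumes


def generate_dataset(spec: SpeciesSpec, seed: int) -> SyntheticDataset:
    """Generate a full species dataset (connectivity + volumes + truth)."""
    spec.validate()
    child = np.random.SeedSequence(seed).spawn(2)
    conn_seed = int(child[0].generate_state(1)[0] % 2**31)
    vol_seed = int(child[1].generate_state(1)[0] % 2**31)
    profiles = generate_connectivity(spec, conn_seed)
    gmv, volumes = generate_volumes(spec, vol_seed)
    truth = {
        "labels": spec.block_assignment.copy(),
        "k_true": spec.k_true,
        "asym_effects": spec.asym_effects.copy(),
        "scaling_exponent": spec.scaling_exponent.copy(),
        "scaling_intercept": spec.scaling_intercept.copy(),
        "volume_ai": spec.volume_ai.copy(),
    }
    return SyntheticDataset(
        spec=spec,
        profiles=profiles,
        gmv=gmv,
        volumes=volumes,
        seed=seed,
        ground_truth=truth,
    )


def block_similarity(
    n_seeds: int = 400,
    k: int = 4,
    r_within: float = 0.8,
    r_between: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Planted k-block seed-similarity matrix plus its true labels.

    Within-block entries are ``r_within``, between-block ``r_between``,
    plus symmetric Gaussian noise of per-entry scale ``noise_sd``; the
    diagonal is 1 and entries are clipped to [−1, 1].  Blocks are
    contiguous and as equal-sized as possible.  This is the benchmark
    input for cluster-recovery checks.
    """
    from .parcellation import SimilarityMatrix

    rng = np.random.default_rng(seed)
    labels = 1 + (np.arange(n_seeds) * k) // n_seeds
    same = labels[:, None] == labels[None, :]
    sim = np.where(same, r_within, r_between).astype(float)
    noise = rng.normal(0.0, noise_sd, size=(n_seeds, n_seeds))
    sim += np.triu(noise, 1) + np.triu(noise, 1).T
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, -1.0, 1.0)
    return SimilarityMatrix(matrix=sim, level="group"), labels


# ---------------------------------------------------------------------------
# Preset species
# ---------------------------------------------------------------------------

# Shared layout: 80 seeds in 4 contiguous blocks of 20; 120 targets of which
# each cluster "prefers" a contiguous band of 25 (with a tall anchor target
# kept symmetric so per-matrix max-normalization is stable across
# hemispheres) and the last 20 targets are low-level background everywhere.
_M, _N, _K = 80, 120, 4
_BAND = 25
_BACKGROUND = 0.2
_PREFERRED = 2.0
_ANCHOR = 6.0

# Allometric truth shared across species so pooling them recovers one
# power law per subregion: exponents all > 1 (positive allometry) with
# intercepts anchored to plausible subregion volumes at a human-scale GMV.
_EXPONENTS = np.array([1.15, 1.20, 1.25, 1.30])
_REF_GMV = 5.5e5
_REF_VOLS = np.array([1500.0, 2000.0, 2500.0, 3000.0])
_INTERCEPTS = np.log(_REF_VOLS) - _EXPONENTS * np.log(_REF_GMV)

_NOISE_SD = 0.4
_VOL_NOISE = 0.05


def _base_profiles(jitter_seed: int) -> np.ndarray:
    rng = np.random.default_rng(jitter_seed)
    prof = np.full((_K, _N), _BACKGROUND)
    for c in range(_K):
        band = slice(c * _BAND, (c + 1) * _BAND)
        prof[c, band] = _PREFERRED
        prof[c, c * _BAND] = _ANCHOR
    # small fixed jitter so no row is exactly piecewise constant
    prof += rng.uniform(0.0, 0.05, size=prof.shape)
    return prof


def _effects(n_affected: int, left_factor: float, right_factor: float) -> np.ndarray:
    """Anterior clusters (1,2) leftward, posterior (3,4) rightward."""
    eff = np.ones((_K, _N))
    for c in range(_K):
        factor = left_factor if c < 2 else right_factor
        lo = c * _BAND + 1  # skip the anchor target
        eff[c, lo : lo + n_affected] = factor
    return eff


def _preset(
    name: str,
    n_subjects: int,
    asym_effects: np.ndarray,
    volume_ai: np.ndarray,
    gmv_range: tuple[float, float],
    jitter_seed: int,
) -> SpeciesSpec:
    return SpeciesSpec(
        name=name,
        n_subjects=n_subjects,
        n_seeds=_M,
        n_targets=_N,
        k_true=_K,
        block_assignment=1 + (np.arange(_M) * _K) // _M,
        cluster_profiles=_base_profiles(jitter_seed),
        asym_effects=asym_effects,
        noise_sd=_NOISE_SD,
        scaling_exponent=_EXPONENTS,
        scaling_intercept=_INTERCEPTS,
        volume_ai=volume_ai,
        gmv_range=gmv_range,
        volume_noise_sd=_VOL_NOISE,
    )


def macaque_like() -> SpeciesSpec:
    """Small-n species with no planted asymmetries (null control)."""
    return _preset(
        "macaque",
        n_subjects=8,
        asym_effects=np.ones((_K, _N)),
        volume_ai=np.zeros(_K),
        gmv_range=(4.5e4, 7.0e4),
        jitter_seed=101,
    )


def chimp_like() -> SpeciesSpec:
    """Anterior-leftward / posterior-rightward volumetric asymmetry plus
    connectional effects on 8 targets per cluster."""
    return _preset(
        "chimp",
        n_subjects=27,
        asym_effects=_effects(8, left_factor=0.78, right_factor=1.28),
        volume_ai=np.array([-0.15, -0.10, 0.10, 0.15]),
        gmv_range=(1.8e5, 2.8e5),
        jitter_seed=102,
    )


def human_like() -> SpeciesSpec:
    """Same volumetric sign pattern as the chimp-like species but with
    connectional effects on 18 targets per cluster (wider asymmetric
    network), mirroring the planted cross-species ordering."""
    return _preset(
        "human",
        n_subjects=40,
        asym_effects=_effects(18, left_factor=0.74, right_factor=1.35),
        volume_ai=np.array([-0.15, -0.10, 0.10, 0.15]),
        gmv_range=(4.2e5, 6.8e5),
        jitter_seed=103,
    )


_PRESETS = {"macaque": macaque_like, "chimp": chimp_like, "human": human_like}


def preset(name: str) -> SpeciesSpec:
    """Look up a preset species spec by name (macaque/chimp/human)."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
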