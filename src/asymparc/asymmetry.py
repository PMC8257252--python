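"""Hemispheric asymmetry indices and their statistics.

The asymmetry index AI = 2(R − L)/(R + L) compares homotopic left/right
measurements on a bounded scale [−2, 2]; negative values mean leftward
(L > R) dominance.  Three test families operate on per-subject AIs:

* vertex-wise one-sample t tests against zero with a sign-flip permutation
  null (exhaustive over all 2^n flips when feasible, Monte Carlo otherwise)
  and Benjamini–Hochberg FDR across the analysis mask, with Cohen's d
  effect sizes;
* ROI-wise and tract-wise two-sided Wilcoxon signed-rank tests with
  Bonferroni correction (exact null by enumeration for small n);
* volumetric Wilcoxon tests per subregion, same correction.

`run_asymmetry_battery` glues these into one tidy results table for a
synthetic species dataset and a parcellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .parcellation import Parcellation
from .profiles import ConnectivityProfile, group_mask, normalize_profile, population_map
from .synth import SyntheticDataset

__all__ = [
    "asymmetry_index",
    "vertexwise_test",
    "region_values",
    "paired_signed_rank",
    "WilcoxonResult",
    "bonferroni_adjust",
    "bh_fdr",
    "run_asymmetry_battery",
]


def asymmetry_index(L, R):
    """AI = 2(R − L)/(R + L); NaN where L + R = 0; errors on negatives.

    Antisymmetric in its arguments, zero at L = R, and bounded in [−2, 2]
    for non-negative inputs.  Accepts scalars or arrays (broadcast).
    """
    left = np.asarray(L, dtype=float)
    right = np.asarray(R, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("asymmetry_index requires non-negative inputs")
    total = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(total > 0, 2.0 * (right - left) / np.where(total > 0, total, 1.0), np.nan)
    if ai.ndim == 0:
        return float(ai)
    return ai


# ---------------------------------------------------------------------------
# Sign-flip permutation engine
# ---------------------------------------------------------------------------


def _flip_matrix(n: int, n_perm: int, rng: np.random.Generator):
    """Sign matrices for the permutation null.

    Returns ``(S, exhaustive)``: all 2^n sign patterns when 2^n <= n_perm,
    else ``n_perm`` Monte Carlo draws (the identity flip is accounted for
    separately by the add-one p estimator).
    """
    if n <= 0:
        raise ValueError("need at least one observation")
    if n < 63 and 2**n <= n_perm:
        bits = (np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)) & 1
        return (2 * bits - 1).astype(float), True
    return (2 * rng.integers(0, 2, size=(n_perm, n)) - 1).astype(float), False


def _flip_t(x: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t statistics of sign-flipped data, vectorized.

    ``x`` has shape (n, V); ``flips`` (P, n).  Because flipping signs
    leaves sum(x²) unchanged, the flipped variance follows from the
    flipped mean alone.  Zero-variance flips yield ±inf (or 0 when the
    mean is also zero); the observed statistic is always computed through
    this same code path (identity flip) so magnitude comparisons are
    bit-consistent.
    """
    n = x.shape[0]
    sumsq = np.sum(x * x, axis=0)  # (V,)
    means = flips @ x / n  # (P, V)
    var = np.maximum(sumsq[None, :] - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
        t = np.where(
            var == 0, np.where(means == 0, 0.0, np.sign(means) * np.inf), t
        )
    return t


def _signflip_pvalues(x: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Two-sided sign-flip p per column of x (n subjects × V units).

    Exhaustive mode: p = #{|t*| >= |t|} / 2^n over all flips (the identity
    is one of them).  Monte Carlo mode: p = (1 + #{|t*| >= |t|}) /
    (1 + n_perm) with the identity flip always included via the add-one
    estimator, so p >= 1/(n_perm + 1) and the estimator is valid.
    Returns (t_obs, p, d).
    """
    n = x.shape[0]
    flips, exhaustive = _flip_matrix(n, n_perm, rng)
    t_obs = _flip_t(x, np.ones((1, n)))[0]
    t_null = _flip_t(x, flips)
    # ulp-tolerant threshold: the identity and mirror flips are exact ties
    # mathematically but may differ in the last bit between matmul shapes
    with np.errstate(invalid="ignore"):
        thresh = np.abs(t_obs) * (1.0 - 1e-12)
    exceed = np.sum(np.abs(t_null) >= thresh[None, :], axis=0)
    if exhaustive:
        p = exceed / flips.shape[0]
    else:
        p = (1.0 + exceed) / (1.0 + flips.shape[0])
    sd = np.std(x, axis=0, ddof=1)
    mean = np.mean(x, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            sd == 0,
            np.where(mean == 0, 0.0, np.sign(mean) * np.inf),
            mean / np.where(sd == 0, 1.0, sd),
        )
    # degenerate all-zero column: null saturates, p = 1 by construction
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    return t_obs, p, d


def vertexwise_test(
    ai: np.ndarray,
    mask=None,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    unit_ids=None,
) -> pd.DataFrame:
    """One-sample sign-flip permutation t tests per vertex, FDR-corrected.

    Parameters
    ----------
    ai
        Array of shape (n_subjects, n_units) of per-subject asymmetry
        values; NaNs are treated as missing and dropped pairwise per unit.
    mask
        Indices of the units to test (the group mask); default all.
    n_perm
        Permutation budget; all 2^n flips are enumerated when 2^n <= n_perm.
    seed, alpha
        RNG seed for Monte Carlo flips; FDR level for the significance flag.

    Returns a tidy frame (one row per masked unit) with columns
    ``unit, n, stat, p, q, d, significant``.  Units with fewer than two
    observed subjects are missing-coded and excluded from the FDR family.
    """
    ai = np.asarray(ai, dtype=float)
    if ai.ndim != 2:
        raise ValueError("ai must be a 2-D (subjects × units) array")
    n_subj, n_units = ai.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if mask is None:
        mask = np.arange(n_units)
    mask = np.asarray(mask, dtype=int)
    if mask.size and (mask.min() < 0 or mask.max() >= n_units):
        raise ValueError("mask references unknown unit indices")
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    rng = np.random.default_rng(seed)

    sub = ai[:, mask]
    obs_counts = np.sum(~np.isnan(sub), axis=0)
    t = np.full(mask.size, np.nan)
    p = np.full(mask.size, np.nan)
    d = np.full(mask.size, np.nan)

    complete = np.flatnonzero(obs_counts == n_subj)
    if complete.size:
        t[complete], p[complete], d[complete] = _signflip_pvalues(
            sub[:, complete], n_perm, rng
        )
    for j in np.flatnonzero((obs_counts < n_subj) & (obs_counts >= 2)):
        col = sub[:, j]
        col = col[~np.isnan(col)]
        tj, pj, dj = _signflip_pvalues(col[:, None], n_perm, rng)
        t[j], p[j], d[j] = tj[0], pj[0], dj[0]

    q = np.full(mask.size, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = bh_fdr(p[valid])
    result = pd.DataFrame(
        {
            "unit": np.asarray(unit_ids)[mask],
            "n": obs_counts,
            "stat": t,
            "p": p,
            "q": q,
            "d": d,
        }
    )
    result["significant"] = (result["q"] < alpha).fillna(False)
    return result


def region_values(L: np.ndarray, R: np.ndarray, region) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject mean connectivity over a region's unit indices.

    ``L`` and ``R`` are (n_subjects × n_units) hemisphere value arrays
    sharing unit indexing; ``region`` is a non-empty index set.  Returns
    the per-subject left and right means.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    region = np.asarray(region, dtype=int)
    if region.size == 0:
        raise ValueError("region index set is empty")
    n_units = L.shape[1]
    if R.shape != L.shape:
        raise ValueError("hemisphere arrays differ in shape")
    if region.min() < 0 or region.max() >= n_units:
        raise ValueError("region references unknown unit indices")
    return L[:, region].mean(axis=1), R[:, region].mean(axis=1)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided signed-rank test outcome.

    ``statistic`` is W+ (sum of ranks of positive R−L differences);
    ``n_used`` counts non-zero differences, ``n_zeros`` the discarded
    zeros (classical handling); ``method`` is ``"exact"`` (full null
    enumeration, used when n_used <= 12) or ``"approx"`` (normal
    approximation with tie and continuity correction).
    """

    statistic: float
    p_value: float
    n_used: int
    n_zeros: int
    method: str


_EXACT_LIMIT = 12


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over the signed-rank null.

    Ranks of |d| (mid-ranks for ties) are doubled to integers; a
    subset-sum convolution enumerates the exact distribution of 2·W+ over
    all 2^n equiprobable sign assignments, and the two-sided p is the
    probability of a deviation from the null mean n(n+1)/4 at least as
    large as observed.
    """
    n = diffs.size
    ranks2 = np.rint(2.0 * stats.rankdata(np.abs(diffs))).astype(int)
    total = int(ranks2.sum())  # = n(n+1)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        counts[r:] = counts[r:] + counts[:-r] if r else counts[r:] * 2
    w2 = int(ranks2[diffs > 0].sum())
    center2 = total // 2  # 2 * n(n+1)/4, exact integer
    dev = abs(w2 - center2)
    values = np.arange(total + 1)
    return float(counts[np.abs(values - center2) >= dev].sum() / 2.0**n)


def paired_signed_rank(
    L_vals, R_vals, zero_method: str = "discard"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of R − L differences.

    Zero differences are discarded (classical Wilcoxon handling; their
    count is reported) unless ``zero_method="pratt"``.  The null is
    enumerated exactly for up to 12 non-zero differences (tie-aware);
    larger samples use the normal approximation with tie and continuity
    correction.  All-zero differences give W = 0, p = 1 with a warning.
    """
    left = np.asarray(L_vals, dtype=float)
    right = np.asarray(R_vals, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("L_vals and R_vals must be 1-D of equal length")
    if left.size < 2:
        raise ValueError("need at least 2 paired observations")
    diffs = right - left
    n_zeros = int(np.sum(diffs == 0))
    if zero_method not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, n_zeros, "degenerate")
    if zero_method == "pratt":
        res = stats.wilcoxon(
            diffs, zero_method="pratt", correction=True, method="approx"
        )
        ranks = stats.rankdata(np.abs(diffs))
        w_plus = float(ranks[diffs > 0].sum())
        return WilcoxonResult(
            w_plus, float(res.pvalue), int(nonzero.size), n_zeros, "approx-pratt"
        )
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if nonzero.size <= _EXACT_LIMIT:
        p = _exact_signed_rank_p(nonzero)
        return WilcoxonResult(w_plus, min(p, 1.0), int(nonzero.size), n_zeros, "exact")
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=True, method="approx"
    )
    return WilcoxonResult(
        w_plus, float(res.pvalue), int(nonzero.size), n_zeros, "approx"
    )


# ---------------------------------------------------------------------------
# Multiple-comparison corrections
# ---------------------------------------------------------------------------


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p·m).

    ``m`` defaults to the list length and may exceed it (e.g. a family
    spanning subregions × regions × species tested in separate calls).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, p * m)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------


def _cluster_means(
    dataset: SyntheticDataset, labels: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Normalized per-subject, per-cluster mean fingerprints (L and R)."""
    sids = dataset.subject_ids
    n_targets = dataset.spec.n_targets
    out = {h: np.empty((len(sids), k, n_targets)) for h in ("L", "R")}
    for s, sid in enumerate(sids):
        for hemi in ("L", "R"):
            if (sid, hemi) not in dataset.profiles:
                raise ValueError(f"missing hemisphere {hemi} for subject {sid}")
            norm = normalize_profile(dataset.profiles[(sid, hemi)]).matrix
            for c in range(1, k + 1):
                out[hemi][s, c - 1] = norm[labels == c].mean(axis=0)
    return out["L"], out["R"], sids


def _battery_mask(cl: np.ndarray, cr: np.ndarray, threshold: float) -> np.ndarray:
    """Group mask: union of thresholded L/R population maps of the
    subject seed-mean profiles (cluster means averaged over clusters)."""
    pops = {}
    for hemi, arr in (("L", cl), ("R", cr)):
        subject_maps = [
            ConnectivityProfile(
                matrix=arr[s].mean(axis=0, keepdims=True),
                subject_id=str(s),
                hemisphere=hemi,
                normalized=True,
            )
            for s in range(arr.shape[0])
        ]
        pops[hemi] = population_map(subject_maps, threshold)
    return group_mask(pops["L"], pops["R"])


def _rank_rows(level, species, names, m_family, alpha, zero_method) -> list[dict]:
    rows = []
    for (subregion, unit), (lv, rv) in names.items():
        ai = asymmetry_index(np.asarray(lv), np.asarray(rv))
        ai = np.atleast_1d(ai)
        ok = ~np.isnan(ai)
        res = paired_signed_rank(np.asarray(lv), np.asarray(rv), zero_method)
        sd = np.std(ai[ok], ddof=1) if ok.sum() > 1 else np.nan
        d = float(np.mean(ai[ok]) / sd) if sd and sd > 0 else np.nan
        rows.append(
            {
                "level": level,
                "species": species,
                "subregion": subregion,
                "unit": unit,
                "n": int(ok.sum()),
                "ai_mean": float(np.mean(ai[ok])) if ok.any() else np.nan,
                "stat": res.statistic,
                "p": res.p_value,
                "p_corr": float(bonferroni_adjust([res.p_value], m_family)[0]),
                "d": d,
            }
        )
    for r in rows:
        r["significant"] = bool(r["p_corr"] < alpha)
    return rows


def run_asymmetry_battery(
    dataset: SyntheticDataset,
    parcellation: Parcellation,
    roi_sets: dict | None = None,
    tract_sets: dict | None = None,
    *,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    pop_threshold: float = 0.15,
    family_scale: int = 1,
    vertex_value: str = "ai",
    zero_method: str = "discard",
) -> pd.DataFrame:
    """Volumetric, vertex-wise, ROI-wise and tract-wise asymmetry tests.

    Per-subject AIs are computed at each level: subregion volumes
    (Wilcoxon + Bonferroni over subregions), cluster-fingerprint values at
    every target in the group mask (sign-flip permutation t tests + FDR
    within the mask), and cluster-to-region mean connectivity for each
    entry of ``roi_sets`` / ``tract_sets`` (Wilcoxon + Bonferroni with
    family m = subregions × regions, times ``family_scale`` for a
    cross-species family).  ``vertex_value="diff"`` tests plain R−L
    differences instead of AIs at the vertex level.

    Returns one tidy table with columns ``level, species, subregion, unit,
    n, ai_mean, stat, p, p_corr, d, significant``; the analysis mask and
    settings are attached in ``result.attrs``.
    """
    if vertex_value not in ("ai", "diff"):
        raise ValueError(f"unknown vertex_value {vertex_value!r}")
    spec = dataset.spec
    k = parcellation.k
    labels = parcellation.labels
    if labels.size != spec.n_seeds:
        raise ValueError("parcellation does not match the dataset's seed count")
    names = list(spec.subregion_names)
    while len(names) < k:
        names.append(f"C{len(names) + 1}")

    cl, cr, sids = _cluster_means(dataset, labels, k)
    mask = _battery_mask(cl, cr, pop_threshold)
    rows: list[dict] = []

    # --- volumetric ---
    vol = dataset.volumes
    vol_pairs = {}
    for sub in vol["subregion"].unique():
        block = vol[vol["subregion"] == sub]
        vol_pairs[(sub, sub)] = (
            block["left_vol"].to_numpy(),
            block["right_vol"].to_numpy(),
        )
    rows += _rank_rows(
        "volumetric", spec.name, vol_pairs,
        m_family=len(vol_pairs) * family_scale, alpha=alpha, zero_method=zero_method,
    )

    # --- vertex-wise, one map per subregion ---
    for c in range(k):
        if vertex_value == "ai":
            values = asymmetry_index(cl[:, c, :], cr[:, c, :])
        else:
            values = cr[:, c, :] - cl[:, c, :]
        vt = vertexwise_test(
            values, mask=mask, n_perm=n_perm, seed=seed + c, alpha=alpha
        )
        ai_vals = asymmetry_index(cl[:, c, :], cr[:, c, :])
        for _, r in vt.iterrows():
            t_idx = int(r["unit"])
            col = ai_vals[:, t_idx]
            rows.append(
                {
                    "level": "vertex",
                    "species": spec.name,
                    "subregion": names[c],
                    "unit": t_idx,
                    "n": int(r["n"]),
                    "ai_mean": float(np.nanmean(col)) if np.any(~np.isnan(col)) else np.nan,
                    "stat": r["stat"],
                    "p": r["p"],
                    "p_corr": r["q"],
                    "d": r["d"],
                    "significant": bool(r["significant"]),
                }
            )

    # --- ROI-wise and tract-wise ---
    for level, sets in (("roi", roi_sets), ("tract", tract_sets)):
        if not sets:
            continue
        pairs = {}
        for region_name, region in sets.items():
            for c in range(k):
                lv, rv = region_values(cl[:, c, :], cr[:, c, :], region)
                pairs[(names[c], region_name)] = (lv, rv)
        rows += _rank_rows(
            level, spec.name, pairs,
            m_family=k * len(sets) * family_scale, alpha=alpha,
            zero_method=zero_method,
        )

    table = pd.DataFrame(rows)
    table.attrs["mask"] = [int(i) for i in mask]
    table.attrs["settings"] = {
        "alpha": alpha,
        "n_perm": n_perm,
        "seed": seed,
        "pop_threshold": pop_threshold,
        "family_scale": family_scale,
        "vertex_value": vertex_value,
        "zero_method": zero_method,
    }
    return table
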