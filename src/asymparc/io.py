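"""Plain-text TSV/JSON serialization of datasets and results.

Layout: one TSV per subject-hemisphere connectivity matrix (rows = seeds,
columns = target ids, header row), one tidy volumes TSV
(subject, gmv, subregion, left_vol, right_vol), a JSON ground-truth file,
two-column TSVs for parcellations (seed_id, label) and population maps
(target_id, value), and one-column 0-based index files for masks.
Everything is diffable text; floats use a fixed format so identical runs
are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import KScanResult, Parcellation, SimilarityMatrix
from .profiles import ConnectivityProfile, PopulationMap
from .synth import SpeciesSpec, SyntheticDataset

FLOAT_FMT = "%.10g"


def _frame(matrix: np.ndarray, prefix: str) -> pd.DataFrame:
    return pd.DataFrame(
        matrix, columns=[f"{prefix}{j}" for j in range(matrix.shape[1])]
    )


def write_profile(profile: ConnectivityProfile, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _frame(profile.matrix, "t").to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    return path


def read_profile(path, subject_id: str = "", hemisphere: str = "L",
                 normalized: bool = False) -> ConnectivityProfile:
    matrix = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    return ConnectivityProfile(
        matrix=matrix, subject_id=subject_id, hemisphere=hemisphere,
        normalized=normalized,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write one species dataset: per-subject-hemisphere profile TSVs,
    volumes TSV and a ground-truth/spec JSON (enough to reload)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sid, hemi), profile in sorted(dataset.profiles.items()):
        write_profile(profile, out / f"{sid}_{hemi}.tsv")
    dataset.volumes.to_csv(
        out / "volumes.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    spec = dataset.spec
    truth = {
        "name": spec.name,
        "n_subjects": spec.n_subjects,
        "n_seeds": spec.n_seeds,
        "n_targets": spec.n_targets,
        "k_true": spec.k_true,
        "block_assignment": spec.block_assignment.tolist(),
        "cluster_profiles": spec.cluster_profiles.tolist(),
        "asym_effects": spec.asym_effects.tolist(),
        "noise_sd": spec.noise_sd,
        "scaling_exponent": spec.scaling_exponent.tolist(),
        "scaling_intercept": spec.scaling_intercept.tolist(),
        "volume_ai": spec.volume_ai.tolist(),
        "gmv_range": list(spec.gmv_range),
        "volume_noise_sd": spec.volume_noise_sd,
        "subregion_names": list(spec.subregion_names),
        "seed": dataset.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out


def spec_from_dict(payload: dict) -> SpeciesSpec:
    fields = {
        k: payload[k]
        for k in (
            "name", "n_subjects", "n_seeds", "n_targets", "k_true",
            "block_assignment", "cluster_profiles", "asym_effects",
            "noise_sd", "scaling_exponent", "scaling_intercept",
            "volume_ai", "volume_noise_sd",
        )
    }
    fields["gmv_range"] = tuple(payload["gmv_range"])
    fields["subregion_names"] = tuple(payload.get("subregion_names", ()))
    return SpeciesSpec(**fields)


def read_dataset(in_dir) -> SyntheticDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    payload = json.loads((src / "ground_truth.json").read_text())
    spec = spec_from_dict(payload)
    spec.validate()
    profiles = {}
    for path in sorted(src.glob("*_[LR].tsv")):
        sid, hemi = path.stem.rsplit("_", 1)
        profiles[(sid, hemi)] = read_profile(path, subject_id=sid, hemisphere=hemi)
    volumes = pd.read_csv(src / "volumes.tsv", sep="\t")
    gmv = volumes.drop_duplicates("subject")["gmv"].to_numpy()
    truth = {
        "labels": np.asarray(payload["block_assignment"]),
        "k_true": payload["k_true"],
        "asym_effects": np.asarray(payload["asym_effects"]),
        "scaling_exponent": np.asarray(payload["scaling_exponent"]),
        "scaling_intercept": np.asarray(payload["scaling_intercept"]),
        "volume_ai": np.asarray(payload["volume_ai"]),
    }
    return SyntheticDataset(
        spec=spec, profiles=profiles, gmv=gmv, volumes=volumes,
        seed=payload.get("seed", -1), ground_truth=truth,
    )


def write_similarity(sim: SimilarityMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _frame(sim.matrix, "s").to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_similarity(path, level: str = "group") -> SimilarityMatrix:
    matrix = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    matrix = (matrix + matrix.T) / 2.0  # repair round-trip rounding
    np.fill_diagonal(matrix, 1.0)
    return SimilarityMatrix(matrix=np.clip(matrix, -1, 1), level=level)


def write_parcellation(parc: Parcellation, path) -> Path:
    """Two-column TSV (seed_id, label) plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"seed_id": np.arange(parc.labels.size), "label": parc.labels}
    ).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"k": parc.k, **parc.provenance}, indent=1))
    return path


def read_parcellation(path) -> Parcellation:
    frame = pd.read_csv(path, sep="\t")
    labels = frame["label"].to_numpy(dtype=int)
    sidecar = Path(path).with_suffix(".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Parcellation(
        labels=labels, k=int(labels.max()), provenance=provenance
    )


def write_population_map(pop: PopulationMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"target_id": np.arange(pop.values.size), "value": pop.values}
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# 0-based unit indices of the group analysis mask"]
    lines += [str(int(i)) for i in mask]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mask(path) -> np.ndarray:
    values = [
        int(line)
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return np.asarray(values, dtype=int)


def write_scan(result: KScanResult, path) -> Path:
    """(k, score) TSV plus JSON sidecar with the selection outcome."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"k": list(result.scores), "score": list(result.scores.values())}
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "chosen_k": result.chosen_k,
                "tau": result.tau,
                "reached_tau": result.reached_tau,
            },
            indent=1,
        )
    )
    return path
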