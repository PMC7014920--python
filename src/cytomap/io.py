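"""Readers and writers for the pipeline's on-disk formats.

Profiles and feature vectors travel as versioned CSV, section truth and
border reports as JSON, label volumes and probability maps as NIfTI-1,
dendrograms as Newick.  Schema versions are embedded so readers can reject
files written by an incompatible major version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .profiles import GLIProfile, ProfileSequence
from .synthetic import SectionTruth

__all__ = [
    "SCHEMA_VERSION",
    "write_profile_sequence",
    "read_profile_sequence",
    "write_features",
    "read_features",
    "write_truth",
    "read_truth",
    "write_label_volume",
    "read_label_volume",
    "write_probability_map",
    "write_border_result",
]

SCHEMA_VERSION = "1.0"


def _check_version(found: str):
    if found is None:
        raise ValueError("file carries no schema version")
    major = str(found).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(f"unsupported schema major version {found!r}")


def write_profile_sequence(seq: ProfileSequence, path, seed=None):
    """Long-format CSV (traverse_index, depth_bin, gli) plus a JSON sidecar."""
    import pandas as pd

    path = Path(path)
    rows = []
    for i, p in enumerate(seq.profiles):
        for j, v in enumerate(p.values):
            rows.append((i, j, v))
    df = pd.DataFrame(rows, columns=["traverse_index", "depth_bin", "gli"])
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "n_profiles": len(seq),
        "n_depth": seq.profiles[0].n_depth if len(seq) else 0,
        "arc_positions": [float(s) for s in seq.arc_positions],
        "seed": seed if seed is not None else seq.meta.get("seed"),
        "meta": {k: v for k, v in seq.meta.items() if _jsonable(v)},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _jsonable(v):
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_profile_sequence(path) -> ProfileSequence:
    import pandas as pd

    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    _check_version(sidecar.get("schema_version"))
    df = pd.read_csv(path)
    profiles = []
    for i, grp in df.groupby("traverse_index", sort=True):
        vals = grp.sort_values("depth_bin")["gli"].to_numpy()
        profiles.append(GLIProfile(values=vals))
    return ProfileSequence(
        profiles=profiles,
        arc_positions=np.asarray(sidecar["arc_positions"], float),
        meta=dict(sidecar.get("meta", {}), seed=sidecar.get("seed")),
    )


def write_features(features: np.ndarray, path):
    """Feature matrix as CSV with columns f01..f10."""
    import pandas as pd

    X = np.asarray(features, float)
    cols = [f"f{k + 1:02d}" for k in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "traverse_index", np.arange(X.shape[0]))
    df.to_csv(path, index=False, float_format="%.12g")
    Path(str(path) + ".json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "n_features": X.shape[1]}, sort_keys=True)
    )


def read_features(path) -> np.ndarray:
    import pandas as pd

    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        _check_version(json.loads(sidecar_path.read_text()).get("schema_version"))
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("f")]
    return df[cols].to_numpy(float)


def write_truth(truth: SectionTruth, path):
    doc = {
        "schema_version": SCHEMA_VERSION,
        "border_positions": [int(b) for b in truth.border_positions],
        "area_labels": [int(a) for a in truth.area_labels],
        "seed": truth.seed,
        "meta": {k: v for k, v in truth.meta.items() if _jsonable(v)},
    }
    if truth.outer_contour is not None:
        doc["outer_contour"] = np.asarray(truth.outer_contour).tolist()
        doc["inner_contour"] = np.asarray(truth.inner_contour).tolist()
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_truth(path) -> SectionTruth:
    doc = json.loads(Path(path).read_text())
    _check_version(doc.get("schema_version"))
    return SectionTruth(
        border_positions=np.asarray(doc["border_positions"], int),
        area_labels=np.asarray(doc["area_labels"], int),
        outer_contour=np.asarray(doc["outer_contour"]) if "outer_contour" in doc else None,
        inner_contour=np.asarray(doc["inner_contour"]) if "inner_contour" in doc else None,
        seed=doc.get("seed"),
        meta=doc.get("meta", {}),
    )


def write_label_volume(volume, path, affine=None):
    """Write an integer label volume as int16 NIfTI-1."""
    import nibabel as nib

    arr = np.asarray(volume)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label volume must have an integer dtype")
    if arr.ndim != 3:
        raise ValueError("label volume must be 3-D")
    img = nib.Nifti1Image(arr.astype(np.int16), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def read_label_volume(path):
    """Read an int label volume; returns (array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D label volume, got shape {img.shape}")
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise ValueError(f"label volume must be integer-typed, got {dtype}")
    return np.asanyarray(img.dataobj).astype(np.int32), np.asarray(img.affine)


def write_probability_map(pmap, path):
    import nibabel as nib

    img = nib.Nifti1Image(pmap.data.astype(np.float32), pmap.affine)
    img.header["descrip"] = f"area {pmap.area_id} n={pmap.n_subjects}".encode()
    nib.save(img, str(path))


def write_border_result(result, csv_path, json_path):
    """MD/p surfaces as long CSV; accepted borders as JSON."""
    import pandas as pd

    rows = []
    for k, b in enumerate(result.block_sizes):
        ok = ~np.isnan(result.md_surface[k])
        for pos in np.nonzero(ok)[0]:
            rows.append((int(pos), int(b), result.md_surface[k, pos], result.p_surface[k, pos]))
    pd.DataFrame(rows, columns=["position", "block_size", "md", "p"]).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    doc = {
        "schema_version": SCHEMA_VERSION,
        "borders": result.borders,
        "config": {
            "block_sizes": list(result.config.block_sizes),
            "alpha": result.config.alpha,
            "correction": result.config.correction,
            "vote_fraction": result.config.vote_fraction,
            "vote_tolerance": result.config.vote_tolerance,
            "shrinkage": str(result.config.shrinkage),
        },
        "vote_histogram": result.vote_histogram.tolist(),
    }
    Path(json_path).write_text(json.dumps(doc, indent=1, sort_keys=True))
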