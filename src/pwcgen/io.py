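"""Plain-text serialization for every artifact the pipeline produces.

Formats (all round-trip tested):

* demographics — CSV with header ``subject_id,dataset,sex,age``;
* connectomes — either one whitespace-delimited P x P matrix file per
  subject plus a manifest CSV (``subject_id,path``), or a packed
  single-file container (all subjects row-major, one subject per line)
  with a JSON sidecar giving the shape and subject order;
* samples — CSV ``name,role,subject_id``;
* accuracy maps — TSV ``parcel_index,parcel_label,balanced_accuracy``
  plus a JSON sidecar with the (train, eval, mode) metadata;
* Dice profiles — TSV ``threshold,p_tr,p_te,p_com,dsc`` with wmDice in
  the sidecar;
* time series — T x P TSV with a header row of parcel ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ParcelTimeSeries
from .consistency import DiceProfile
from .errors import ConfigurationError
from .pwc import AccuracyMap
from .samples import SampleDefinition

DEMOGRAPHICS_COLUMNS = ["subject_id", "dataset", "sex", "age"]


# -- demographics -----------------------------------------------------------

def write_demographics(demo: pd.DataFrame, path) -> None:
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in demo.columns]
    if missing:
        raise ConfigurationError(f"demographics missing columns {missing}")
    demo[DEMOGRAPHICS_COLUMNS].to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    demo = pd.read_csv(path, dtype={"subject_id": str, "dataset": str, "sex": str})
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in demo.columns]
    if missing:
        raise ConfigurationError(f"demographics file missing columns {missing}")
    bad = set(demo["sex"].unique()) - {"F", "M"}
    if bad:
        raise ConfigurationError(f"sex column must contain F/M only, got {bad}")
    return demo[DEMOGRAPHICS_COLUMNS]


# -- connectomes ------------------------------------------------------------

def write_connectomes_dir(
    connectomes: np.ndarray, subject_ids, out_dir
) -> Path:
    """One matrix file per subject plus a ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, mat in zip(subject_ids, connectomes):
        fname = f"{sid}.txt"
        np.savetxt(out_dir / fname, mat, fmt="%.10g", delimiter="\t")
        rows.append({"subject_id": sid, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_connectomes_dir(manifest_path) -> tuple[np.ndarray, list[str]]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, dtype=str)
    mats, sids = [], []
    for _, row in manifest.iterrows():
        mats.append(np.loadtxt(manifest_path.parent / row["path"]))
        sids.append(row["subject_id"])
    return np.stack(mats), sids


def write_connectomes_packed(
    connectomes: np.ndarray, subject_ids, path
) -> None:
    """All subjects in one text file, one row-major-flattened matrix per line."""
    path = Path(path)
    connectomes = np.asarray(connectomes, dtype=float)
    n, p, _ = connectomes.shape
    np.savetxt(path, connectomes.reshape(n, p * p), fmt="%.10g", delimiter="\t")
    sidecar = {
        "n_subjects": int(n),
        "n_parcels": int(p),
        "subject_ids": list(subject_ids),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_connectomes_packed(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n, p = sidecar["n_subjects"], sidecar["n_parcels"]
    flat = np.loadtxt(path, delimiter="\t", ndmin=2)
    if flat.shape != (n, p * p):
        raise ConfigurationError(
            f"packed file shape {flat.shape} does not match sidecar ({n}, {p * p})"
        )
    return flat.reshape(n, p, p), list(sidecar["subject_ids"])


# -- samples ----------------------------------------------------------------

def write_samples(samples, path) -> None:
    rows = [
        {"name": s.name, "role": s.role, "subject_id": sid}
        for s in samples
        for sid in s.subject_ids
    ]
    pd.DataFrame(rows, columns=["name", "role", "subject_id"]).to_csv(
        path, index=False
    )


def read_samples(path) -> dict[str, SampleDefinition]:
    df = pd.read_csv(path, dtype=str)
    out: dict[str, SampleDefinition] = {}
    for name, group in df.groupby("name", sort=False):
        roles = group["role"].unique()
        if len(roles) != 1:
            raise ConfigurationError(f"sample {name!r} has mixed roles {roles}")
        out[name] = SampleDefinition(
            name=name,
            role=roles[0],
            subject_ids=tuple(group["subject_id"]),
        )
    return out


# -- accuracy maps ----------------------------------------------------------

def write_accuracy_map(
    amap: AccuracyMap, path, parcel_labels=None, extra_meta: dict | None = None
) -> None:
    path = Path(path)
    p = amap.n_parcels
    labels = (
        list(parcel_labels)
        if parcel_labels is not None
        else [f"parcel{i:03d}" for i in range(p)]
    )
    pd.DataFrame(
        {
            "parcel_index": np.arange(p),
            "parcel_label": labels,
            "balanced_accuracy": amap.values,
        }
    ).to_csv(path, sep="\t", index=False)
    meta = {
        "train_sample": amap.train_sample,
        "eval_sample": amap.eval_sample,
        "mode": amap.mode,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_accuracy_map(path) -> AccuracyMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return AccuracyMap(
        df["balanced_accuracy"].to_numpy(),
        train_sample=meta.get("train_sample", ""),
        eval_sample=meta.get("eval_sample", ""),
        mode=meta.get("mode", "within_cv"),
    )


# -- Dice profiles ----------------------------------------------------------

def write_dice_profile(profile: DiceProfile, path) -> None:
    path = Path(path)
    profile.to_frame().to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"wm_dice": profile.wm_dice}, indent=1)
    )


def read_dice_profile(path) -> DiceProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DiceProfile(
        thresholds=df["threshold"].to_numpy(),
        dsc=df["dsc"].to_numpy(),
        p_tr=df["p_tr"].to_numpy(),
        p_te=df["p_te"].to_numpy(),
        p_com=df["p_com"].to_numpy(),
        wm_dice=meta["wm_dice"],
    )


# -- time series ------------------------------------------------------------

def write_timeseries(ts: ParcelTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.parcel_ids)).to_csv(
        path, sep="\t", index=False
    )


def read_timeseries(path) -> ParcelTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ParcelTimeSeries(df.to_numpy(), tuple(df.columns))
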