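"""Text formats: region tables as tab-delimited files with a metadata
header block, normative maps and overlap tables as TSV, sets and results
as JSON, volumes as NIfTI-1."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .changepoint import AbnormalitySet
from .cohort import RegionTable
from .normative import NormativeMap
from .volumetric import ParcellationVolume

__all__ = [
    "read_region_table", "write_region_table",
    "read_normative_map", "write_normative_map",
    "read_abnormal_sets", "write_abnormal_sets",
    "read_resected_sets", "write_resected_sets",
    "read_parcellation", "write_parcellation", "read_mask", "write_mask",
]

_META_COLS = ["age", "sex", "site", "group", "tle_side", "outcome"]


def write_region_table(table: RegionTable, path) -> None:
    """Tab-delimited values with a '#'-prefixed metadata header block."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# modality\t{table.modality}\n")
        for col in _META_COLS:
            vals = "\t".join(str(v) for v in table.metadata[col])
            fh.write(f"# {col}\t{vals}\n")
        table.values.to_csv(fh, sep="\t", index_label="subject_id",
                            float_format="%.17g")


def read_region_table(path) -> RegionTable:
    path = Path(path)
    meta: dict[str, list[str]] = {}
    modality = None
    n_header = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n_header += 1
            parts = line[1:].strip().split("\t")
            key, vals = parts[0], parts[1:]
            if key == "modality":
                modality = vals[0]
            else:
                meta[key] = vals
    if modality is None:
        raise ValueError(f"{path}: missing '# modality' header line")
    for col in _META_COLS:
        if col not in meta:
            raise ValueError(f"{path}: missing metadata column {col!r}")
    values = pd.read_csv(path, sep="\t", comment="#", index_col="subject_id")
    values.index.name = None
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate subject ID {dup!r}")
    bad = values.columns[~values.dtypes.map(
        lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric cells in column(s) "
                         f"{list(bad)} (data begin at line {n_header + 2})")
    mdf = pd.DataFrame(index=values.index)
    for col in _META_COLS:
        if len(meta[col]) != len(values):
            raise ValueError(f"{path}: metadata column {col!r} has "
                             f"{len(meta[col])} entries for {len(values)} subjects")
        mdf[col] = meta[col]
    mdf["age"] = mdf["age"].astype(float)
    mdf["sex"] = mdf["sex"].astype(int)
    mdf["site"] = mdf["site"].astype(int)
    return RegionTable(values, mdf, modality)


def write_normative_map(nmap: NormativeMap, path) -> None:
    df = nmap.to_frame()
    with Path(path).open("w") as fh:
        fh.write(f"# modality\t{nmap.modality}\n")
        fh.write(f"# n_controls\t{nmap.n_controls}\n")
        df.to_csv(fh, sep="\t", index_label="region")


def read_normative_map(path) -> NormativeMap:
    path = Path(path)
    modality, n_controls = None, 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, val = line[1:].strip().split("\t")
            if key == "modality":
                modality = val
            elif key == "n_controls":
                n_controls = int(val)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="region")
    return NormativeMap(list(df.index.astype(str)), df["mu"].to_numpy(),
                        df["sd"].to_numpy(), modality or "gm_volume", n_controls)


def write_abnormal_sets(sets: dict[str, dict[str, AbnormalitySet]], path) -> None:
    """JSON keyed by patient then modality."""
    payload = {
        pid: {
            mod: {"regions": sorted(ab.regions),
                  "threshold_z": ab.threshold_z}
            for mod, ab in by_mod.items()
        }
        for pid, by_mod in sets.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_abnormal_sets(path) -> dict[str, dict[str, AbnormalitySet]]:
    payload = json.loads(Path(path).read_text())
    return {
        pid: {mod: AbnormalitySet(pid, mod, set(d["regions"]), d["threshold_z"])
              for mod, d in by_mod.items()}
        for pid, by_mod in payload.items()
    }


def write_resected_sets(resected: dict[str, set[str]], path) -> None:
    Path(path).write_text(json.dumps(
        {pid: sorted(s) for pid, s in resected.items()}, indent=1, sort_keys=True))


def read_resected_sets(path) -> dict[str, set[str]]:
    return {pid: set(v) for pid, v in json.loads(Path(path).read_text()).items()}


def write_parcellation(parc: ParcellationVolume, labels_path,
                       gm_path=None, wm_path=None) -> None:
    affine = np.diag(list(parc.spacing) + [1.0])
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), affine), str(labels_path))
    if gm_path is not None and parc.gm_mask is not None:
        nib.save(nib.Nifti1Image(parc.gm_mask.astype(np.uint8), affine), str(gm_path))
    if wm_path is not None and parc.wm_mask is not None:
        nib.save(nib.Nifti1Image(parc.wm_mask.astype(np.uint8), affine), str(wm_path))


def read_parcellation(labels_path, gm_path=None, wm_path=None) -> ParcellationVolume:
    img = nib.load(str(labels_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    gm = np.asarray(nib.load(str(gm_path)).dataobj).astype(bool) if gm_path else None
    wm = np.asarray(nib.load(str(wm_path)).dataobj).astype(bool) if wm_path else None
    return ParcellationVolume(np.asarray(img.dataobj).astype(np.int32),
                              spacing, gm, wm)


def write_mask(mask: np.ndarray, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine), str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)
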