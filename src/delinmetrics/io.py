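"""Readers and writers for the on-disk study layout.

A dataset directory holds::

    manifest.yaml            # sets: dimensions, modalities, independence,
                             # optional central/peripheral stimulus labels
    observers.csv            # observer_id, group
    contours.csv             # observer_id, group, set_id, slice_index,
                             # contour_id, point_order, x, y   (one vertex/row)
    sequences.csv            # observer_id, set_id, event_order, slice_index
    images/  masks/          # grayscale rasters

Images and brain masks are 16-bit grayscale PNGs named
``set<id>_slice<idx>_<modality>.png`` / ``set<id>_slice<idx>_mask.png``,
or one NIfTI volume per set per modality (``image_format: nifti`` in
the manifest). Vertex coordinates are written with 17 significant
digits, so ``read_dataset(write_dataset(d))`` reproduces ``d``
bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    Delineation,
    ObserverRecord,
    SliceStack,
    StudyDataset,
    ValidationError,
)

__all__ = ["read_dataset", "write_dataset", "FormatError"]

MANIFEST = "manifest.yaml"


class FormatError(ValueError):
    """The on-disk layout is missing or malformed."""


def _png_name(set_id: str, k: int, suffix: str) -> str:
    return f"set{set_id}_slice{k:03d}_{suffix}.png"


def write_dataset(dataset: StudyDataset, path: str | Path, image_format: str = "png") -> Path:
    """Write a validated dataset to a directory; returns the directory."""
    if image_format not in ("png", "nifti"):
        raise ValueError(f"image_format must be 'png' or 'nifti', got {image_format!r}")
    dataset.validate()
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(exist_ok=True)

    manifest = {
        "image_format": image_format,
        "sets": [
            {
                "set_id": s.set_id,
                "n_slices": s.n_slices,
                "width": s.width,
                "height": s.height,
                "modalities": list(s.modalities),
                "independent_slices": s.independent_slices,
                "slice_location_labels": s.slice_location_labels,
            }
            for s in dataset.stacks
        ],
    }
    (root / MANIFEST).write_text(yaml.safe_dump(manifest, sort_keys=False))

    for s in dataset.stacks:
        if image_format == "png":
            for mod in s.modalities:
                for k, img in enumerate(s.images[mod]):
                    iio.imwrite(
                        root / "images" / _png_name(s.set_id, k, mod),
                        img.astype(np.uint16),
                    )
            for k, m in enumerate(s.brain_masks):
                iio.imwrite(
                    root / "masks" / _png_name(s.set_id, k, "mask"),
                    (m.astype(np.uint16) * 65535),
                )
        else:
            for mod in s.modalities:
                vol = np.stack(s.images[mod], axis=-1).astype(np.uint16)
                nib.save(
                    nib.Nifti1Image(vol, affine=np.eye(4)),
                    root / "images" / f"set{s.set_id}_{mod}.nii",
                )
            mvol = np.stack(s.brain_masks, axis=-1).astype(np.uint8)
            nib.save(
                nib.Nifti1Image(mvol, affine=np.eye(4)),
                root / "masks" / f"set{s.set_id}_mask.nii",
            )

    obs_df = pd.DataFrame(
        [{"observer_id": o.observer_id, "group": o.group} for o in dataset.observers],
        columns=["observer_id", "group"],
    )
    obs_df.to_csv(root / "observers.csv", index=False)

    crows = []
    for o in dataset.observers:
        for ci, d in enumerate(o.delineations):
            for pi, (x, y) in enumerate(d.vertices):
                crows.append(
                    (o.observer_id, o.group, d.set_id, d.slice_index, ci, pi, x, y)
                )
    contours = pd.DataFrame(
        crows,
        columns=[
            "observer_id", "group", "set_id", "slice_index",
            "contour_id", "point_order", "x", "y",
        ],
    )
    contours.to_csv(root / "contours.csv", index=False, float_format="%.17g")

    srows = []
    for o in dataset.observers:
        for set_id, seq in sorted(o.interaction_sequences.items()):
            for ei, k in enumerate(seq):
                srows.append((o.observer_id, set_id, ei, k))
    sequences = pd.DataFrame(
        srows, columns=["observer_id", "set_id", "event_order", "slice_index"]
    )
    sequences.to_csv(root / "sequences.csv", index=False)
    return root


def _read_stack(root: Path, entry: dict, image_format: str) -> SliceStack:
    required = {"set_id", "n_slices", "width", "height", "modalities"}
    missing = required - set(entry)
    if missing:
        raise FormatError(f"manifest set entry missing keys {sorted(missing)}: {entry}")
    set_id = str(entry["set_id"])
    n, w, h = int(entry["n_slices"]), int(entry["width"]), int(entry["height"])
    modalities = [str(m) for m in entry["modalities"]]
    images: dict[str, list[np.ndarray]] = {}
    masks: list[np.ndarray] = []
    if image_format == "png":
        for mod in modalities:
            imgs = []
            for k in range(n):
                p = root / "images" / _png_name(set_id, k, mod)
                if not p.exists():
                    raise FormatError(f"missing image raster: {p}")
                imgs.append(np.asarray(iio.imread(p), dtype=np.uint16))
            images[mod] = imgs
        for k in range(n):
            p = root / "masks" / _png_name(set_id, k, "mask")
            if not p.exists():
                raise FormatError(f"missing brain mask: {p}")
            masks.append(np.asarray(iio.imread(p)) > 0)
    else:
        for mod in modalities:
            p = root / "images" / f"set{set_id}_{mod}.nii"
            if not p.exists():
                raise FormatError(f"missing image volume: {p}")
            vol = np.asarray(nib.load(p).dataobj).astype(np.uint16)
            images[mod] = [vol[:, :, k] for k in range(vol.shape[2])]
        p = root / "masks" / f"set{set_id}_mask.nii"
        if not p.exists():
            raise FormatError(f"missing mask volume: {p}")
        mvol = np.asarray(nib.load(p).dataobj)
        masks = [mvol[:, :, k] > 0 for k in range(mvol.shape[2])]
    labels = entry.get("slice_location_labels")
    return SliceStack(
        set_id=set_id,
        width=w,
        height=h,
        images=images,
        brain_masks=masks,
        independent_slices=bool(entry.get("independent_slices", False)),
        slice_location_labels=list(labels) if labels is not None else None,
    )


def read_dataset(path: str | Path) -> StudyDataset:
    """Read and fully validate a dataset directory written by
    :func:`write_dataset` (or assembled by hand in the same layout)."""
    root = Path(path)
    mpath = root / MANIFEST
    if not mpath.exists():
        raise FormatError(f"no {MANIFEST} in {root}")
    manifest = yaml.safe_load(mpath.read_text())
    if not isinstance(manifest, dict) or "sets" not in manifest:
        raise FormatError(f"{mpath}: manifest must be a mapping with a 'sets' list")
    image_format = manifest.get("image_format", "png")
    stacks = [_read_stack(root, e, image_format) for e in manifest["sets"]]

    opath = root / "observers.csv"
    if not opath.exists():
        raise FormatError(f"missing {opath}")
    obs_df = pd.read_csv(opath, dtype=str)
    observers = {
        row.observer_id: ObserverRecord(observer_id=row.observer_id, group=row.group)
        for row in obs_df.itertuples()
    }

    cpath = root / "contours.csv"
    if cpath.exists() and cpath.stat().st_size > 0:
        cdf = pd.read_csv(
            cpath,
            dtype={"observer_id": str, "group": str, "set_id": str},
            float_precision="round_trip",
        )
        if len(cdf):
            # contour_id indexes each observer's delineation list, so
            # grouping by it restores the original list order exactly
            for (oid, ci), g in cdf.groupby(["observer_id", "contour_id"], sort=True):
                if oid not in observers:
                    raise ValidationError(
                        f"contours.csv references unknown observer {oid!r}"
                    )
                group = g["group"].iloc[0]
                set_id = g["set_id"].iloc[0]
                k = g["slice_index"].iloc[0]
                if g["set_id"].nunique() > 1 or g["slice_index"].nunique() > 1:
                    raise ValidationError(
                        f"contours.csv: contour {ci} of observer {oid!r} spans "
                        f"multiple sets or slices"
                    )
                if observers[oid].group != group:
                    raise ValidationError(
                        f"contours.csv group {group!r} for observer {oid!r} "
                        f"contradicts observers.csv ({observers[oid].group!r})"
                    )
                g = g.sort_values("point_order")
                observers[oid].delineations.append(
                    Delineation(
                        observer_id=oid,
                        set_id=set_id,
                        slice_index=int(k),
                        vertices=g[["x", "y"]].to_numpy(dtype=float),
                    )
                )

    spath = root / "sequences.csv"
    if spath.exists() and spath.stat().st_size > 0:
        sdf = pd.read_csv(spath, dtype={"observer_id": str, "set_id": str})
        if len(sdf):
            for (oid, set_id), g in sdf.groupby(["observer_id", "set_id"], sort=True):
                if oid not in observers:
                    raise ValidationError(
                        f"sequences.csv references unknown observer {oid!r}"
                    )
                g = g.sort_values("event_order")
                observers[oid].interaction_sequences[set_id] = [
                    int(v) for v in g["slice_index"]
                ]

    dataset = StudyDataset(stacks=stacks, observers=list(observers.values()))
    dataset.validate()
    return dataset
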