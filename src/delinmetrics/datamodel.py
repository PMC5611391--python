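"""Core data model for multi-observer tumor delineation studies.

A study consists of one or more image *sets* (stacks of grayscale MR
slices with brain masks), and a panel of *observers* (experts and
novices) who each draw stylus polylines ("delineations") around tissue
they judge tumorous, and whose slice-by-slice navigation is recorded as
an ordered interaction sequence.

Conventions
-----------
* Coordinates are 0-based pixel indices with ``x`` = column and ``y`` =
  row, origin at the top-left of the raster; a pixel's center is at
  integer coordinates ``(x, y)``.
* Binary masks are boolean ``(height, width)`` numpy arrays.
* Whole-brain stacks are ordered superior to inferior; an
  *independent* set holds unrelated single slices, one per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

#: Boolean raster, shape (height, width). True marks the region.
BinaryMask = npt.NDArray[np.bool_]

VALID_GROUPS = ("expert", "novice")
VALID_MODALITIES = ("T1", "T2")
VALID_LOCATIONS = ("central", "peripheral")


class ValidationError(ValueError):
    """A record violates a structural invariant of the study data model."""


def mask_area(mask: BinaryMask) -> int:
    """Number of true pixels in a binary mask."""
    return int(np.count_nonzero(mask))


@dataclass
class SliceStack:
    """One image set: a stack of co-registered grayscale slices.

    Parameters
    ----------
    set_id : str
        Identifier of the set (e.g. ``"2"``).
    images : dict[str, list[numpy.ndarray]]
        Per-modality list of per-slice uint16 grayscale rasters, keyed
        by modality name (``"T1"``, ``"T2"``). All modalities present
        must cover every slice.
    brain_masks : list[BinaryMask]
        Per-slice binary rasters, true inside the brain.
    independent_slices : bool
        True when each slice comes from a different patient (a
        "single-slice" set); such sets carry stimulus-level
        central/peripheral labels instead of a slice ordering.
    slice_location_labels : list[str] | None
        Optional per-slice label in {"central", "peripheral"}; stimulus
        metadata, meaningful for independent sets.
    """

    set_id: str
    width: int
    height: int
    images: dict[str, list[np.ndarray]]
    brain_masks: list[BinaryMask]
    independent_slices: bool = False
    slice_location_labels: list[str] | None = None

    @property
    def n_slices(self) -> int:
        return len(self.brain_masks)

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(sorted(self.images))

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValidationError(f"set {self.set_id!r}: needs at least one slice")
        for mod, imgs in self.images.items():
            if mod not in VALID_MODALITIES:
                raise ValidationError(f"set {self.set_id!r}: unknown modality {mod!r}")
            if len(imgs) != self.n_slices:
                raise ValidationError(
                    f"set {self.set_id!r}: modality {mod} has {len(imgs)} images "
                    f"for {self.n_slices} slices"
                )
            for k, img in enumerate(imgs):
                if img.shape != (self.height, self.width):
                    raise ValidationError(
                        f"set {self.set_id!r} slice {k} ({mod}): shape {img.shape} "
                        f"!= ({self.height}, {self.width})"
                    )
        for k, m in enumerate(self.brain_masks):
            if m.shape != (self.height, self.width):
                raise ValidationError(
                    f"set {self.set_id!r} brain mask {k}: shape {m.shape} "
                    f"!= ({self.height}, {self.width})"
                )
        if self.slice_location_labels is not None:
            if len(self.slice_location_labels) != self.n_slices:
                raise ValidationError(
                    f"set {self.set_id!r}: {len(self.slice_location_labels)} location "
                    f"labels for {self.n_slices} slices"
                )
            bad = set(self.slice_location_labels) - set(VALID_LOCATIONS)
            if bad:
                raise ValidationError(f"set {self.set_id!r}: bad location labels {bad}")


@dataclass
class Delineation:
    """One observer's polyline on one slice.

    ``vertices`` is an ordered ``(n, 2)`` float array of ``(x, y)``
    pixel coordinates, ``n >= 3``. The polyline is treated as closed
    (last vertex joined back to the first) whenever a region is needed.
    A slice may carry several delineations from the same observer;
    their rasterized regions are merged by union.
    """

    observer_id: str
    set_id: str
    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError(
                f"delineation {self.observer_id}/{self.set_id}/{self.slice_index}: "
                f"vertices must be an (n, 2) array"
            )
        if len(self.vertices) < 3:
            raise ValidationError(
                f"delineation {self.observer_id}/{self.set_id}/{self.slice_index}: "
                f"needs >= 3 vertices, got {len(self.vertices)}"
            )


@dataclass
class ObserverRecord:
    """All data contributed by one observer.

    ``interaction_sequences`` maps set_id to the ordered list of slice
    indices the observer visited while inspecting that set (recorded
    for whole-brain sets only).
    """

    observer_id: str
    group: str
    delineations: list[Delineation] = field(default_factory=list)
    interaction_sequences: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"observer {self.observer_id!r}: group must be one of "
                f"{VALID_GROUPS}, got {self.group!r}"
            )


@dataclass
class StudyDataset:
    """All observers x sets x slices of one study."""

    stacks: list[SliceStack]
    observers: list[ObserverRecord]

    def stack(self, set_id: str) -> SliceStack:
        for s in self.stacks:
            if s.set_id == set_id:
                return s
        raise KeyError(f"no set {set_id!r} in dataset")

    def observer(self, observer_id: str) -> ObserverRecord:
        for o in self.observers:
            if o.observer_id == observer_id:
                return o
        raise KeyError(f"no observer {observer_id!r} in dataset")

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.stacks]

    def observers_in_group(self, group: str) -> list[ObserverRecord]:
        return [o for o in self.observers if o.group == group]

    def validate(self) -> None:
        """Check every cross-referencing invariant; raise on the first violation."""
        ids = [s.set_id for s in self.stacks]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate set ids: {ids}")
        for s in self.stacks:
            s.validate()
        oids = [o.observer_id for o in self.observers]
        if len(set(oids)) != len(oids):
            raise ValidationError(f"duplicate observer ids: {oids}")
        by_id = {s.set_id: s for s in self.stacks}
        for obs in self.observers:
            for d in obs.delineations:
                if d.observer_id != obs.observer_id:
                    raise ValidationError(
                        f"delineation owner {d.observer_id!r} filed under "
                        f"observer {obs.observer_id!r}"
                    )
                stack = by_id.get(d.set_id)
                if stack is None:
                    raise ValidationError(
                        f"observer {obs.observer_id!r}: delineation references "
                        f"unknown set {d.set_id!r}"
                    )
                if not 0 <= d.slice_index < stack.n_slices:
                    raise ValidationError(
                        f"observer {obs.observer_id!r}, set {d.set_id!r}: "
                        f"slice_index {d.slice_index} out of range "
                        f"[0, {stack.n_slices})"
                    )
                x, y = d.vertices[:, 0], d.vertices[:, 1]
                if (x < 0).any() or (x >= stack.width).any() or (y < 0).any() or (
                    y >= stack.height
                ).any():
                    raise ValidationError(
                        f"observer {obs.observer_id!r}, set {d.set_id!r}, slice "
                        f"{d.slice_index}: vertex outside "
                        f"[0, {stack.width}) x [0, {stack.height})"
                    )
            for set_id, seq in obs.interaction_sequences.items():
                stack = by_id.get(set_id)
                if stack is None:
                    raise ValidationError(
                        f"observer {obs.observer_id!r}: sequence references "
                        f"unknown set {set_id!r}"
                    )
                if any(not 0 <= i < stack.n_slices for i in seq):
                    raise ValidationError(
                        f"observer {obs.observer_id!r}, set {set_id!r}: sequence "
                        f"visits a slice outside [0, {stack.n_slices})"
                    )
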