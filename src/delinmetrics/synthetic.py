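"""Synthetic delineation-study generator.

Real delineation studies rarely share their raw data (participant
consent), so every downstream measure here is exercised against a
generated study with the same statistical structure:

* an **ellipsoidal tumor phantom** inside an elliptical brain on a
  stack of axial grayscale slices, with tumor contrast fading toward
  the peripheral slices of the lesion (where real margins are faint),
  plus a bright skull ring outside the brain mask;
* an **observer model** with two expertise groups. Each observer
  detects the tumor on a given slice with a probability that decays
  with distance from the lesion's central slice (floored at
  ``detect_floor``), and draws the true contour resampled to ~64
  vertices, radially scaled by ``area_bias`` and perturbed by smooth
  angular Gaussian noise of sd ``jitter_sd`` pixels. Experts get
  smaller jitter and a higher detection floor than novices;
* **inspection sequences**: a superior-to-inferior sweep with
  Poisson-distributed local back-steps.

Everything is reproducible from a single seed; per-observer sub-seeds
are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

from .datamodel import Delineation, ObserverRecord, SliceStack, StudyDataset

__all__ = [
    "PhantomParams",
    "GroupParams",
    "GroundTruth",
    "EXPERT_DEFAULTS",
    "NOVICE_DEFAULTS",
    "generate_phantom",
    "simulate_observer",
    "simulate_sequence",
    "generate_study",
    "default_phantoms",
]


@dataclass
class PhantomParams:
    """Geometry and intensity of one whole-brain phantom.

    Lengths are pixels; the slice axis is in slice units. The default
    raster is 512 x 512 over 31 axial slices, matching a typical
    whole-brain stimulus. ``tumor_contrast`` is the intensity offset of
    tumor over brain tissue at the lesion's central slice; it decays by
    ``peripheral_contrast_decay`` per slice of distance from that
    slice, so peripheral cross-sections are fainter. Intensities are
    uint16.
    """

    n_slices: int = 31
    width: int = 512
    height: int = 512
    brain_ellipse: tuple[float, float] = (215.0, 230.0)  # semi-axes (x, y)
    tumor_center: tuple[int, int, int] = (300, 230, 15)  # (x, y, slice)
    tumor_semi_axes: tuple[float, float, float] = (40.0, 30.0, 5.0)
    tumor_contrast: float = 8000.0
    noise_sd: float = 800.0
    peripheral_contrast_decay: float = 0.85
    modalities: tuple[str, ...] = ("T1",)

    def __post_init__(self) -> None:
        if not 0 < self.peripheral_contrast_decay <= 1:
            raise ValueError(
                f"peripheral_contrast_decay must be in (0, 1], got "
                f"{self.peripheral_contrast_decay}"
            )
        cx, cy, _ = self.tumor_center
        a, b, _ = self.tumor_semi_axes
        ax, ay = self.brain_ellipse
        bx, by = self.width / 2.0, self.height / 2.0
        # conservative containment: bounding box of the tumor inside the brain
        if ((abs(cx - bx) + a) / ax) ** 2 + ((abs(cy - by) + b) / ay) ** 2 > 1.0:
            raise ValueError("tumor ellipsoid does not fit inside the brain ellipse")


@dataclass
class GroupParams:
    """Behavioral parameters of one expertise group.

    jitter_sd : pixels of smooth radial boundary perturbation.
    detect_halfwidth : slices at which the detection curve has fallen
        halfway to the floor.
    detect_floor : minimum detection probability on any tumor slice.
    area_bias : multiplicative factor on contour radius (1 = unbiased;
        area scales with its square).
    revisit_rate : expected local back-steps per slice while paging
        through a stack.
    """

    jitter_sd: float = 4.0
    detect_halfwidth: float = 4.0
    detect_floor: float = 0.7
    area_bias: float = 1.0
    revisit_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if not 0 <= self.detect_floor <= 1:
            raise ValueError(f"detect_floor must be in [0, 1], got {self.detect_floor}")
        if self.area_bias <= 0:
            raise ValueError(f"area_bias must be > 0, got {self.area_bias}")
        if self.detect_halfwidth <= 0:
            raise ValueError(
                f"detect_halfwidth must be > 0, got {self.detect_halfwidth}"
            )
        if self.revisit_rate < 0:
            raise ValueError(f"revisit_rate must be >= 0, got {self.revisit_rate}")


#: Experts draw tighter, more consistent boundaries and keep detecting
#: tumor tissue on faint peripheral slices; novices jitter more, draw
#: slightly larger regions, and miss faint cross-sections more often.
EXPERT_DEFAULTS = GroupParams(
    jitter_sd=3.0, detect_halfwidth=4.0, detect_floor=0.9, area_bias=0.95,
    revisit_rate=1.0,
)
NOVICE_DEFAULTS = GroupParams(
    jitter_sd=6.0, detect_halfwidth=4.0, detect_floor=0.5, area_bias=1.15,
    revisit_rate=1.0,
)


@dataclass
class GroundTruth:
    """True per-slice tumor masks of one set.

    For a whole-brain set the lesion is centered on ``center_slice``
    and a slice's distance is ``|k - center_slice|``. For an
    independent single-slice set each slice came from a different
    phantom; ``slice_distances`` stores each slice's distance from its
    own lesion center (0 for central stimuli).
    """

    set_id: str
    masks: list[np.ndarray]
    center_slice: int | None = None
    slice_distances: list[float] | None = None

    def distance(self, slice_index: int) -> float:
        if self.slice_distances is not None:
            return self.slice_distances[slice_index]
        if self.center_slice is None:
            raise ValueError(f"ground truth for set {self.set_id!r} has no geometry")
        return abs(slice_index - self.center_slice)

    @property
    def tumor_slices(self) -> list[int]:
        return [k for k, m in enumerate(self.masks) if m.any()]


def _tumor_cross_section(
    params: PhantomParams, slice_index: int, xx: np.ndarray, yy: np.ndarray
) -> np.ndarray:
    cx, cy, cz = params.tumor_center
    a, b, c = params.tumor_semi_axes
    dz2 = ((slice_index - cz) / c) ** 2
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + dz2 <= 1.0


def generate_phantom(
    params: PhantomParams, seed: int, set_id: str = "phantom"
) -> tuple[SliceStack, GroundTruth]:
    """Generate one whole-brain slice stack and its ground truth.

    Each slice is a smooth brain background (low-frequency intensity
    variation inside an elliptical brain), a bright skull ring outside
    the brain mask, the tumor ellipsoid's cross-section at elevated
    intensity (fading toward peripheral slices), and Gaussian noise;
    quantized to uint16. The brain mask is the brain ellipse.
    """
    rng = np.random.default_rng(seed)
    w, h = params.width, params.height
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    bx, by = w / 2.0, h / 2.0
    ax, ay = params.brain_ellipse
    r2 = ((xx - bx) / ax) ** 2 + ((yy - by) / ay) ** 2
    brain = r2 <= 1.0
    skull = (r2 > 1.0) & (r2 <= 1.12**2)

    # smooth anatomical-looking background, fixed per phantom
    ph = rng.uniform(0, 2 * np.pi, size=4)
    texture = (
        np.cos(2 * np.pi * xx / w * 1.7 + ph[0]) * np.cos(2 * np.pi * yy / h * 1.3 + ph[1])
        + 0.6 * np.cos(2 * np.pi * xx / w * 3.1 + ph[2]) * np.cos(2 * np.pi * yy / h * 2.6 + ph[3])
    )

    base = {"T1": 20000.0, "T2": 15000.0}
    contrast_gain = {"T1": 1.0, "T2": 1.25}
    cz = params.tumor_center[2]

    images: dict[str, list[np.ndarray]] = {m: [] for m in params.modalities}
    masks = []
    truth = []
    for k in range(params.n_slices):
        tumor = _tumor_cross_section(params, k, xx, yy)
        truth.append(tumor)
        decay = params.peripheral_contrast_decay ** abs(k - cz)
        for mod in params.modalities:
            img = np.zeros((h, w), dtype=float)
            img[brain] = base[mod] + 1500.0 * texture[brain]
            img[skull] = 30000.0
            img[tumor] += contrast_gain[mod] * params.tumor_contrast * decay
            if params.noise_sd > 0:
                img += rng.normal(0.0, params.noise_sd, size=img.shape)
            images[mod].append(np.clip(np.rint(img), 0, 65535).astype(np.uint16))
        masks.append(brain.copy())

    stack = SliceStack(
        set_id=set_id,
        width=w,
        height=h,
        images=images,
        brain_masks=masks,
        independent_slices=False,
    )
    gt = GroundTruth(set_id=set_id, masks=truth, center_slice=cz)
    return stack, gt


def _detection_probability(distance: float, gp: GroupParams) -> float:
    """detect_floor + (1 - floor) * logistic fall-off; exactly 1 at the
    lesion's central slice, halfway to the floor at detect_halfwidth."""
    h = gp.detect_halfwidth
    tau = h / 4.0
    g = _sigmoid((h - distance) / tau) / _sigmoid(h / tau)
    return gp.detect_floor + (1.0 - gp.detect_floor) * min(1.0, g)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n vertices uniformly by arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _smooth_circular_noise(n: int, rng: np.random.Generator, sigma: float = 3.0) -> np.ndarray:
    """Unit-variance smooth noise on a circle of n samples."""
    white = rng.standard_normal(n)
    smooth = ndimage.gaussian_filter1d(white, sigma=sigma, mode="wrap")
    impulse = np.zeros(n)
    impulse[0] = 1.0
    kernel = ndimage.gaussian_filter1d(impulse, sigma=sigma, mode="wrap")
    return smooth / np.sqrt((kernel**2).sum())


def _true_contour(mask: np.ndarray) -> np.ndarray | None:
    """Sub-pixel contour of a binary mask as (x, y) points, longest first."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    longest = max(contours, key=len)
    return longest[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding


def _draw_contour(
    mask: np.ndarray,
    gp: GroupParams,
    rng: np.random.Generator,
    width: int,
    height: int,
    n_vertices: int = 64,
) -> np.ndarray | None:
    """One simulated polyline around a true mask: resampled true contour,
    radius scaled by area_bias, perturbed by smooth radial noise."""
    contour = _true_contour(mask)
    if contour is None or len(contour) < 4:
        return None
    pts = _resample_closed(contour, n_vertices)
    cy, cx = ndimage.center_of_mass(mask)
    center = np.array([cx, cy])
    radial = pts - center
    r = np.linalg.norm(radial, axis=1)
    r_safe = np.where(r == 0, 1.0, r)
    unit = radial / r_safe[:, None]
    new_r = gp.area_bias * r
    if gp.jitter_sd > 0:
        new_r = new_r + gp.jitter_sd * _smooth_circular_noise(n_vertices, rng)
    new_r = np.maximum(new_r, 0.5)
    out = center + unit * new_r[:, None]
    out[:, 0] = np.clip(out[:, 0], 0, width - 1)
    out[:, 1] = np.clip(out[:, 1], 0, height - 1)
    return out


def simulate_observer(
    gt: GroundTruth,
    group: str,
    gp: GroupParams,
    seed: int,
    width: int,
    height: int,
    observer_id: str | None = None,
) -> ObserverRecord:
    """Simulate one observer's delineations of one set.

    Each tumor-bearing slice is delineated with the group's detection
    probability at that slice's distance from the lesion center; drawn
    boundaries are noisy, possibly bias-scaled copies of the true
    contour. The returned record holds no interaction sequences; those
    are attached by :func:`generate_study`.
    """
    rng = np.random.default_rng(seed)
    observer_id = observer_id or f"{group}_{seed}"
    delins = []
    for k in gt.tumor_slices:
        p = _detection_probability(gt.distance(k), gp)
        if rng.random() >= p:
            continue
        verts = _draw_contour(gt.masks[k], gp, rng, width, height)
        if verts is None:
            continue
        delins.append(
            Delineation(
                observer_id=observer_id,
                set_id=gt.set_id,
                slice_index=k,
                vertices=verts,
            )
        )
    return ObserverRecord(observer_id=observer_id, group=group, delineations=delins)


def simulate_sequence(n_slices: int, gp: GroupParams, seed: int) -> list[int]:
    """One inspection sequence: a superior-to-inferior sweep 0..n-1 with
    Poisson(revisit_rate) local back-steps (step back one slice and
    return) inserted after each visited slice."""
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    rng = np.random.default_rng(seed)
    seq = []
    for k in range(n_slices):
        seq.append(k)
        if k > 0 and gp.revisit_rate > 0:
            for _ in range(rng.poisson(gp.revisit_rate)):
                seq.extend([k - 1, k])
    return seq


def default_phantoms(
    width: int = 512, height: int = 512, n_slices: int = 31
) -> list[PhantomParams]:
    """Three whole-brain phantoms with distinct lesion geometry, mirroring
    a study design of one T1-only set and two dual-modality (T1+T2) sets."""
    s = n_slices // 2
    scale = width / 512.0
    return [
        PhantomParams(
            n_slices=n_slices, width=width, height=height,
            tumor_center=(int(300 * scale), int(230 * scale), s),
            tumor_semi_axes=(40 * scale, 30 * scale, max(2.0, n_slices * 5 / 31)),
            modalities=("T1",),
        ),
        PhantomParams(
            n_slices=n_slices, width=width, height=height,
            tumor_center=(int(210 * scale), int(300 * scale), s - 1),
            tumor_semi_axes=(36 * scale, 42 * scale, max(2.0, n_slices * 6 / 31)),
            modalities=("T1", "T2"),
        ),
        PhantomParams(
            n_slices=n_slices, width=width, height=height,
            tumor_center=(int(256 * scale), int(170 * scale), s + 1),
            tumor_semi_axes=(28 * scale, 24 * scale, max(2.0, n_slices * 4 / 31)),
            tumor_contrast=6000.0,
            modalities=("T1", "T2"),
        ),
    ]


def _independent_set(
    base: PhantomParams,
    rng_seed: int,
    n_central: int = 8,
    n_peripheral: int = 8,
) -> tuple[SliceStack, GroundTruth]:
    """Single-slice set: one slice from each of 16 distinct phantoms,
    half taken at the lesion's central slice, half at a peripheral one."""
    rng = np.random.default_rng(rng_seed)
    images: dict[str, list[np.ndarray]] = {m: [] for m in ("T1", "T2")}
    brain_masks, truth_masks, distances, labels = [], [], [], []
    n_total = n_central + n_peripheral
    for i in range(n_total):
        peripheral = i >= n_central
        a, b, c = base.tumor_semi_axes
        jitter = rng.uniform(0.85, 1.15, size=3)
        angle = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 40 * base.width / 512)
        cx = int(base.width / 2 + rad * np.cos(angle))
        cy = int(base.height / 2 + rad * np.sin(angle))
        params = replace(
            base,
            tumor_center=(cx, cy, base.n_slices // 2),
            tumor_semi_axes=(a * jitter[0], b * jitter[1], c * jitter[2]),
            modalities=("T1", "T2"),
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        stack, gt = generate_phantom(params, sub_seed, set_id=f"1.{i}")
        cz = params.tumor_center[2]
        offset = max(1, int(round(0.7 * params.tumor_semi_axes[2]))) if peripheral else 0
        k = cz + offset
        for m in ("T1", "T2"):
            images[m].append(stack.images[m][k])
        brain_masks.append(stack.brain_masks[k])
        truth_masks.append(gt.masks[k])
        distances.append(float(offset))
        labels.append("peripheral" if peripheral else "central")
    stack = SliceStack(
        set_id="1",
        width=base.width,
        height=base.height,
        images=images,
        brain_masks=brain_masks,
        independent_slices=True,
        slice_location_labels=labels,
    )
    gt = GroundTruth(set_id="1", masks=truth_masks, slice_distances=distances)
    return stack, gt


@dataclass
class SyntheticStudy:
    """A generated dataset together with its ground truth."""

    dataset: StudyDataset
    ground_truths: dict[str, GroundTruth] = field(default_factory=dict)


def generate_study(
    phantoms: list[PhantomParams] | None = None,
    expert_gp: GroupParams = EXPERT_DEFAULTS,
    novice_gp: GroupParams = NOVICE_DEFAULTS,
    n_experts: int = 8,
    n_novices: int = 12,
    seed: int = 0,
    include_independent_set: bool = True,
) -> SyntheticStudy:
    """Compose a full synthetic study.

    Whole-brain sets "2", "3", ... come from ``phantoms`` (three
    default phantoms when omitted); set "1" is an independent
    single-slice set of 16 stimuli from 16 distinct phantoms, 8
    central and 8 peripheral, included by default. Observers are
    simulated per set with deterministically spawned sub-seeds, and
    each gets an inspection sequence per whole-brain set.
    """
    if n_experts < 1 or n_novices < 1:
        raise ValueError("need at least one observer per group")
    phantoms = phantoms if phantoms is not None else default_phantoms()
    root = np.random.SeedSequence(seed)
    stack_seeds, obs_seeds = root.spawn(2)

    stacks: list[SliceStack] = []
    truths: dict[str, GroundTruth] = {}
    stack_children = stack_seeds.spawn(len(phantoms) + 1)
    if include_independent_set:
        stack, gt = _independent_set(
            replace(phantoms[0], modalities=("T1", "T2")),
            int(stack_children[0].generate_state(1)[0] % (2**31 - 1)),
        )
        stacks.append(stack)
        truths["1"] = gt
    for i, params in enumerate(phantoms):
        set_id = str(i + 2)
        sub = int(stack_children[i + 1].generate_state(1)[0] % (2**31 - 1))
        stack, gt = generate_phantom(params, sub, set_id=set_id)
        stacks.append(stack)
        truths[set_id] = gt

    groups = [("expert", expert_gp)] * n_experts + [("novice", novice_gp)] * n_novices
    observers = []
    obs_children = obs_seeds.spawn(len(groups))
    counters = {"expert": 0, "novice": 0}
    for (group, gp), child in zip(groups, obs_children):
        counters[group] += 1
        oid = f"{group[0].upper()}{counters[group]:02d}"
        per_set = child.spawn(2 * len(stacks))
        delins = []
        sequences: dict[str, list[int]] = {}
        for j, stack in enumerate(stacks):
            s_del = int(per_set[2 * j].generate_state(1)[0] % (2**31 - 1))
            s_seq = int(per_set[2 * j + 1].generate_state(1)[0] % (2**31 - 1))
            rec = simulate_observer(
                truths[stack.set_id], group, gp, s_del, stack.width, stack.height,
                observer_id=oid,
            )
            delins.extend(rec.delineations)
            if not stack.independent_slices:
                sequences[stack.set_id] = simulate_sequence(stack.n_slices, gp, s_seq)
        observers.append(
            ObserverRecord(
                observer_id=oid,
                group=group,
                delineations=delins,
                interaction_sequences=sequences,
            )
        )
    dataset = StudyDataset(stacks=stacks, observers=observers)
    dataset.validate()
    return SyntheticStudy(dataset=dataset, ground_truths=truths)
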