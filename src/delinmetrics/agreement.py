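"""Delineation agreement measures.

Implements the quantitative measures of a multi-observer delineation
study:

* **GTV** (gross tumor volume): total delineated pixels over a whole
  brain stack.
* **GTA** (gross tumor area): mean delineated pixels per delineated
  slice, used for independent single-slice sets.
* **Slices delineated**: number of slices bearing at least one boundary.
* **Pairwise concordance rate**: overlap between two observers'
  delineated regions on one slice, 0% (disjoint) to 100% (identical).
  The default formula is the Jaccard index, ``100 * |A∩B| / |A∪B|``;
  the Dice coefficient ``100 * 2|A∩B| / (|A|+|B|)`` is available via
  configuration. Both honor the 0/100% anchors.
* **Central/peripheral classification**: within a tumor's slice
  extent, the ``central_k`` slices most observers delineated are
  "central", the remainder "peripheral" (where the tumor margin is
  faint).
* **Per-observer agreement**: each observer's concordance against all
  same-group peers, averaged over peers then over slices, separately
  at central and peripheral locations.

Undefined cells are reported as NaN, never silently as zero: a
slice where *neither* pair member delineated carries no information
(0/0) and is excluded; a slice where exactly *one* member delineated
scores 0% — disagreement about tumor presence is disagreement.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import BinaryMask, ObserverRecord, StudyDataset, mask_area
from .raster import observer_slice_mask

__all__ = [
    "AgreementConfig",
    "AgreementResult",
    "pairwise_concordance",
    "gross_tumor_volume",
    "gross_tumor_area",
    "slices_delineated",
    "classify_central_peripheral",
    "observer_set_agreement",
    "set_agreement",
    "summary_tables",
    "MaskCache",
]

logger = logging.getLogger(__name__)

FORMULAS = ("jaccard", "dice")


@dataclass
class AgreementConfig:
    """Configuration of the agreement analysis.

    formula : "jaccard" (default) or "dice".
    central_k : number of slices labelled central (default 5).
    """

    formula: str = "jaccard"
    central_k: int = 5

    def __post_init__(self) -> None:
        if self.formula not in FORMULAS:
            raise ValueError(f"formula must be one of {FORMULAS}, got {self.formula!r}")
        if self.central_k < 1:
            raise ValueError(f"central_k must be >= 1, got {self.central_k}")


@dataclass
class AgreementResult:
    """Per-observer per-set agreement with the full audit trail.

    ``table`` has one row per observer with mean concordance (percent)
    at central and peripheral locations; ``pairwise`` retains every
    (slice, observer, peer) concordance value for audit.
    """

    set_id: str
    table: pd.DataFrame
    pairwise: pd.DataFrame
    slice_labels: dict[int, str]
    warnings: list[str] = field(default_factory=list)


class MaskCache:
    """Lazy cache of per-(observer, set, slice) union masks.

    Rasterization dominates the cost of the agreement analysis; every
    measure below funnels through this cache so each mask is computed
    once per run.
    """

    def __init__(self, dataset: StudyDataset, mode: str = "filled") -> None:
        self.dataset = dataset
        self.mode = mode
        self._cache: dict[tuple[str, str, int], BinaryMask] = {}

    def mask(self, observer_id: str, set_id: str, slice_index: int) -> BinaryMask:
        key = (observer_id, set_id, slice_index)
        if key not in self._cache:
            stack = self.dataset.stack(set_id)
            obs = self.dataset.observer(observer_id)
            self._cache[key] = observer_slice_mask(
                obs, set_id, slice_index, stack.width, stack.height, self.mode
            )
        return self._cache[key]


def pairwise_concordance(
    mask_a: BinaryMask, mask_b: BinaryMask, formula: str = "jaccard"
) -> float:
    """Concordance rate (percent) between two delineation masks.

    Jaccard: ``100 * |A∩B| / |A∪B|``; Dice: ``100 * 2|A∩B| / (|A|+|B|)``.
    Symmetric in its arguments. Returns NaN when both masks are empty
    (0/0 is undefined, not agreement).
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    inter = int(np.count_nonzero(mask_a & mask_b))
    na, nb = mask_area(mask_a), mask_area(mask_b)
    if na == 0 and nb == 0:
        return math.nan
    if formula == "jaccard":
        union = na + nb - inter
        return 100.0 * inter / union
    return 100.0 * 2 * inter / (na + nb)


def _delineated_slices(observer: ObserverRecord, set_id: str) -> set[int]:
    return {d.slice_index for d in observer.delineations if d.set_id == set_id}


def gross_tumor_volume(
    dataset: StudyDataset, observer_id: str, set_id: str, cache: MaskCache | None = None
) -> int:
    """GTV: sum of delineated pixels over all slices of a whole-brain set.

    Overlapping contours on one slice count once (per-slice union).
    Raises on an independent-slice set, where GTA is the defined
    measure.
    """
    stack = dataset.stack(set_id)
    if stack.independent_slices:
        raise ValueError(
            f"set {set_id!r} holds independent slices; use gross_tumor_area"
        )
    cache = cache or MaskCache(dataset)
    obs = dataset.observer(observer_id)
    return sum(
        mask_area(cache.mask(observer_id, set_id, k))
        for k in sorted(_delineated_slices(obs, set_id))
    )


def gross_tumor_area(
    dataset: StudyDataset, observer_id: str, set_id: str, cache: MaskCache | None = None
) -> float:
    """GTA: total delineated pixels divided by the number of slices the
    observer drew on. Defined for the independent single-slice set;
    NaN when the observer delineated no slice at all.
    """
    cache = cache or MaskCache(dataset)
    obs = dataset.observer(observer_id)
    slices = sorted(_delineated_slices(obs, set_id))
    if not slices:
        return math.nan
    total = sum(mask_area(cache.mask(observer_id, set_id, k)) for k in slices)
    return total / len(slices)


def slices_delineated(dataset: StudyDataset, observer_id: str, set_id: str) -> int:
    """Number of slices on which the observer drew at least one boundary."""
    obs = dataset.observer(observer_id)
    return len(_delineated_slices(obs, set_id))


def classify_central_peripheral(
    dataset: StudyDataset,
    set_id: str,
    config: AgreementConfig | None = None,
    cache: MaskCache | None = None,
) -> dict[int, str]:
    """Label each slice of a set "central" or "peripheral".

    For an independent set with stimulus metadata the labels are
    returned unchanged. Otherwise the ``central_k`` slices on which
    the most observers (both groups pooled) drew a boundary are
    central; ties are broken by larger total delineated area, then by
    lower slice index. Slices no observer delineated are peripheral.
    """
    config = config or AgreementConfig()
    stack = dataset.stack(set_id)
    if stack.independent_slices and stack.slice_location_labels is not None:
        return dict(enumerate(stack.slice_location_labels))

    counts = np.zeros(stack.n_slices, dtype=int)
    for obs in dataset.observers:
        for k in _delineated_slices(obs, set_id):
            counts[k] += 1
    n_any = int(np.count_nonzero(counts))
    candidates = [k for k in range(stack.n_slices) if counts[k] > 0]
    if n_any < config.central_k:
        warnings.warn(
            f"set {set_id!r}: only {n_any} slices have any delineation "
            f"(central_k={config.central_k}); all delineated slices labelled central",
            stacklevel=2,
        )
        central = set(candidates)
    else:
        cache = cache or MaskCache(dataset)
        areas = {
            k: sum(
                mask_area(cache.mask(o.observer_id, set_id, k))
                for o in dataset.observers
            )
            for k in candidates
        }
        # sort: most observers first, then largest summed area, then lowest index
        order = sorted(candidates, key=lambda k: (-counts[k], -areas[k], k))
        central = set(order[: config.central_k])
        kth = order[config.central_k - 1]
        ties = [k for k in candidates if counts[k] == counts[kth] and k not in central]
        if ties:
            logger.info(
                "set %s: central/peripheral tie at count %d broken by area then "
                "index (central: %s; excluded: %s)",
                set_id,
                counts[kth],
                sorted(central),
                sorted(ties),
            )
    return {
        k: ("central" if k in central else "peripheral") for k in range(stack.n_slices)
    }


def _pairwise_long(
    dataset: StudyDataset,
    set_id: str,
    config: AgreementConfig,
    cache: MaskCache,
) -> pd.DataFrame:
    """Long-form concordance of every same-group pair on every slice
    where at least one member delineated."""
    stack = dataset.stack(set_id)
    rows = []
    for group in ("expert", "novice"):
        members = dataset.observers_in_group(group)
        drawn = {o.observer_id: _delineated_slices(o, set_id) for o in members}
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                for k in range(stack.n_slices):
                    a_drew = k in drawn[a.observer_id]
                    b_drew = k in drawn[b.observer_id]
                    if not a_drew and not b_drew:
                        continue  # 0/0: no information, excluded
                    if a_drew and b_drew:
                        c = pairwise_concordance(
                            cache.mask(a.observer_id, set_id, k),
                            cache.mask(b.observer_id, set_id, k),
                            config.formula,
                        )
                    else:
                        c = 0.0  # presence/absence disagreement
                    rows.append(
                        {
                            "group": group,
                            "observer_a": a.observer_id,
                            "observer_b": b.observer_id,
                            "slice_index": k,
                            "concordance": c,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["group", "observer_a", "observer_b", "slice_index", "concordance"],
    )


def set_agreement(
    dataset: StudyDataset,
    set_id: str,
    config: AgreementConfig | None = None,
    cache: MaskCache | None = None,
) -> AgreementResult:
    """Agreement analysis of one set: per-observer mean concordance at
    central and peripheral locations, plus the pairwise audit table.

    For each observer and each slice, concordance is averaged over
    same-group peers (slices where neither pair member delineated are
    excluded; one-sided slices score 0%), then over slices, separately
    within central and peripheral labels. Observers whose group has no
    peer get NaN.
    """
    config = config or AgreementConfig()
    cache = cache or MaskCache(dataset)
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        labels = classify_central_peripheral(dataset, set_id, config, cache)
    for w in caught:  # record for the audit trail, but keep them visible
        warns.append(str(w.message))
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    pairwise = _pairwise_long(dataset, set_id, config, cache)

    rows = []
    for obs in dataset.observers:
        peers = [
            o
            for o in dataset.observers_in_group(obs.group)
            if o.observer_id != obs.observer_id
        ]
        row: dict[str, object] = {"observer_id": obs.observer_id, "group": obs.group}
        if not peers:
            msg = f"observer {obs.observer_id!r}: no same-group peer; agreement undefined"
            warns.append(msg)
            row["central"] = math.nan
            row["peripheral"] = math.nan
            rows.append(row)
            continue
        mine = pairwise[
            (pairwise["observer_a"] == obs.observer_id)
            | (pairwise["observer_b"] == obs.observer_id)
        ]
        for location in ("central", "peripheral"):
            keep = mine[mine["slice_index"].map(labels) == location]
            if keep.empty:
                row[location] = math.nan
            else:
                # mean over peers within slice, then over slices
                row[location] = float(
                    keep.groupby("slice_index")["concordance"].mean().mean()
                )
        rows.append(row)
    table = pd.DataFrame(rows, columns=["observer_id", "group", "central", "peripheral"])
    return AgreementResult(
        set_id=set_id,
        table=table,
        pairwise=pairwise,
        slice_labels=labels,
        warnings=warns,
    )


def observer_set_agreement(
    dataset: StudyDataset,
    observer_id: str,
    set_id: str,
    config: AgreementConfig | None = None,
    cache: MaskCache | None = None,
) -> pd.Series:
    """One observer's central/peripheral mean concordance for one set."""
    result = set_agreement(dataset, set_id, config, cache)
    row = result.table[result.table["observer_id"] == observer_id]
    if row.empty:
        raise KeyError(f"no observer {observer_id!r} in dataset")
    return row.iloc[0]


def summary_tables(
    dataset: StudyDataset,
    config: AgreementConfig | None = None,
    cache: MaskCache | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive group-level tables of the study.

    Returns ``{"gta_gtv": ..., "slices": ..., "agreement": ...,
    "agreement_observers": ...}``: mean and SD per group per set (per
    location for agreement), mirroring the standard reporting layout
    of delineation-agreement studies. GTV is reported for whole-brain
    sets and GTA for independent sets; slice counts cover whole-brain
    sets only (every slice of an independent set bears a tumor by
    construction). SDs are sample SDs (ddof=1), NaN for singleton
    groups.
    """
    config = config or AgreementConfig()
    cache = cache or MaskCache(dataset)

    vol_rows = []
    slice_rows = []
    for stack in dataset.stacks:
        for obs in dataset.observers:
            if stack.independent_slices:
                value = gross_tumor_area(dataset, obs.observer_id, stack.set_id, cache)
                measure = "GTA"
            else:
                value = float(
                    gross_tumor_volume(dataset, obs.observer_id, stack.set_id, cache)
                )
                measure = "GTV"
                slice_rows.append(
                    {
                        "set_id": stack.set_id,
                        "group": obs.group,
                        "observer_id": obs.observer_id,
                        "n_slices": slices_delineated(
                            dataset, obs.observer_id, stack.set_id
                        ),
                    }
                )
            vol_rows.append(
                {
                    "set_id": stack.set_id,
                    "measure": measure,
                    "group": obs.group,
                    "observer_id": obs.observer_id,
                    "pixels": value,
                }
            )
    vol = pd.DataFrame(vol_rows)
    gta_gtv = (
        vol.groupby(["set_id", "measure", "group"])["pixels"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    slc = pd.DataFrame(slice_rows)
    slices = (
        slc.groupby(["set_id", "group"])["n_slices"].agg(mean="mean", sd="std").reset_index()
        if not slc.empty
        else pd.DataFrame(columns=["set_id", "group", "mean", "sd"])
    )

    agr_obs_rows = []
    for stack in dataset.stacks:
        result = set_agreement(dataset, stack.set_id, config, cache)
        t = result.table.assign(set_id=stack.set_id)
        agr_obs_rows.append(t)
    agr_obs = pd.concat(agr_obs_rows, ignore_index=True)
    long = agr_obs.melt(
        id_vars=["set_id", "group", "observer_id"],
        value_vars=["central", "peripheral"],
        var_name="location",
        value_name="concordance",
    )
    agreement = (
        long.groupby(["set_id", "location", "group"])["concordance"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    return {
        "gta_gtv": gta_gtv,
        "slices": slices,
        "agreement": agreement,
        "agreement_observers": agr_obs[
            ["set_id", "observer_id", "group", "central", "peripheral"]
        ],
    }
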