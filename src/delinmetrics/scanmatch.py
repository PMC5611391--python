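"""Inspection-sequence similarity by global alignment.

Observers page through a slice stack; the ordered list of slices they
visit is a scanpath in one dimension. Two sequences are compared the
ScanMatch way: consecutive repeats are collapsed, slice indices are
encoded as two-letter tokens, and the token strings are globally
aligned with the Needleman–Wunsch algorithm under a substitution
matrix whose score falls off linearly with slice distance,

    score(i, j) = (n_bins - 1) - |i - j|,

so aligning a slice with itself earns the maximum ``n_bins - 1`` and
aligning the two extreme slices earns 0. The raw alignment score is
normalized by ``max_score * len(longer sequence)``, giving a
similarity of 1 for identical sequences and 0 for maximally dissimilar
ones; negative values (possible under nonzero gap penalties) are
clipped to 0.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import StudyDataset

__all__ = [
    "AlignmentConfig",
    "collapse_repeats",
    "encode_sequence",
    "decode_sequence",
    "substitution_matrix",
    "needleman_wunsch",
    "similarity_score",
    "group_similarity",
]


@dataclass
class AlignmentConfig:
    """Alignment settings: linear-distance substitution scores and a
    non-positive gap penalty (default 0, the ScanMatch toolbox default)."""

    gap_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_penalty > 0:
            raise ValueError(f"gap_penalty must be <= 0, got {self.gap_penalty}")


def collapse_repeats(seq: list[int]) -> list[int]:
    """Merge consecutive duplicate slice visits; idempotent.

    Two sequential interactions with one slice count as a single visit
    (modality toggles on the same slice are likewise not new visits).
    """
    return [k for k, _ in itertools.groupby(seq)]


def encode_sequence(seq: list[int], n_bins: int) -> str:
    """Encode slice indices as a two-letter-per-token string (supports
    up to 676 slices); bijective with :func:`decode_sequence`."""
    if n_bins < 1 or n_bins > 26 * 26:
        raise ValueError(f"n_bins must be in [1, 676], got {n_bins}")
    out = []
    for k in seq:
        if not 0 <= k < n_bins:
            raise ValueError(f"slice index {k} outside [0, {n_bins})")
        out.append(chr(ord("A") + k // 26) + chr(ord("a") + k % 26))
    return "".join(out)


def decode_sequence(tokens: str) -> list[int]:
    """Inverse of :func:`encode_sequence`."""
    if len(tokens) % 2:
        raise ValueError("token string length must be even (two chars per token)")
    out = []
    for i in range(0, len(tokens), 2):
        hi, lo = tokens[i], tokens[i + 1]
        if not ("A" <= hi <= "Z" and "a" <= lo <= "z"):
            raise ValueError(f"malformed token {tokens[i:i + 2]!r} at position {i}")
        out.append((ord(hi) - ord("A")) * 26 + (ord(lo) - ord("a")))
    return out


def substitution_matrix(n_bins: int) -> np.ndarray:
    """Linear-distance substitution scores: ``(n_bins-1) - |i-j|``.

    Symmetric, maximal (= n_bins - 1) on the diagonal, non-negative,
    non-increasing in slice distance.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    idx = np.arange(n_bins)
    return (n_bins - 1) - np.abs(idx[:, None] - idx[None, :]).astype(float)


def _as_indices(seq: list[int] | str) -> list[int]:
    return decode_sequence(seq) if isinstance(seq, str) else list(seq)


def needleman_wunsch(
    a: list[int] | str,
    b: list[int] | str,
    sub: np.ndarray,
    gap_penalty: float = 0.0,
) -> float:
    """Maximal global-alignment score of two sequences by dynamic
    programming under substitution matrix ``sub`` and a linear gap
    penalty. Accepts slice-index lists or encoded token strings;
    symmetric in (a, b).
    """
    ia, ib = _as_indices(a), _as_indices(b)
    if not ia or not ib:
        raise ValueError("needleman_wunsch requires two nonempty sequences")
    n_bins = sub.shape[0]
    if max(ia) >= n_bins or max(ib) >= n_bins:
        raise ValueError(
            f"sequence token outside the {n_bins}x{n_bins} substitution matrix"
        )
    la, lb = len(ia), len(ib)
    prev = np.arange(lb + 1, dtype=float) * gap_penalty
    arr_b = np.asarray(ib)
    for i in range(1, la + 1):
        cur = np.empty(lb + 1)
        cur[0] = i * gap_penalty
        match = prev[:-1] + sub[ia[i - 1], arr_b]
        for j in range(1, lb + 1):
            cur[j] = max(match[j - 1], prev[j] + gap_penalty, cur[j - 1] + gap_penalty)
        prev = cur
    return float(prev[lb])


def similarity_score(
    a: list[int] | str,
    b: list[int] | str,
    n_bins: int,
    config: AlignmentConfig | None = None,
) -> float:
    """Normalized sequence similarity in [0, 1].

    Sequences are collapsed, aligned under the linear-distance
    substitution matrix, and the raw score divided by
    ``max_score * len(longer collapsed sequence)``; clipped below at 0.
    Identical sequences score exactly 1.
    """
    config = config or AlignmentConfig()
    ia = collapse_repeats(_as_indices(a))
    ib = collapse_repeats(_as_indices(b))
    if not ia or not ib:
        raise ValueError("similarity_score requires nonempty sequences")
    sub = substitution_matrix(n_bins)
    raw = needleman_wunsch(ia, ib, sub, config.gap_penalty)
    max_score = n_bins - 1
    norm = raw / (max_score * max(len(ia), len(ib)))
    return max(0.0, min(1.0, norm))


def group_similarity(
    dataset: StudyDataset,
    set_id: str,
    config: AlignmentConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Within-group pairwise sequence similarity for one whole-brain set.

    Returns ``{"pairwise": ..., "observers": ..., "summary": ...}``:
    every same-group pair's score; each observer's mean over same-group
    peers; and group mean/SD. Observers without a recorded sequence for
    the set are excluded with a warning. Independent-slice sets carry
    no meaningful inspection order and are rejected.
    """
    config = config or AlignmentConfig()
    stack = dataset.stack(set_id)
    if stack.independent_slices:
        raise ValueError(
            f"set {set_id!r} holds independent slices; inspection order is "
            "not meaningful there"
        )
    n_bins = stack.n_slices
    pair_rows = []
    for group in ("expert", "novice"):
        members = []
        for o in dataset.observers_in_group(group):
            seq = o.interaction_sequences.get(set_id)
            if not seq:
                warnings.warn(
                    f"observer {o.observer_id!r} has no interaction sequence for "
                    f"set {set_id!r}; excluded from similarity",
                    stacklevel=2,
                )
                continue
            members.append((o.observer_id, collapse_repeats(seq)))
        for (ida, sa), (idb, sb) in itertools.combinations(members, 2):
            pair_rows.append(
                {
                    "group": group,
                    "observer_a": ida,
                    "observer_b": idb,
                    "similarity": similarity_score(sa, sb, n_bins, config),
                }
            )
    pairwise = pd.DataFrame(
        pair_rows, columns=["group", "observer_a", "observer_b", "similarity"]
    )
    obs_rows = []
    for group in ("expert", "novice"):
        g = pairwise[pairwise["group"] == group]
        ids = sorted(set(g["observer_a"]) | set(g["observer_b"]))
        for oid in ids:
            mine = g[(g["observer_a"] == oid) | (g["observer_b"] == oid)]
            obs_rows.append(
                {
                    "set_id": set_id,
                    "group": group,
                    "observer_id": oid,
                    "similarity": float(mine["similarity"].mean())
                    if not mine.empty
                    else math.nan,
                }
            )
    observers = pd.DataFrame(
        obs_rows, columns=["set_id", "group", "observer_id", "similarity"]
    )
    summary = (
        observers.groupby(["set_id", "group"])["similarity"]
        .agg(mean="mean", sd="std")
        .reset_index()
        if not observers.empty
        else pd.DataFrame(columns=["set_id", "group", "mean", "sd"])
    )
    return {"pairwise": pairwise, "observers": observers, "summary": summary}
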