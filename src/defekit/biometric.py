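"""Biometric identification from defecation habits.

Eleven per-event biomarkers, in three categories:

* defecation-time-dependent — DT (hour of day), SDD, FSD, ADD, TDD, ETD;
* stool-shape-dependent — ST (thickness, mm), BSFS (Bristol scale 1-7),
  SC (stool count);
* behavior-dependent — CT (cleansing type: 0 seated / 1 standing),
  U (urination before [1] / after [0] the first stool).

The biometric question: which subsets of these biomarkers separate
participants best?  Every subset of at least three biomarkers (1,981
subsets for all 11) is evaluated by Min-Max normalizing the selected
columns, embedding the events in 2-D with t-SNE, and scoring how well
the embedding clusters by *predefined participant labels* with the
silhouette coefficient

    a(i) = mean distance from event i to other events of its participant
    b(i) = min over other participants of the mean distance to them
    s(i) = (b(i) - a(i)) / max(a(i), b(i)),     S = mean_i s(i)

using Euclidean distances (s(i) = 0 for singleton clusters).  Subsets
are ranked per category grouping and the top scorers reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .errors import DefekitError, UndefinedScoreError

__all__ = [
    "FEATURES",
    "CATEGORIES",
    "GROUPINGS",
    "BINARY_FEATURES",
    "SilhouetteResult",
    "assemble_features",
    "minmax_normalize",
    "enumerate_subsets",
    "embed_2d",
    "silhouette_score",
    "rank_subsets",
    "default_perplexity",
]

CATEGORIES: dict[str, tuple[str, ...]] = {
    "time": ("DT", "SDD", "FSD", "ADD", "TDD", "ETD"),
    "shape": ("ST", "BSFS", "SC"),
    "behavior": ("CT", "U"),
}

FEATURES: tuple[str, ...] = (
    CATEGORIES["time"] + CATEGORIES["shape"] + CATEGORIES["behavior"]
)

BINARY_FEATURES: tuple[str, ...] = ("CT", "U")

#: Category groupings reported in the ranked output.
GROUPINGS: dict[str, tuple[str, ...]] = {
    "time+shape": CATEGORIES["time"] + CATEGORIES["shape"],
    "time+behavior": CATEGORIES["time"] + CATEGORIES["behavior"],
    "shape+behavior": CATEGORIES["shape"] + CATEGORIES["behavior"],
    "all": FEATURES,
}


@dataclass(frozen=True)
class SilhouetteResult:
    subset: tuple[str, ...]
    grouping: str
    score: float

    def to_dict(self) -> dict:
        return {
            "subset": "+".join(self.subset),
            "grouping": self.grouping,
            "score": self.score,
        }


def assemble_features(
    dataset,
    bsfs_source="truth",
    waterline_row: int | None = None,
) -> pd.DataFrame:
    """Build the 11-biomarker table from a dataset's raw sensor streams.

    Every biomarker except BSFS is re-derived from the frame and pressure
    streams through the timeline and optical-calibration layers (nothing
    is copied from the ground truth).  BSFS labels come from an external
    classifier plug-in: ``bsfs_source`` is either ``"truth"`` (use the
    dataset's labels) or a callable ``event -> int``.  Events whose
    streams cannot be extracted are skipped with a logged warning.

    Returns one row per event with the Table-style columns
    DT..U plus ``participant``, ``day_index`` and ``gender``.
    """
    import logging

    from .geometry import thickness_mm, x_from_row
    from .timeline import derive_durations, extract_event

    log = logging.getLogger(__name__)
    cal = dataset.config.calibration
    wl = waterline_row if waterline_row is not None else cal.waterline_row
    genders = {p.participant_id: p.gender for p in dataset.participants}

    rows = []
    for ev in dataset.events:
        try:
            tl, episodes = extract_event(ev.frames, ev.pressures, waterline_row=wl)
        except DefekitError as exc:
            log.warning(
                "skipping participant %s day %s: %s",
                ev.participant_id, ev.day_index, exc,
            )
            continue
        add, tdd, etd = derive_durations(tl)
        sdds = [ep.sdd for ep in episodes if ep.sdd is not None]
        thicknesses = [
            thickness_mm(ep.pixel_width, x_from_row(ep.pixel_row, cal), cal)
            for ep in episodes
            if ep.pixel_width is not None and ep.pixel_row is not None
        ]
        if not sdds or not thicknesses:
            log.warning(
                "skipping participant %s day %s: no confirmed drop episode",
                ev.participant_id, ev.day_index,
            )
            continue
        bsfs = (
            ev.truth.row.BSFS if bsfs_source == "truth" else int(bsfs_source(ev))
        )
        rows.append(
            {
                "DT": int(tl.t0 // 3600),
                "SDD": float(np.mean(sdds)),
                "FSD": tl.t1 - tl.t0,
                "ADD": add,
                "TDD": tdd,
                "ETD": etd,
                "ST": float(np.mean(thicknesses)),
                "BSFS": bsfs,
                "SC": tl.stool_count,
                "CT": 0 if tl.cleansing_seated else 1,
                "U": 1 if tl.urination_first else 0,
                "participant": ev.participant_id,
                "day_index": ev.day_index,
                "gender": genders.get(ev.participant_id, "unknown"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=list(FEATURES) + ["participant", "day_index", "gender"],
    )


def default_perplexity(n: int) -> float:
    """Embedding perplexity: min(30, (n - 1) / 3), the classic heuristic
    bounded so that perplexity stays below the sample count."""
    return float(min(30.0, max(1.0, (n - 1) / 3.0)))


def minmax_normalize(
    matrix,
    binary_columns: Sequence[int] | None = None,
):
    """Column-wise Min-Max scaling: (x - min) / (max - min).

    Non-constant columns map onto [0, 1] with min -> 0 and max -> 1;
    constant columns map to 0.  Columns listed in ``binary_columns``
    (already {0, 1}-coded) pass through unchanged.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("matrix must be 2-D with at least one row")
    out = x.copy()
    binary = set(binary_columns or ())
    for j in range(x.shape[1]):
        if j in binary:
            continue
        lo = x[:, j].min()
        hi = x[:, j].max()
        if hi > lo:
            out[:, j] = (x[:, j] - lo) / (hi - lo)
        else:
            out[:, j] = 0.0
    return out


def enumerate_subsets(
    parameters: Sequence[str] = FEATURES,
    min_size: int = 3,
) -> list[tuple[str, ...]]:
    """All subsets of at least ``min_size`` parameters, in a deterministic
    canonical order (by size, then lexicographic in the input order).

    For the 11 biomarkers and ``min_size=3`` this enumerates
    2^11 - 1 - 11 - 55 = 1,981 subsets.
    """
    params = list(parameters)
    if len(set(params)) != len(params):
        raise ValueError("parameter abbreviations must be distinct")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    subsets: list[tuple[str, ...]] = []
    for k in range(min_size, len(params) + 1):
        subsets.extend(combinations(params, k))
    return subsets


def embed_2d(
    matrix,
    seed: int = 0,
    perplexity: float | None = None,
    max_iter: int = 500,
):
    """Deterministic 2-D t-SNE embedding of a (normalized) feature matrix.

    PCA initialisation and a fixed ``random_state`` make repeated calls
    byte-identical.  Requires at least 4 rows and perplexity < n.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise ValueError("embedding needs a 2-D matrix with n >= 4 rows")
    n = x.shape[0]
    if perplexity is None:
        perplexity = default_perplexity(n)
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n ({n})")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=max_iter,
    )
    return tsne.fit_transform(x)


def silhouette_score(points, labels) -> float:
    """Mean silhouette coefficient of points under predefined labels.

    Implements a(i), b(i) and s(i) = (b - a)/max(a, b) directly on the
    Euclidean pairwise-distance matrix; points in singleton clusters
    score 0, as does any point with max(a, b) = 0.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if pts.ndim != 2 or pts.shape[0] != labels.shape[0]:
        raise ValueError("points must be n x k with one label per row")
    n = pts.shape[0]
    if n < 2:
        raise UndefinedScoreError("silhouette needs at least two points")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedScoreError("silhouette needs at least two distinct labels")

    dist = cdist(pts, pts)
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    s = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0  # singleton-cluster convention
            continue
        a_i = dist[i, own].sum() / (own.size - 1)
        b_i = min(
            dist[i, members[lab]].mean() for lab in uniq if lab != labels[i]
        )
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0.0 else (b_i - a_i) / denom
    return float(s.mean())


def rank_subsets(
    table: pd.DataFrame,
    grouping: str = "all",
    seed: int = 0,
    perplexity: float | None = None,
    min_size: int = 3,
    use_embedding: bool = True,
    max_iter: int = 500,
    label_column: str = "participant",
) -> list[SilhouetteResult]:
    """Score every eligible biomarker subset of a category grouping.

    For each subset drawn from the grouping's feature pool: select the
    columns, Min-Max normalize, embed in 2-D (``use_embedding=False``
    scores the normalized features directly), and compute the silhouette
    against the participant labels.  Returns all results sorted by
    descending score (ties broken by subset order); slice ``[:3]`` for
    the headline top-3.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; one of {sorted(GROUPINGS)}")
    if label_column not in table.columns:
        raise KeyError(f"table lacks the {label_column!r} column")
    labels = table[label_column].to_numpy()
    if np.unique(labels).size < 2:
        raise UndefinedScoreError("ranking needs at least two participants")

    pool = [f for f in GROUPINGS[grouping] if f in table.columns]
    missing = set(GROUPINGS[grouping]) - set(pool)
    if missing:
        raise KeyError(f"table lacks biomarker columns {sorted(missing)}")

    results: list[SilhouetteResult] = []
    for subset in enumerate_subsets(pool, min_size=min_size):
        x = table[list(subset)].to_numpy(dtype=float)
        binary_idx = [k for k, f in enumerate(subset) if f in BINARY_FEATURES]
        xn = minmax_normalize(x, binary_columns=binary_idx)
        pts = (
            embed_2d(xn, seed=seed, perplexity=perplexity, max_iter=max_iter)
            if use_embedding
            else xn
        )
        results.append(
            SilhouetteResult(subset, grouping, silhouette_score(pts, labels))
        )
    results.sort(key=lambda r: (-r.score, r.subset))
    return results


def results_frame(results: Iterable[SilhouetteResult]) -> pd.DataFrame:
    """Ranked results as a flat table (subset, grouping, score)."""
    return pd.DataFrame([r.to_dict() for r in results])
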