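"""COPAS event-table analysis: filtering, PCA, k-means clustering and gating.

A COPAS run yields one row per detected object with size measurements
(TOF, time of flight; EXT, optical extinction) and two fluorescence channels,
all in instrument arbitrary units.  Raw tables contain debris, dead larvae
and doublets, so counting larvae per fluorescence class takes a four-stage
cleaning pass — manual bounds on log size, bounds on the first two principal
components of the size variables, manual bounds on log fluorescence, bounds
on the first two principal components of the fluorescence variables —
followed by k-means clustering and/or rectangular gating in log-fluorescence
space.

Filter bounds here default to ±k standard deviations (the field practice is
visual outlier removal; the pipeline structure is fixed, the thresholds are
configurable).  All intervals are half-open ``[low, high)`` and events on a
gate boundary are excluded from that gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "SIZE_VARS",
    "FLUOR_VARS",
    "STAGE_ORDER",
    "FilterSpec",
    "ClusterResult",
    "read_events",
    "write_events",
    "log_features",
    "pca_scores",
    "build_default_filters",
    "apply_filter_pipeline",
    "kmeans_cluster",
    "gate_counts",
]

SIZE_VARS = ("TOF", "EXT")
FLUOR_VARS = ("FLU_GREEN", "FLU_RED")
STAGE_ORDER = ("size_manual", "size_pca", "fluor_manual", "fluor_pca")

REQUIRED_COLUMNS = SIZE_VARS + FLUOR_VARS


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event CSV with header TOF,EXT,FLU_GREEN,FLU_RED[,LABEL].

    Extra columns are tolerated and preserved; ``#`` lines are comments.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError("event table contains missing values")
    if (df[list(SIZE_VARS)] <= 0).any().any():
        raise ValueError("TOF and EXT must be strictly positive")
    if (df[list(FLUOR_VARS)] < 0).any().any():
        raise ValueError("fluorescence must be nonnegative")
    return df


def write_events(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write an event table; an optional seed is recorded as a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def log_features(events: pd.DataFrame, variables: Sequence[str]) -> np.ndarray:
    """log10 feature matrix for the requested variables.

    Size variables are strictly positive; fluorescence channels may contain
    zeros, so they are offset by one unit (negligible at signal level).
    """
    cols = []
    for v in variables:
        x = events[v].to_numpy(dtype=float)
        if v in FLUOR_VARS:
            cols.append(np.log10(x + 1.0))
        else:
            cols.append(np.log10(x))
    return np.column_stack(cols)


def pca_scores(
    events: pd.DataFrame,
    variables: Sequence[str],
    scale: bool = False,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Principal-component scores of the chosen log-transformed variables.

    Variables are centered (and optionally scaled to unit variance) before
    decomposition.  Returns (scores, explained variance ratio, fitted model).
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events for PCA")
    if len(variables) < 2:
        raise ValueError("need at least 2 variables for PCA")
    X = log_features(events, variables)
    sd = X.std(axis=0, ddof=1)
    if scale:
        if np.any(sd == 0):
            bad = [v for v, s in zip(variables, sd) if s == 0]
            raise ValueError(f"constant-variance variables cannot be scaled: {bad}")
        X = X / sd
    n_components = min(n_components, X.shape[1])
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    return scores, model.explained_variance_ratio_, model


def _check_interval(lo: float, hi: float, what: str) -> None:
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
        raise ValueError(f"malformed interval for {what}: ({lo}, {hi})")


@dataclass(frozen=True)
class FilterSpec:
    """One filtering stage with materialized inclusion intervals.

    For manual stages ``intervals`` maps variable name → (low, high) in log10
    units.  For PCA stages the fitted projection (center, optional scaling,
    loadings) is stored alongside per-component intervals, so re-applying the
    same spec to already-filtered data is a no-op (idempotence).
    """

    stage: str
    intervals: Mapping[str, tuple[float, float]]
    variables: tuple[str, ...] = ()
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    loadings: np.ndarray | None = None  # (n_components, n_variables)

    def __post_init__(self):
        if self.stage not in STAGE_ORDER:
            raise ValueError(f"unknown filter stage {self.stage!r}")
        for key, (lo, hi) in self.intervals.items():
            _check_interval(lo, hi, f"{self.stage}:{key}")
        if self.stage.endswith("_pca") and self.loadings is None:
            raise ValueError("PCA filter stage requires a fitted projection")

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        """Boolean keep-mask; intervals are half-open [low, high)."""
        keep = np.ones(len(events), dtype=bool)
        if self.stage.endswith("_pca"):
            X = log_features(events, self.variables) - self.center
            if self.scale is not None:
                X = X / self.scale
            scores = X @ self.loadings.T
            for key, (lo, hi) in self.intervals.items():
                comp = int(key.lstrip("PC")) - 1
                s = scores[:, comp]
                keep &= (s >= lo) & (s < hi)
        else:
            for var, (lo, hi) in self.intervals.items():
                x = log_features(events, [var])[:, 0]
                keep &= (x >= lo) & (x < hi)
        return keep


def build_default_filters(
    events: pd.DataFrame,
    n_sd: float = 3.0,
    stages: Sequence[str] = STAGE_ORDER,
    scale_pca: bool = False,
) -> list[FilterSpec]:
    """Materialize a default 4-stage pipeline with ±``n_sd`` SD intervals.

    Each stage's statistics (and PCA projection) are computed on the events
    surviving the previous stages, then frozen into the returned specs.
    """
    for a, b in zip(stages, stages[1:]):
        if STAGE_ORDER.index(a) >= STAGE_ORDER.index(b):
            raise ValueError("filter stages must follow the fixed pipeline order")
    specs: list[FilterSpec] = []
    current = events
    for stage in stages:
        variables = SIZE_VARS if stage.startswith("size") else FLUOR_VARS
        if stage.endswith("_pca"):
            scores, _, model = pca_scores(current, variables, scale=scale_pca)
            sd_in = log_features(current, variables).std(axis=0, ddof=1)
            intervals = {}
            for i in range(scores.shape[1]):
                mu, sd = scores[:, i].mean(), scores[:, i].std(ddof=1)
                intervals[f"PC{i + 1}"] = (mu - n_sd * sd, mu + n_sd * sd)
            spec = FilterSpec(
                stage=stage,
                intervals=intervals,
                variables=tuple(variables),
                # PCA was fit on (optionally scaled) features; express the
                # center on the raw log scale so mask() can redo the pipeline.
                center=model.mean_ * sd_in if scale_pca else model.mean_,
                scale=sd_in if scale_pca else None,
                loadings=model.components_,
            )
        else:
            # manual stages use robust statistics (median, normal-scaled MAD):
            # a visual screen centres on the main cloud, so the planted
            # outliers must not inflate their own inclusion bounds
            X = log_features(current, variables)
            intervals = {}
            for j, v in enumerate(variables):
                mu = float(np.median(X[:, j]))
                sd = float(sp_stats.median_abs_deviation(X[:, j], scale="normal"))
                if sd == 0.0:
                    sd = X[:, j].std(ddof=1)
                intervals[v] = (mu - n_sd * sd, mu + n_sd * sd)
            spec = FilterSpec(stage=stage, intervals=intervals)
        specs.append(spec)
        current = current[spec.mask(current)]
    return specs


def apply_filter_pipeline(
    events: pd.DataFrame, filters: Sequence[FilterSpec]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply filter stages in the fixed pipeline order.

    Returns the surviving events and per-stage removal counts.  Filtering
    never adds events, and re-applying the same (materialized) pipeline to
    its own output removes nothing.
    """
    order = [STAGE_ORDER.index(f.stage) for f in filters]
    if order != sorted(order) or len(set(order)) != len(order):
        raise ValueError("filters must be unique and in the fixed stage order")
    removed: dict[str, int] = {}
    current = events
    for spec in filters:
        mask = spec.mask(current)
        removed[spec.stage] = int((~mask).sum())
        current = current[mask]
    return current, removed


@dataclass(frozen=True)
class ClusterResult:
    """k-means result: 1-based labels, centroids, per-cluster counts, WCSS."""

    labels: np.ndarray
    centroids: np.ndarray
    counts: np.ndarray
    wcss: float
    features: tuple[str, ...]

    def __post_init__(self):
        k = len(self.counts)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=k) > k:
            raise ValueError("labels must lie in [1, k]")
        if int(self.counts.sum()) != len(self.labels):
            raise ValueError("cluster counts must sum to the number of events")


def kmeans_cluster(
    events: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    features: Sequence[str] = FLUOR_VARS,
) -> ClusterResult:
    """Lloyd k-means on the log-fluorescence feature space.

    Runs ``restarts`` seeded random initializations and keeps the solution
    with the lowest within-cluster sum of squares.  Deterministic for a fixed
    (seed, restarts, data).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(events) < k:
        raise ValueError(f"cannot form {k} clusters from {len(events)} events")
    X = log_features(events, features)
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    labels = km.labels_.astype(int) + 1
    counts = np.bincount(labels, minlength=k + 1)[1:]
    return ClusterResult(
        labels=labels,
        centroids=km.cluster_centers_,
        counts=counts,
        wcss=float(km.inertia_),
        features=tuple(features),
    )


def gate_counts(
    events: pd.DataFrame,
    gates: Mapping[str, Mapping[str, tuple[float, float]]],
    allow_overlap: bool = False,
) -> dict[str, int]:
    """Count events per named rectangular gate in log-fluorescence space.

    Each gate maps channel name → (low, high) in log10 units, half-open;
    events exactly on a boundary are excluded.  Ungated events are reported
    under ``"ungated"``.  Overlapping gates are rejected unless explicitly
    permitted.
    """
    for name, region in gates.items():
        for ch, (lo, hi) in region.items():
            if ch not in FLUOR_VARS:
                raise ValueError(f"gate {name!r} uses unknown channel {ch!r}")
            if lo >= hi:
                raise ValueError(f"inverted gate bounds for {name!r}:{ch}")
    if not allow_overlap:
        names = list(gates)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if _rects_overlap(gates[a], gates[b]):
                    raise ValueError(f"gates {a!r} and {b!r} overlap")
    logf = {ch: log_features(events, [ch])[:, 0] for ch in FLUOR_VARS}
    counts: dict[str, int] = {}
    assigned = np.zeros(len(events), dtype=bool)
    for name, region in gates.items():
        mask = np.ones(len(events), dtype=bool)
        for ch, (lo, hi) in region.items():
            mask &= (logf[ch] >= lo) & (logf[ch] < hi)
        counts[name] = int(mask.sum())
        assigned |= mask
    counts["ungated"] = int((~assigned).sum())
    return counts


def _rects_overlap(a: Mapping, b: Mapping) -> bool:
    """Two rectangular gates overlap iff their intervals overlap on every
    channel constrained by both (an unconstrained channel spans everything)."""
    for ch in FLUOR_VARS:
        if ch in a and ch in b:
            alo, ahi = a[ch]
            blo, bhi = b[ch]
            if ahi <= blo or bhi <= alo:
                return False
    return True
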