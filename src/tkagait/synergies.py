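"""Muscle-synergy extraction, classification and activation-timing metrics.

A synergy factorizes the 8 x (200 * cycles) envelope matrix V into
non-negative modules W (8 x k, time-independent muscle weightings) and
activation patterns H (k x 200*cycles, time-dependent coefficients),
V ~= W H, by multiplicative-update NMF under the Frobenius objective.
The per-subject rank is the smallest k whose reconstruction R^2 reaches a
threshold (default 0.90); the group-level rank is then imposed as the
rounded mean of the per-group mean ranks for each activity. Extracted
synergies are functionally classified across a group by k-means on
unit-norm (module (+) downsampled-pattern) features, and each classified
activation pattern is summarized by its full width at half maximum (FWHM,
in points of the 200-point cycle) and centre of activity (CoA, degrees on
the 0-360 circle spanned by one touchdown to the next).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .emg import MUSCLES, N_POINTS

__all__ = [
    "SynergySet",
    "ClassifiedSynergy",
    "ClassifiedSynergies",
    "nmf",
    "choose_rank",
    "rank_scan",
    "impose_group_rank",
    "classify",
    "fwhm",
    "fwhm_to_pct",
    "coa",
    "FOUR_SYNERGY_LABELS",
    "THREE_SYNERGY_LABELS",
]

# functional muscle groups by channel index (RF VM VL TA HM HL GM GL)
_GROUPS_4 = {
    "knee_extensors": (0, 1, 2),   # quadriceps
    "dorsiflexors": (3,),          # tibialis anterior
    "knee_flexors": (4, 5),        # hamstrings
    "plantarflexors": (6, 7),      # gastrocnemii
}
# stair descent merges the dorsiflexor- and knee-flexor-dominated synergy
_GROUPS_3 = {
    "knee_extensors": (0, 1, 2),
    "dorsi_knee_flexors": (3, 4, 5),
    "plantarflexors": (6, 7),
}
FOUR_SYNERGY_LABELS = tuple(_GROUPS_4)
THREE_SYNERGY_LABELS = tuple(_GROUPS_3)


@dataclass
class SynergySet:
    """NMF result for one subject-activity: W (8 x k), H (k x T), R^2, rank."""

    modules: np.ndarray
    patterns: np.ndarray
    r_squared: float
    k: int
    sse: float = math.nan
    objective_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.modules = np.asarray(self.modules, dtype=float)
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.modules.shape[1] != self.k or self.patterns.shape[0] != self.k:
            raise ValueError("modules/patterns ranks disagree with k")
        if self.modules.min() < 0 or self.patterns.min() < 0:
            raise ValueError("synergy factors must be non-negative")

    def mean_pattern(self, i: int) -> np.ndarray:
        """Pattern i averaged over concatenated 200-point cycles."""
        h = self.patterns[i]
        if h.size % N_POINTS:
            raise ValueError("pattern length is not a multiple of 200")
        return h.reshape(-1, N_POINTS).mean(axis=0)


# ---------------------------------------------------------------------------
# non-negative matrix factorization (multiplicative updates)
# ---------------------------------------------------------------------------

def nmf(
    V: np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
    patience: int = 20,
    track_objective: bool = False,
) -> SynergySet:
    """Multiplicative-update NMF under the Frobenius objective.

    Runs ``n_restarts`` random restarts jointly (all restarts advance in a
    single batched update) and keeps the lowest-SSE solution. Iteration stops
    when the relative SSE improvement over the last ``patience`` iterations
    falls below ``tol`` for every restart, or after ``max_iter`` iterations.
    Module columns are rescaled to unit maximum with compensating row scaling
    of H, so W entries are interpretable as relative muscle contributions.

    ``track_objective=True`` stores the winning restart's SSE trajectory
    (one value per iteration) for monotonicity checks.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if V.min() < 0:
        raise ValueError("V must be non-negative")
    m, n = V.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank k={k} outside valid range 1..{min(m, n)}")
    if n_restarts < 1:
        raise ValueError("need at least one restart")

    rng = np.random.default_rng(seed)
    scale = math.sqrt(max(V.mean(), np.finfo(float).tiny) / k)
    W = rng.uniform(0.1, 1.0, size=(n_restarts, m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(n_restarts, k, n)) * scale
    eps = 1e-12

    history = np.empty((max_iter, n_restarts))
    sse_prev = np.full(n_restarts, np.inf)
    ring = np.full((patience, n_restarts), np.inf)
    n_done = 0
    for it in range(max_iter):
        WT = W.transpose(0, 2, 1)
        H *= (WT @ V) / (WT @ W @ H + eps)
        HT = H.transpose(0, 2, 1)
        W *= (V @ HT) / (W @ (H @ HT) + eps)
        resid = V - W @ H
        sse = np.einsum("rij,rij->r", resid, resid)
        history[it] = sse
        n_done = it + 1
        old = ring[it % patience].copy()
        ring[it % patience] = sse
        if it >= patience:
            rel = (old - sse) / np.where(old > 0, old, 1.0)
            if np.all(rel < tol):
                break
        sse_prev = sse

    best = int(np.argmin(sse_prev if n_done == 0 else history[n_done - 1]))
    Wb, Hb = W[best], H[best]
    col_max = Wb.max(axis=0)
    safe = np.where(col_max > 0, col_max, 1.0)
    Wb = Wb / safe
    Hb = Hb * safe[:, None]
    sse_best = float(history[n_done - 1, best])
    sst = float(((V - V.mean()) ** 2).sum())
    r2 = 1.0 - sse_best / sst if sst > 0 else 1.0
    return SynergySet(
        modules=Wb,
        patterns=Hb,
        r_squared=float(r2),
        k=k,
        sse=sse_best,
        objective_history=history[:n_done, best].copy() if track_objective else None,
    )


def rank_scan(
    V: np.ndarray,
    seed: int,
    r2_threshold: float = 0.90,
    k_max: int = 8,
    **nmf_kwargs,
) -> tuple[int, dict[int, SynergySet]]:
    """Fit increasing ranks until R^2 reaches the threshold.

    Returns the chosen rank and all fitted :class:`SynergySet` objects
    (so callers can reuse, e.g., the fit at the imposed group rank).
    Falls back to ``k_max`` when the threshold is never reached.
    """
    V = np.asarray(V, dtype=float)
    k_max = min(k_max, min(V.shape))
    fits: dict[int, SynergySet] = {}
    for k in range(1, k_max + 1):
        fits[k] = nmf(V, k, seed=seed + k, **nmf_kwargs)
        if fits[k].r_squared >= r2_threshold:
            return k, fits
    return k_max, fits


def choose_rank(V: np.ndarray, seed: int, r2_threshold: float = 0.90, k_max: int = 8) -> int:
    """Smallest rank whose reconstruction R^2 reaches ``r2_threshold``."""
    k, _ = rank_scan(V, seed, r2_threshold=r2_threshold, k_max=k_max)
    return k


def impose_group_rank(per_group_ks: list[list[float]]) -> int:
    """Group-level rank for one activity from per-subject ranks of each group.

    The mean rank is computed per group, the group means are averaged, and
    the result is rounded half away from zero (3.6 -> 4, 3.3 -> 3), matching
    the published rule that set 4 synergies for level/downhill walking and 3
    for stair descent.
    """
    if not per_group_ks or any(len(g) == 0 for g in per_group_ks):
        raise ValueError("every group must contribute at least one rank")
    group_means = [float(np.mean(g)) for g in per_group_ks]
    x = float(np.mean(group_means))
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


# ---------------------------------------------------------------------------
# functional classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedSynergy:
    subject: str
    index: int            # synergy index within the subject's SynergySet
    cluster: int
    label: str
    classified: bool
    fwhm: float
    coa: float
    distance: float       # distance to the cluster centroid in feature space


@dataclass
class ClassifiedSynergies:
    """Group-activity classification result."""

    entries: list[ClassifiedSynergy]
    labels: tuple[str, ...]
    k_imposed: int
    classifiable_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        total = len(self.entries)
        classified = sum(e.classified for e in self.entries)
        self.classifiable_ratio = classified / total if total else 0.0

    def classified_entries(self, label: str | None = None) -> list[ClassifiedSynergy]:
        out = [e for e in self.entries if e.classified]
        if label is not None:
            out = [e for e in out if e.label == label]
        return out


def _downsample(pattern: np.ndarray, n_out: int = 20) -> np.ndarray:
    p = np.asarray(pattern, dtype=float)
    if p.size % n_out:
        raise ValueError(f"pattern length {p.size} not divisible by {n_out}")
    return p.reshape(n_out, -1).mean(axis=1)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def classify(
    synergy_sets: dict[str, SynergySet],
    k_imposed: int,
    seed: int,
    n_restarts: int = 50,
) -> ClassifiedSynergies:
    """Functionally classify all synergies of one group-activity by k-means.

    Feature vector per synergy: unit-norm module (8 values) concatenated
    with the unit-norm mean activation pattern downsampled to 20 points.
    When one subject places more than one synergy in a cluster, only the
    member closest to the centroid keeps the cluster; the rest are flagged
    unclassified (a subject contributes at most one synergy per functional
    cluster). Each cluster is labelled by the functional muscle group
    (quadriceps / gastrocnemii / tibialis anterior / hamstrings; the
    dorsiflexor and hamstring groups merge in the 3-synergy scheme used for
    stair descent) with the largest summed centroid weight.
    """
    if len(synergy_sets) < 2:
        raise ValueError("classification needs at least 2 subjects")
    rows = []
    meta: list[tuple[str, int, np.ndarray]] = []
    for subject in sorted(synergy_sets):
        ss = synergy_sets[subject]
        for i in range(ss.k):
            pattern200 = ss.mean_pattern(i)
            feat = np.concatenate(
                [_unit(ss.modules[:, i]), _unit(_downsample(pattern200))]
            )
            rows.append(feat)
            meta.append((subject, i, pattern200))
    X = np.asarray(rows)
    if k_imposed > len(X):
        raise ValueError(
            f"k_imposed={k_imposed} exceeds the {len(X)} extracted synergies"
        )
    km = KMeans(n_clusters=k_imposed, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[assign], axis=1)

    groups = _GROUPS_4 if k_imposed != 3 else _GROUPS_3
    labels = []
    for c in range(k_imposed):
        w = km.cluster_centers_[c, : len(MUSCLES)]
        labels.append(max(groups, key=lambda g: w[list(groups[g])].sum()))

    classified = np.ones(len(X), dtype=bool)
    for c in range(k_imposed):
        members = np.nonzero(assign == c)[0]
        by_subject: dict[str, list[int]] = {}
        for j in members:
            by_subject.setdefault(meta[j][0], []).append(j)
        for subj_members in by_subject.values():
            if len(subj_members) > 1:
                keep = min(subj_members, key=lambda j: dists[j])
                for j in subj_members:
                    if j != keep:
                        classified[j] = False

    entries = []
    for j, (subject, idx, pattern200) in enumerate(meta):
        entries.append(
            ClassifiedSynergy(
                subject=subject,
                index=idx,
                cluster=int(assign[j]),
                label=labels[assign[j]],
                classified=bool(classified[j]),
                fwhm=fwhm(pattern200),
                coa=coa(pattern200),
                distance=float(dists[j]),
            )
        )
    return ClassifiedSynergies(entries=entries, labels=tuple(labels), k_imposed=k_imposed)


# ---------------------------------------------------------------------------
# activation-timing metrics
# ---------------------------------------------------------------------------

def fwhm(pattern: np.ndarray) -> float:
    """Full width at half maximum of an activation pattern, in cycle points.

    The pattern minimum is subtracted first; the FWHM is the number of
    samples strictly greater than half the resulting maximum. Counting
    samples (rather than interpolating threshold crossings) keeps widths
    integer-valued on the normalized grid and handles multi-burst patterns.
    """
    p = np.asarray(pattern, dtype=float)
    if p.ndim != 1:
        raise ValueError("pattern must be 1-D")
    if p.min() < 0:
        raise ValueError("pattern must be non-negative")
    q = p - p.min()
    peak = q.max()
    if peak <= 0:
        raise ValueError("FWHM is undefined for a constant pattern")
    return float(np.count_nonzero(q > peak / 2.0))


def fwhm_to_pct(width_points: float, n_points: int = N_POINTS) -> float:
    """Convert an FWHM in cycle points to % of the normalized cycle."""
    return 100.0 * width_points / n_points


def coa(pattern: np.ndarray) -> float:
    """Centre of activity: circular mean angle of the pattern, degrees in [0, 360).

    Sample t (1-based) sits at angle 360*(t-1)/N on the circle spanned by
    one touchdown and the next; the CoA is the angle of the resultant vector
    of the activation mass, atan2(sum P sin, sum P cos).
    """
    p = np.asarray(pattern, dtype=float)
    if p.ndim != 1:
        raise ValueError("pattern must be 1-D")
    if p.min() < 0:
        raise ValueError("pattern must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("CoA is undefined for a zero-sum pattern")
    theta = 2.0 * np.pi * np.arange(p.size) / p.size
    a = float(p @ np.cos(theta))
    b = float(p @ np.sin(theta))
    return float(np.rad2deg(np.arctan2(b, a)) % 360.0)
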