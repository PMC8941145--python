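"""SIsCA core: R² grids per peptide, per-MAG aggregation, ordination,
cluster validation and trophic-lifestyle classification.

The central object is the RIA profile: the vector of coefficients of
determination obtained by comparing one measured isotopologue pattern against
the predicted pattern at every grid RIA.  Unlike a single point-estimate RIA,
the full R² vector preserves the shape of the measured pattern (e.g. the
bimodality of a partially-turned-over population), which is what lets
organisms be clustered by carbon-utilization profile over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .chem import IsotopologuePattern, RIAGrid

__all__ = [
    "RIAProfile",
    "MAGTrajectory",
    "OrdinationResult",
    "ConfidenceEllipse",
    "r_squared",
    "ria_profile",
    "aggregate_profiles",
    "ordinate",
    "validate_clusters",
    "classify_lifestyle",
    "LifestyleThresholds",
    "ward_clusters",
]


def r_squared(measured, predicted) -> float:
    """Coefficient of determination between two isotopologue patterns.

    ``1 − SS_res/SS_tot`` with ``SS_res = Σ(mᵢ − pᵢ)²`` and
    ``SS_tot = Σ(mᵢ − mean(m))²``, after aligning both vectors on the union
    of isotopologue indices (missing positions are zero) and normalizing each
    to sum 1.  Can be negative when the predicted pattern fits worse than the
    measured mean; negative values are kept, since only the relative ordering
    across the RIA grid and averages over peptides matter.
    """
    m = np.asarray(
        measured.intensities if hasattr(measured, "intensities") else measured,
        dtype=float,
    )
    p = np.asarray(
        predicted.intensities if hasattr(predicted, "intensities") else predicted,
        dtype=float,
    )
    if m.sum() <= 0:
        raise ValueError("measured pattern has zero total intensity")
    size = max(len(m), len(p))
    m = np.pad(m, (0, size - len(m))) / m.sum()
    p = np.pad(p, (0, size - len(p))) / p.sum()
    ss_res = float(np.sum((m - p) ** 2))
    if ss_res == 0.0:
        return 1.0
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        # perfectly uniform measured vector: R² degenerates; match only when
        # the prediction is (numerically) uniform too
        return 1.0 if ss_res <= 1e-24 else float("-inf")
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class RIAProfile:
    """R² vector over the RIA grid for one peptide (or MAG aggregate)."""

    owner: str
    timepoint: str
    r2: np.ndarray
    grid: RIAGrid = field(default_factory=RIAGrid.default)

    def __post_init__(self) -> None:
        arr = np.asarray(self.r2, dtype=float)
        if len(arr) != len(self.grid):
            raise ValueError(
                f"profile length {len(arr)} != grid length {len(self.grid)}"
            )
        object.__setattr__(self, "r2", arr)


def ria_profile(
    measured,
    refs: Sequence[IsotopologuePattern],
    grid: RIAGrid | None = None,
    owner: str = "",
    timepoint: str = "",
) -> RIAProfile:
    """Score one measured pattern against the full reference set.

    `refs` must be the predicted patterns of the *same* peptide (composition
    and charge) evaluated at each grid RIA, in grid order.
    """
    grid = grid or RIAGrid.default()
    if len(refs) != len(grid):
        raise ValueError(f"{len(refs)} reference patterns for {len(grid)}-point grid")
    pattern = measured.pattern if hasattr(measured, "pattern") else measured
    r2 = np.array([r_squared(pattern, ref) for ref in refs])
    return RIAProfile(owner=owner, timepoint=timepoint, r2=r2, grid=grid)


@dataclass(frozen=True)
class MAGTrajectory:
    """Aggregated profile, point-estimate RIA and labeled fraction per time
    point, for one MAG (or genus-level group)."""

    mag_id: str
    timepoints: tuple[str, ...]
    profiles: tuple[RIAProfile, ...]
    ria: tuple[float, ...] = ()
    labeled_fraction: tuple[float, ...] = ()

    def feature_vector(self) -> np.ndarray:
        """Time-concatenated R² features (grid length × n timepoints)."""
        return np.concatenate([p.r2 for p in self.profiles])


def aggregate_profiles(profiles: Iterable[RIAProfile]) -> list[RIAProfile]:
    """Element-wise mean R² over all peptides/replicates of each MAG/time point.

    Profiles with the same ``(owner, timepoint)`` key are averaged; output is
    sorted by key for determinism.
    """
    groups: dict[tuple[str, str], list[RIAProfile]] = {}
    for prof in profiles:
        groups.setdefault((prof.owner, prof.timepoint), []).append(prof)
    if not groups:
        raise ValueError("no profiles to aggregate")
    out = []
    for (owner, tp) in sorted(groups):
        members = groups[(owner, tp)]
        grid = members[0].grid
        mean = np.mean([m.r2 for m in members], axis=0)
        out.append(RIAProfile(owner=owner, timepoint=tp, r2=mean, grid=grid))
    return out


@dataclass(frozen=True)
class ConfidenceEllipse:
    """2-D confidence ellipse of a cluster mean in ordination space."""

    center: np.ndarray
    covariance: np.ndarray  # covariance of the mean (cov / n)
    scale: float  # chi-square quantile at the requested confidence

    def boundary(self, n_points: int = 720) -> np.ndarray:
        """(n_points, 2) boundary polyline."""
        vals, vecs = np.linalg.eigh(self.covariance)
        vals = np.clip(vals, 0.0, None)
        t = np.linspace(0.0, 2 * np.pi, n_points)
        circle = np.stack([np.cos(t), np.sin(t)])
        return (
            self.center[:, None]
            + vecs @ (np.sqrt(self.scale * vals)[:, None] * circle)
        ).T

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        cov = self.covariance + 1e-30 * np.eye(2)
        md2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        return md2 <= self.scale


@dataclass(frozen=True)
class OrdinationResult:
    """PCA of MAG carbon-utilization feature vectors."""

    mag_ids: tuple[str, ...]
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    layout: str
    cluster_labels: dict[str, str] = field(default_factory=dict)
    ellipses: dict[str, ConfidenceEllipse] = field(default_factory=dict)


def ordinate(
    trajectories: Sequence[MAGTrajectory],
    layout: Literal["per-mag", "per-mag-time"] = "per-mag",
) -> OrdinationResult:
    """Mean-centered, unscaled PCA of R² feature vectors.

    ``per-mag`` (default) concatenates each MAG's per-time-point profiles
    into one feature vector, so every point in the ordination is one
    organism; ``per-mag-time`` keeps one row per MAG and time point.  Scores
    carry a deterministic sign convention: the largest-magnitude loading of
    each component is positive.
    """
    if len(trajectories) < 3:
        raise ValueError("ordination needs at least 3 MAGs")
    if layout == "per-mag":
        timepoint_sets = {t.timepoints for t in trajectories}
        if len(timepoint_sets) != 1:
            missing = sorted(
                t.mag_id
                for t in trajectories
                if t.timepoints != max(timepoint_sets, key=len)
            )
            raise ValueError(
                f"MAGs missing time points for concatenated layout: {missing}"
            )
        ids = tuple(t.mag_id for t in trajectories)
        X = np.stack([t.feature_vector() for t in trajectories])
    elif layout == "per-mag-time":
        ids = tuple(
            f"{t.mag_id}@{tp}" for t in trajectories for tp in t.timepoints
        )
        X = np.stack([p.r2 for t in trajectories for p in t.profiles])
    else:
        raise ValueError(f"unknown layout {layout!r}")

    Xc = X - X.mean(axis=0)
    # SVD-based PCA; features already share the R² scale, so no rescaling.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # deterministic sign: largest-|loading| of each component made positive
    for i in range(n_comp):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * s
    total_var = float(np.sum(Xc**2))
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return OrdinationResult(
        mag_ids=ids,
        scores=scores,
        explained_variance_ratio=evr,
        loadings=Vt,
        layout=layout,
    )


def validate_clusters(
    ordination: OrdinationResult,
    labels: Mapping[str, str],
    confidence: float = 0.95,
) -> OrdinationResult:
    """Confidence ellipses of cluster means in PC1/PC2 and pairwise overlap.

    Each cluster with ≥ 2 members gets a standard-error ellipse of its mean
    (sample covariance / n) scaled by the chi-square(2) quantile at the
    requested confidence.  Clusters whose ellipses intersect or contain one
    another are flagged non-distinct.  Singleton clusters have no ellipse and
    are flagged, not treated as errors.
    """
    missing = [m for m in ordination.mag_ids if m not in labels]
    if missing:
        raise ValueError(f"unlabeled MAGs: {missing}")
    scale = stats.chi2.ppf(confidence, df=2)
    pc12 = ordination.scores[:, :2]
    ellipses: dict[str, ConfidenceEllipse] = {}
    for cluster in sorted(set(labels.values())):
        idx = [i for i, m in enumerate(ordination.mag_ids) if labels[m] == cluster]
        if len(idx) < 2:
            continue
        pts = pc12[idx]
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False) / len(idx)
        ellipses[cluster] = ConfidenceEllipse(center, np.atleast_2d(cov), scale)
    return OrdinationResult(
        mag_ids=ordination.mag_ids,
        scores=ordination.scores,
        explained_variance_ratio=ordination.explained_variance_ratio,
        loadings=ordination.loadings,
        layout=ordination.layout,
        cluster_labels=dict(labels),
        ellipses=ellipses,
    )


def ellipses_overlap(a: ConfidenceEllipse, b: ConfidenceEllipse) -> bool:
    """Boundary-intersection / containment test on dense boundary polylines."""
    if a.contains(b.center[None, :]).any() or b.contains(a.center[None, :]).any():
        return True
    return bool(a.contains(b.boundary()).any() or b.contains(a.boundary()).any())


def overlap_verdicts(
    result: OrdinationResult,
) -> dict[tuple[str, str], bool]:
    """Pairwise ellipse-overlap verdicts for every cluster pair."""
    names = sorted(result.ellipses)
    return {
        (x, y): ellipses_overlap(result.ellipses[x], result.ellipses[y])
        for i, x in enumerate(names)
        for y in names[i + 1 :]
    }


@dataclass(frozen=True)
class LifestyleThresholds:
    """Decision thresholds for trophic-lifestyle calls; defaults distilled
    from the expected RIA regimes: exclusive CO₂ fixers sit high (>0.90) and
    stable, organisms on unlabeled carbon sit near natural abundance (≤0.10),
    and gradually rising intermediate RIAs indicate cross-feeding."""

    high: float = 0.90
    low_start: float = 0.75
    unlabeled: float = 0.10
    stable_range: float = 0.10


LIFESTYLES = (
    "strict_autotroph",
    "switching_mixotroph",
    "crossfeeding_incorporator",
    "unlabeled_heterotroph",
)


def classify_lifestyle(
    trajectory: MAGTrajectory | Sequence[float],
    thresholds: LifestyleThresholds | None = None,
) -> tuple[str, str]:
    """Classify a MAG's carbon-utilization lifestyle from its RIA trajectory.

    Returns ``(label, rule)`` where `rule` states which decision fired.
    Rules, in order:

    1. all RIAs > high and range ≤ stable_range → ``strict_autotroph``
    2. final ≥ high and first ≤ low_start → ``switching_mixotroph``
    3. non-decreasing with final in (unlabeled, high) →
       ``crossfeeding_incorporator``
    4. all ≤ unlabeled → ``unlabeled_heterotroph``
    5. otherwise → ``crossfeeding_incorporator`` (fallback for mixed signals)

    The high gate is inclusive in rule 2 so that a trajectory whose final RIA
    sits exactly on the 0.90 grid point (e.g. a true 0.91 snapped to a 5 %
    grid) is still called a switch to autotrophy.
    """
    th = thresholds or LifestyleThresholds()
    ria = np.asarray(
        trajectory.ria if isinstance(trajectory, MAGTrajectory) else trajectory,
        dtype=float,
    )
    if len(ria) < 2:
        raise ValueError("lifestyle classification needs at least 2 time points")
    if np.all(ria > th.high) and ria.max() - ria.min() <= th.stable_range:
        return "strict_autotroph", "high-and-stable"
    if ria[-1] >= th.high and ria[0] <= th.low_start:
        return "switching_mixotroph", "low-start-high-finish"
    if np.all(np.diff(ria) >= 0) and th.unlabeled < ria[-1] < th.high:
        return "crossfeeding_incorporator", "monotone-rise-moderate-finish"
    if np.all(ria <= th.unlabeled):
        return "unlabeled_heterotroph", "near-natural-abundance"
    return "crossfeeding_incorporator", "fallback-mixed-signal"


def ward_clusters(result: OrdinationResult, k: int) -> dict[str, str]:
    """Convenience agglomerative (Ward) clustering of ordination scores into
    a user-chosen number of clusters.  Never selects k automatically —
    cluster definition is the analyst's call; this only mechanizes it."""
    from scipy.cluster.hierarchy import fcluster, linkage

    Z = linkage(result.scores, method="ward")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    return {m: f"cluster_{c}" for m, c in zip(result.mag_ids, assignment)}
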