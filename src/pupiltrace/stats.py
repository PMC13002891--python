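"""Pointwise paired Wilcoxon testing and cluster-based permutation inference.

The family-wise procedure: at every timepoint of the analysis window the two
condition curves are compared across participants with a Wilcoxon
signed-rank test; maximal runs of consecutive pointwise-significant
timepoints with a consistent effect sign form clusters scored by their
summed z (cluster mass); a null distribution of the maximum absolute
cluster mass is built by randomly flipping each participant's condition
assignment, and an observed cluster is significant when its |mass| exceeds
the 95th percentile of that null.

The permutation engine exploits that a paired label swap only flips the sign
of a participant's difference curve: the ranks of |differences| (and hence
each timepoint's null variance) are flip-invariant, so every permutation's
z-series is a single matrix product over precomputed signed ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .data_model import (
    Cluster,
    ClusterTestResult,
    ConditionAverage,
    ValidationError,
)
from .segment import contrast_participants

#: a grid point enters testing only if non-missing in both curves for at
#: least this fraction of participants; rarer points are untestable and
#: break clusters.
MIN_PAIRED_VALID_FRACTION = 0.9

#: minimum number of non-zero paired differences for a testable point.
MIN_NONZERO_DIFFS = 5


@dataclass
class PermConfig:
    n_permutations: int = 500
    pointwise_alpha: float = 0.05
    cluster_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pointwise_alpha < 1 and 0 < self.cluster_alpha < 1):
            raise ValidationError("alphas must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


@dataclass
class PairedCurves:
    """Per-participant mean curves for two conditions on a common grid."""

    participant_ids: list[str]
    curves_a: np.ndarray  # (n_participants, n_points)
    curves_b: np.ndarray
    label_a: str
    label_b: str
    alignment: str | None = None
    grid_start_s: float = 0.0
    rate_hz: float = 50.0

    def __post_init__(self) -> None:
        self.curves_a = np.atleast_2d(np.asarray(self.curves_a, dtype=float))
        self.curves_b = np.atleast_2d(np.asarray(self.curves_b, dtype=float))
        if self.curves_a.shape != self.curves_b.shape:
            raise ValidationError("condition curve matrices must share a shape")
        if self.curves_a.shape[0] != len(self.participant_ids):
            raise ValidationError("one curve row per participant required")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def analysis_window(self) -> tuple[slice, float]:
        """Slice of the grid entering testing, and its start time.

        Stimulus-aligned curves are tested over the 5 s after onset (250
        points at 50 Hz); response-aligned curves over the full +/-3 s
        window; curves with no declared alignment are tested everywhere.
        """
        n = self.curves_a.shape[1]
        if self.alignment == "stimulus":
            start = int(round((0.0 - self.grid_start_s) * self.rate_hz))
            return slice(start, n), 0.0
        return slice(0, n), self.grid_start_s

    def swapped(self) -> "PairedCurves":
        return PairedCurves(
            participant_ids=list(self.participant_ids),
            curves_a=self.curves_b.copy(),
            curves_b=self.curves_a.copy(),
            label_a=self.label_b,
            label_b=self.label_a,
            alignment=self.alignment,
            grid_start_s=self.grid_start_s,
            rate_hz=self.rate_hz,
        )


def pair_condition_averages(avgs: Sequence[ConditionAverage], label_a: str,
                            label_b: str, min_trials: int = 2,
                            alignment: str | None = None
                            ) -> tuple[PairedCurves, list[tuple[str, str]]]:
    """Assemble PairedCurves from per-participant condition averages.

    Participants lacking either curve or the minimum trial count are dropped
    and reported alongside the pairing.
    """
    keep, dropped = contrast_participants(avgs, label_a, label_b, min_trials)
    if not keep:
        raise ValidationError(
            f"no participant qualifies for contrast {label_a} vs {label_b}"
        )
    by_key = {(a.participant_id, a.condition_label): a for a in avgs}
    rows_a = [by_key[(pid, label_a)] for pid in keep]
    rows_b = [by_key[(pid, label_b)] for pid in keep]
    first = rows_a[0]
    pc = PairedCurves(
        participant_ids=keep,
        curves_a=np.vstack([a.curve_mm for a in rows_a]),
        curves_b=np.vstack([b.curve_mm for b in rows_b]),
        label_a=label_a,
        label_b=label_b,
        alignment=first.alignment,
        grid_start_s=-3.0,
        rate_hz=50.0,
    )
    return pc, dropped


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_stats(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Ranks of |d| among non-zero entries, their signs, n, and the null SD.

    Zeros are discarded (Wilcoxon's original rule); tied magnitudes receive
    midranks and the variance gets the standard tie correction
    sum(t^3 - t)/48.
    """
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return np.array([]), np.array([]), 0, 0.0
    ranks = sps.rankdata(np.abs(nz))
    _, counts = np.unique(np.abs(nz), return_counts=True)
    tie_corr = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    return ranks, np.sign(nz), n, float(np.sqrt(var)) if var > 0 else 0.0


def _exact_two_sided_p(w_pos: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the positive-rank sum by enumerating the null.

    Valid for tie-free integer ranks 1..n; the distribution of W+ under the
    null is built by dynamic programming over all 2^n sign assignments.
    """
    ranks_int = np.rint(ranks).astype(int)
    total = int(ranks_int.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks_int:
        counts[r:] = counts[r:] + counts[:-r]  # rhs copy: no overlap hazard
    counts /= counts.sum()
    w = int(round(w_pos))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(diffs: Sequence[float], method: str = "auto"
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Returns ``(z, p_two_sided)`` where z is the normal-approximation score of
    the positive-rank sum (with midranks and tie-corrected variance). With
    ``method="exact"`` -- or ``"auto"`` when n <= 12 and the magnitudes are
    tie-free -- the p value comes from exact enumeration of all sign
    assignments instead; z is always the approximation score, since it is the
    currency of cluster mass. Fewer than 5 non-zero differences make the
    point untestable: ``(0.0, 1.0)``.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    ranks, signs, n, sd = _signed_rank_stats(np.asarray(diffs, dtype=float))
    if n < MIN_NONZERO_DIFFS or sd == 0:
        return 0.0, 1.0
    w_pos = float(ranks[signs > 0].sum())
    mean = n * (n + 1) / 4.0
    z = (w_pos - mean) / sd
    tie_free = len(np.unique(ranks)) == n
    use_exact = method == "exact" or (method == "auto" and n <= 12 and tie_free)
    if use_exact:
        if not tie_free:
            raise ValidationError("exact enumeration requires tie-free magnitudes")
        p = _exact_two_sided_p(w_pos, ranks)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def positive_rank_sum(diffs: Sequence[float]) -> float:
    """The V statistic: sum of ranks of positive differences (zeros dropped)."""
    ranks, signs, _, _ = _signed_rank_stats(np.asarray(diffs, dtype=float))
    return float(ranks[signs > 0].sum()) if len(ranks) else 0.0


# ---------------------------------------------------------------------------
# Vectorised pointwise testing over a curve grid
# ---------------------------------------------------------------------------

@dataclass
class _PointwiseDesign:
    """Flip-invariant precomputation for a paired-difference matrix."""

    signed_ranks: np.ndarray  # (n_participants, n_points); R * sign(d), 0 if excluded
    sd: np.ndarray            # per-point null SD of W+
    testable: np.ndarray      # boolean per point


def _prepare_design(diff: np.ndarray,
                    min_valid_fraction: float = MIN_PAIRED_VALID_FRACTION
                    ) -> _PointwiseDesign:
    n_part, n_pts = diff.shape
    signed = np.zeros_like(diff)
    sd = np.zeros(n_pts)
    testable = np.zeros(n_pts, dtype=bool)
    finite_frac = np.isfinite(diff).mean(axis=0)
    for j in range(n_pts):
        if finite_frac[j] < min_valid_fraction:
            continue
        d = diff[:, j]
        ok = np.isfinite(d) & (d != 0)
        n = int(ok.sum())
        if n < MIN_NONZERO_DIFFS:
            continue
        ranks = sps.rankdata(np.abs(d[ok]))
        _, counts = np.unique(np.abs(d[ok]), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(counts**3 - counts)) / 48.0
        if var <= 0:
            continue
        signed[ok, j] = ranks * np.sign(d[ok])
        sd[j] = np.sqrt(var)
        testable[j] = True
    return _PointwiseDesign(signed_ranks=signed, sd=sd, testable=testable)


def _z_rows(design: _PointwiseDesign, flips: np.ndarray) -> np.ndarray:
    """z-series for each row of +/-1 participant flips: (W+ - mean)/sd.

    Uses W+ - n(n+1)/4 = sum_i flip_i * R_i * sign(d_i) / 2.
    """
    num = flips @ design.signed_ranks  # (n_rows, n_points)
    z = np.zeros_like(num)
    t = design.testable
    z[:, t] = num[:, t] / (2.0 * design.sd[t])
    return z


def pointwise_test(pc: PairedCurves,
                   min_valid_fraction: float = MIN_PAIRED_VALID_FRACTION
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Wilcoxon z and two-sided p at every testable point of the analysis window.

    Untestable points (too many missing participants, fewer than 5 non-zero
    differences, or zero variance) report z = 0, p = 1.
    """
    window, _ = pc.analysis_window()
    diff = (pc.curves_a - pc.curves_b)[:, window]
    design = _prepare_design(diff, min_valid_fraction)
    z = _z_rows(design, np.ones((1, diff.shape[0])))[0]
    p = np.ones_like(z)
    t = design.testable
    p[t] = 2.0 * sps.norm.sf(np.abs(z[t]))
    return z, p


def form_clusters(z_series: np.ndarray, p_series: np.ndarray,
                  pointwise_alpha: float = 0.05) -> list[Cluster]:
    """Maximal runs of consecutive significant points with constant z sign."""
    z = np.asarray(z_series, dtype=float)
    p = np.asarray(p_series, dtype=float)
    if z.shape != p.shape:
        raise ValidationError("z and p series must have equal length")
    sig = p < pointwise_alpha
    key = np.where(sig, np.sign(z).astype(int), 0)
    clusters: list[Cluster] = []
    if not sig.any():
        return clusters
    change = np.flatnonzero(np.diff(key) != 0) + 1
    bounds = np.concatenate([[0], change, [len(key)]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        k = key[lo]
        if k == 0:
            continue
        clusters.append(
            Cluster(start=int(lo), end=int(hi), sign=int(k),
                    mass=float(z[lo:hi].sum()))
        )
    return clusters


def _max_abs_masses(z_rows: np.ndarray, pointwise_alpha: float) -> np.ndarray:
    """Maximum |cluster mass| per row of z-series (0 when no cluster)."""
    crit = sps.norm.isf(pointwise_alpha / 2.0)
    out = np.zeros(z_rows.shape[0])
    for i, z in enumerate(z_rows):
        sig = np.abs(z) > crit
        if not sig.any():
            continue
        key = np.where(sig, np.sign(z).astype(int), 0)
        change = np.flatnonzero(np.diff(key) != 0) + 1
        bounds = np.concatenate([[0], change, [len(key)]])
        cum = np.concatenate([[0.0], np.cumsum(z)])
        best = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if key[lo] == 0:
                continue
            best = max(best, abs(cum[hi] - cum[lo]))
        out[i] = best
    return out


def permutation_null(pc: PairedCurves, cfg: PermConfig) -> np.ndarray:
    """Null distribution of the maximum absolute cluster mass.

    Each permutation independently flips every participant's condition
    assignment with probability 1/2 (for paired curves this is a sign flip of
    the difference curve), recomputes the pointwise z-series and clusters,
    and records the largest |mass| (0 if no cluster forms). Draws come from
    a counter-based Philox stream keyed by the config seed, so results are
    reproducible across runs and platforms.
    """
    window, _ = pc.analysis_window()
    diff = (pc.curves_a - pc.curves_b)[:, window]
    design = _prepare_design(diff)
    rng = np.random.Generator(np.random.Philox(key=cfg.seed))
    flips = rng.integers(0, 2, size=(cfg.n_permutations, diff.shape[0])) * 2 - 1
    z_rows = _z_rows(design, flips.astype(float))
    return _max_abs_masses(z_rows, cfg.pointwise_alpha)


def cluster_significance(clusters: Sequence[Cluster], null_masses: np.ndarray,
                         cluster_alpha: float = 0.05) -> list[Cluster]:
    """Permutation p and significance flag for each observed cluster.

    ``p_perm`` uses the add-one estimator (1 + #{null >= |mass|}) / (N + 1);
    a cluster is significant when |mass| strictly exceeds the empirical
    (1 - cluster_alpha) quantile of the null masses.
    """
    null = np.asarray(null_masses, dtype=float)
    if len(null) == 0:
        raise ValidationError("empty null distribution")
    threshold = float(np.quantile(null, 1.0 - cluster_alpha))
    out = []
    for c in clusters:
        m = abs(c.mass)
        p_perm = (1.0 + float(np.sum(null >= m))) / (len(null) + 1.0)
        out.append(
            Cluster(start=c.start, end=c.end, sign=c.sign, mass=c.mass,
                    p_perm=p_perm, significant=bool(m > threshold),
                    start_ms=c.start_ms, end_ms=c.end_ms)
        )
    return out


def run_cluster_test(pc: PairedCurves, cfg: PermConfig | None = None
                     ) -> ClusterTestResult:
    """Full cluster-based permutation test on a paired-curves contrast.

    Cluster windows are also reported in milliseconds relative to the
    alignment event (half-open, index * 20 ms + window start at 50 Hz).
    """
    cfg = cfg or PermConfig()
    _, window_start_s = pc.analysis_window()
    z, p = pointwise_test(pc)
    clusters = form_clusters(z, p, cfg.pointwise_alpha)
    null = permutation_null(pc, cfg)
    clusters = cluster_significance(clusters, null, cfg.cluster_alpha)
    dt_ms = 1000.0 / pc.rate_hz
    for c in clusters:
        c.start_ms = window_start_s * 1000.0 + c.start * dt_ms
        c.end_ms = window_start_s * 1000.0 + c.end * dt_ms
    return ClusterTestResult(
        label_a=pc.label_a,
        label_b=pc.label_b,
        alignment=pc.alignment,
        window_start_s=window_start_s,
        rate_hz=pc.rate_hz,
        z_series=z,
        p_series=p,
        clusters=clusters,
        null_masses=null,
        n_permutations=cfg.n_permutations,
        pointwise_alpha=cfg.pointwise_alpha,
        cluster_alpha=cfg.cluster_alpha,
        seed=cfg.seed,
        n_participants=pc.n_participants,
    )


# ---------------------------------------------------------------------------
# Behavioral paired tests
# ---------------------------------------------------------------------------

@dataclass
class BehavioralTestReport:
    test_name: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    shapiro_p: float
    n: int
    mean_diff: float


def behavioral_paired_test(x: Sequence[float], y: Sequence[float]
                           ) -> BehavioralTestReport:
    """Paired comparison of per-participant behavioral summaries.

    Normality of the differences is checked with Shapiro-Wilk at alpha .05:
    normal-looking differences get a paired t-test, otherwise a Wilcoxon
    signed-rank test whose statistic is the positive-rank sum V. Constant
    differences yield a degenerate report (no distributional test applies).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(x) < 5:
        raise ValidationError("need at least 5 pairs")
    d = x - y
    if np.ptp(d) == 0:
        return BehavioralTestReport("degenerate", float("nan"), float("nan"),
                                    float("nan"), len(d), float(d.mean()))
    shapiro_p = float(sps.shapiro(d).pvalue)
    if shapiro_p > 0.05:
        t = sps.ttest_rel(x, y)
        return BehavioralTestReport("paired_t", float(t.statistic),
                                    float(t.pvalue), shapiro_p, len(d),
                                    float(d.mean()))
    v = positive_rank_sum(d)
    _, p = wilcoxon_signed_rank(d)
    return BehavioralTestReport("wilcoxon", v, p, shapiro_p, len(d),
                                float(d.mean()))
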