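"""Cluster-based permutation testing of paired 1-D time courses.

The time-course contrast between two within-subject conditions is
tested with the max-statistic cluster permutation scheme: a paired
t-test at every time bin, maximal runs of consecutive same-sign bins
whose |t| exceeds the two-tailed pointwise critical value (the cluster
forming threshold), the signed sum of t within a run as the cluster
mass, and a null distribution of the maximum |cluster mass| obtained by
independently sign-flipping each subject's difference trace.  A cluster
is significant when its |mass| falls beyond the 1 - alpha quantile of
that null, which controls the family-wise error rate over time.

For n subjects with 2**n <= n_permutations the full set of sign
patterns is enumerated and p-values are exact; otherwise random flips
are drawn and the add-one estimator p = (1 + #{null >= |mass|}) /
(1 + n_permutations) is used, which is exact under exchangeability and
never returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ClusterTestConfig",
    "Cluster",
    "ClusterTestResult",
    "pointwise_paired_t",
    "form_clusters",
    "permutation_null",
    "cluster_test",
]

# relative slack when counting null values >= the observed mass, so the
# identity permutation (same statistic, different arithmetic path) is
# always counted
_COUNT_RTOL = 1e-9


@dataclass(frozen=True)
class ClusterTestConfig:
    alpha_forming: float = 0.05      # two-tailed pointwise threshold
    n_permutations: int = 2000
    alpha_cluster: float = 0.05
    seed: int = 0
    enumeration: str = "auto"        # "auto" | "always" | "never"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_forming < 1 and 0 < self.alpha_cluster < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.enumeration not in ("auto", "always", "never"):
            raise ValueError("enumeration must be 'auto', 'always' or 'never'")


@dataclass(frozen=True)
class Cluster:
    start_bin: int
    end_bin: int          # inclusive
    start_ms: float
    end_ms: float
    signed_mass: float
    p: float | None = None


@dataclass
class ClusterTestResult:
    t_series: np.ndarray
    df: int
    forming_threshold: float
    clusters: list[Cluster]
    null_distribution: np.ndarray
    exact: bool
    bin_centers_ms: np.ndarray
    bin_width_ms: float
    uncorrected_sig_windows: list[tuple[float, float]]
    corrected_sig_windows: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "forming_threshold": self.forming_threshold,
            "exact": self.exact,
            "n_permutations": int(self.null_distribution.size - (0 if self.exact else 1)),
            "t_series": [float(v) for v in self.t_series],
            "bin_centers_ms": [float(v) for v in self.bin_centers_ms],
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "signed_mass": c.signed_mass,
                    "p": c.p,
                }
                for c in self.clusters
            ],
            "null_max_mass_q95": float(np.quantile(self.null_distribution, 0.95))
            if self.null_distribution.size
            else None,
            "uncorrected_sig_windows": [list(w) for w in self.uncorrected_sig_windows],
            "corrected_sig_windows": [list(w) for w in self.corrected_sig_windows],
        }


def pointwise_paired_t(matrix_a: np.ndarray, matrix_b: np.ndarray) -> np.ndarray:
    """Paired t statistic at every bin (df = n - 1).

    Bins where the differences have zero variance get +/-inf with the
    sign of the mean difference (0 when the mean is also zero), so a
    constant nonzero difference is always supra-threshold.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0.0
    with np.errstate(invalid="ignore"):
        t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[zero_var & (mean == 0.0)] = 0.0
    return t


def forming_threshold(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical t at the forming alpha, df = n - 1."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))


def form_clusters(
    t_series: np.ndarray,
    n: int,
    cfg: ClusterTestConfig | None = None,
    bin_centers_ms: np.ndarray | None = None,
    bin_width_ms: float = 50.0,
) -> list[Cluster]:
    """Maximal runs of consecutive supra-threshold bins of constant sign.

    The signed mass of a run is the sum of its t values; a sign change
    without a sub-threshold gap starts a new cluster.
    """
    cfg = ClusterTestConfig() if cfg is None else cfg
    t_series = np.asarray(t_series, dtype=float)
    thr = forming_threshold(n, cfg.alpha_forming)
    if bin_centers_ms is None:
        bin_centers_ms = (np.arange(t_series.size) + 0.5) * bin_width_ms
    label = np.zeros(t_series.size, dtype=np.int8)
    label[t_series > thr] = 1
    label[t_series < -thr] = -1
    clusters: list[Cluster] = []
    start = 0
    for i in range(1, t_series.size + 1):
        if i == t_series.size or label[i] != label[start]:
            if label[start] != 0:
                clusters.append(
                    Cluster(
                        start_bin=start,
                        end_bin=i - 1,
                        start_ms=float(bin_centers_ms[start] - bin_width_ms / 2.0),
                        end_ms=float(bin_centers_ms[i - 1] + bin_width_ms / 2.0),
                        signed_mass=float(t_series[start:i].sum()),
                    )
                )
            start = i
    return clusters


def _sign_flip_t(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t series for every sign-flip pattern at once.

    ``d``: (n, bins) difference traces; ``signs``: (P, n) of +/-1.
    Sign flips leave each subject's squared contribution unchanged, so
    only the mean depends on the pattern.
    """
    n = d.shape[0]
    mean = signs @ d / n                      # (P, bins)
    msq = (d * d).mean(axis=0)                # (bins,)
    var = (msq - mean**2) * (n / (n - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    zero = var <= 0.0
    with np.errstate(invalid="ignore"):
        t[zero] = np.sign(mean[zero]) * np.inf
    t[zero & (mean == 0.0)] = 0.0
    return t


def _max_abs_mass_rows(t_rows: np.ndarray, thr: float) -> np.ndarray:
    """Max |cluster mass| per row of a (P, bins) t matrix (0 if none)."""
    p, b = t_rows.shape
    lab = np.zeros((p, b + 1), dtype=np.int8)
    lab[:, :b][t_rows > thr] = 1
    lab[:, :b][t_rows < -thr] = -1
    tp = np.zeros((p, b + 1))
    tp[:, :b] = np.where(lab[:, :b] != 0, t_rows, 0.0)
    flat_l = lab.ravel()
    flat_t = tp.ravel()
    change = np.flatnonzero(np.diff(flat_l) != 0) + 1
    starts = np.concatenate([[0], change])
    run_lab = flat_l[starts]
    sums = np.add.reduceat(flat_t, starts)
    keep = run_lab != 0
    out = np.zeros(p)
    rows = starts[keep] // (b + 1)
    np.maximum.at(out, rows, np.abs(sums[keep]))
    return out


def permutation_null(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    cfg: ClusterTestConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """Null distribution of the maximum |cluster mass| under subject-wise
    sign flips of the difference traces.

    Returns ``(null_values, exact)``; exact means all 2**n patterns were
    enumerated (including the identity), otherwise ``n_permutations``
    random patterns were drawn from the seeded generator.
    """
    cfg = ClusterTestConfig() if cfg is None else cfg
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    d = a - b
    n = d.shape[0]
    thr = forming_threshold(n, cfg.alpha_forming)

    exact = cfg.enumeration == "always" or (
        cfg.enumeration == "auto" and 2**n <= cfg.n_permutations
    )
    if exact:
        patterns = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1) * 2 - 1
        signs = patterns.astype(float)
    else:
        rng = np.random.default_rng(cfg.seed)
        signs = rng.integers(0, 2, size=(cfg.n_permutations, n)).astype(float) * 2 - 1

    # chunk to bound memory for large permutation counts
    out = np.empty(signs.shape[0])
    step = max(1, int(2e6 // max(d.shape[1], 1)))
    for i in range(0, signs.shape[0], step):
        t_rows = _sign_flip_t(d, signs[i : i + step])
        out[i : i + step] = _max_abs_mass_rows(t_rows, thr)
    return out, exact


def cluster_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    cfg: ClusterTestConfig | None = None,
    bin_centers_ms: np.ndarray | None = None,
    bin_width_ms: float = 50.0,
) -> ClusterTestResult:
    """Full cluster-based permutation test of A vs B (paired).

    Cluster p-values compare |mass| against the max-|mass| null; windows
    are reported in ms (bin edges).  ``uncorrected_sig_windows`` are the
    spans where the pointwise test alone is significant.
    """
    cfg = ClusterTestConfig() if cfg is None else cfg
    a = np.asarray(matrix_a, dtype=float)
    n = a.shape[0]
    if bin_centers_ms is None:
        bin_centers_ms = (np.arange(a.shape[1]) + 0.5) * bin_width_ms
    bin_centers_ms = np.asarray(bin_centers_ms, dtype=float)

    t = pointwise_paired_t(matrix_a, matrix_b)
    clusters = form_clusters(t, n, cfg, bin_centers_ms, bin_width_ms)
    null, exact = permutation_null(matrix_a, matrix_b, cfg)

    scored: list[Cluster] = []
    for c in clusters:
        mass = abs(c.signed_mass)
        count = int(np.sum(null >= mass * (1.0 - _COUNT_RTOL)))
        if exact:
            p = count / null.size
        else:
            p = (1 + count) / (1 + null.size)
        scored.append(
            Cluster(c.start_bin, c.end_bin, c.start_ms, c.end_ms, c.signed_mass, p)
        )

    thr = forming_threshold(n, cfg.alpha_forming)
    supra = np.abs(t) > thr
    uncorrected: list[tuple[float, float]] = []
    start = None
    for i in range(t.size + 1):
        if i < t.size and supra[i]:
            if start is None:
                start = i
        elif start is not None:
            uncorrected.append(
                (
                    float(bin_centers_ms[start] - bin_width_ms / 2.0),
                    float(bin_centers_ms[i - 1] + bin_width_ms / 2.0),
                )
            )
            start = None
    corrected = [
        (c.start_ms, c.end_ms) for c in scored if c.p is not None and c.p < cfg.alpha_cluster
    ]
    return ClusterTestResult(
        t_series=t,
        df=n - 1,
        forming_threshold=thr,
        clusters=scored,
        null_distribution=null,
        exact=exact,
        bin_centers_ms=bin_centers_ms,
        bin_width_ms=bin_width_ms,
        uncorrected_sig_windows=uncorrected,
        corrected_sig_windows=corrected,
    )
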