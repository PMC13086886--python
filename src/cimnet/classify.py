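"""Impact classification and representativeness statistics.

Three pieces: Fisher-Jenks natural-breaks classification of CI values
into low/medium/high, a two-group ANOVA comparing each MCA's cells with
the full regional cell population, and a kernel-density overlap
coefficient measuring how representative the MCA network's CI
distribution is of the region's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

CLASS_LABELS_3 = ("Low", "Medium", "High")


@dataclass(frozen=True)
class ClassBreaks:
    """Natural-breaks partition of a value set into k ordered classes.

    ``boundaries`` are the k-1 upper class limits, reported as the
    maximum data value of each lower class; classes are right-closed
    (x <= b_1 is class 0, b_1 < x <= b_2 is class 1, ...).
    """

    k: int
    boundaries: tuple[float, ...]
    data_min: float
    data_max: float
    class_labels: tuple[str, ...]
    within_class_sse: float

    def __post_init__(self) -> None:
        bs = self.boundaries
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("boundaries must be strictly increasing")


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group ANOVA of MCA cells against the regional cell population."""

    F: float
    p: float
    direction: str  # above | below | none
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class OverlapResult:
    """Percent overlap of two estimated frequency distributions."""

    overlap_pct: float
    method: str  # kde | histogram
    grid_n: int
    bandwidth_rule: str


# ---------------------------------------------------------------------------
# Fisher-Jenks natural breaks


def _prefix_sse(values: np.ndarray):
    """Return sse(a, b) = within-class sum of squared deviations of
    values[a:b], as a closure over prefix sums."""
    s = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(a: int | np.ndarray, b: int | np.ndarray):
        n = b - a
        tot = s[b] - s[a]
        return (s2[b] - s2[a]) - tot * tot / n

    return sse


def jenks_breaks(values, k: int) -> ClassBreaks:
    """Exact Fisher-Jenks optimum by dynamic programming.

    Partitions the sorted multiset into ``k`` contiguous classes
    minimising the total within-class sum of squared deviations. Among
    cost-ties the partition with the smallest lowest boundary (then the
    next, lexicographically) is returned. O(k n^2) time.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    n_distinct = np.unique(values).size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")
    sse = _prefix_sse(values)

    # a cut inside a run of equal values would repeat a boundary value;
    # only cuts between distinct neighbours are admissible
    cut_ok = np.ones(n + 1, dtype=bool)
    cut_ok[1:n] = values[1:] != values[:-1]

    # suffix DP: cost[j][i] = minimal SSE partitioning values[i:] into j classes,
    # so cuts can be reconstructed left-to-right taking the smallest tie.
    idx = np.arange(n + 1)
    cost = np.full((k + 1, n + 1), np.inf)
    cost[0, n] = 0.0
    cost[1, :n] = sse(idx[:n], n)

    def _candidates(j: int, i: int) -> tuple[np.ndarray, np.ndarray]:
        m = np.arange(i + 1, n - j + 2)
        cand = sse(i, m) + cost[j - 1, m]
        cand[~cut_ok[m]] = np.inf
        return m, cand

    for j in range(2, k + 1):
        for i in range(0, n - j + 1):
            cost[j, i] = _candidates(j, i)[1].min()

    # greedy left-to-right reconstruction, smallest cut on ties
    rel_tol = 1e-9
    cuts: list[int] = []
    i = 0
    for j in range(k, 1, -1):
        total = cost[j, i]
        m, cand = _candidates(j, i)
        ok = cand <= total + rel_tol * (1.0 + abs(total))
        m_star = int(m[np.argmax(ok)])
        cuts.append(m_star)
        i = m_star
    boundaries = tuple(float(values[c - 1]) for c in cuts)
    labels = CLASS_LABELS_3 if k == 3 else tuple(f"class_{j}" for j in range(k))
    total_sse = 0.0
    edges = [0, *cuts, n]
    for a, b in zip(edges[:-1], edges[1:]):
        total_sse += float(sse(a, b))
    return ClassBreaks(
        k=k,
        boundaries=boundaries,
        data_min=float(values[0]),
        data_max=float(values[-1]),
        class_labels=labels,
        within_class_sse=total_sse,
    )


def assign_class(x: float, breaks: ClassBreaks) -> str:
    """Label a value using right-closed class intervals.

    Values below the data minimum clamp to the lowest class; values above
    the data maximum clamp to the highest.
    """
    for j, b in enumerate(breaks.boundaries):
        if x <= b:
            return breaks.class_labels[j]
    return breaks.class_labels[breaks.k - 1]


# ---------------------------------------------------------------------------
# ANOVA comparison


def compare_mca_to_region(
    mca_values, region_values, alpha: float = 0.05
) -> ComparisonResult:
    """One-way two-group ANOVA: MCA cells vs all regional cells.

    The regional sample is the full region inclusive of MCA cells. The
    direction (above/below) is reported only when p < alpha. A zero
    pooled variance with unequal means is flagged degenerate (p = 0).
    """
    a = np.asarray(mca_values, dtype=float)
    b = np.asarray(region_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have size >= 2")
    diff = a.mean() - b.mean()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if diff == 0:
            return ComparisonResult(F=0.0, p=1.0, direction="none", significant=False)
        return ComparisonResult(
            F=np.inf,
            p=0.0,
            direction="above" if diff > 0 else "below",
            significant=True,
            degenerate=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # f_oneway warns on near-constant input
        F, p = stats.f_oneway(a, b)
    F, p = float(F), float(p)
    significant = p < alpha
    if significant:
        direction = "above" if diff > 0 else "below"
    else:
        direction = "none"
    return ComparisonResult(F=F, p=p, direction=direction, significant=significant)


# ---------------------------------------------------------------------------
# distribution overlap


def _bw_nrd0(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (R's bw.nrd0)."""
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    lo = min(sd, iqr / 1.349)
    if lo == 0:
        lo = sd or abs(x[0]) or 1.0
    return 0.9 * lo * n ** (-0.2)


def _kde_on_grid(x: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    # block over data to bound memory at ~grid_n * block doubles
    dens = np.zeros(grid.size)
    block = 4096
    for start in range(0, x.size, block):
        chunk = x[start : start + block]
        z = (grid[:, None] - chunk[None, :]) / h
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    return dens / (x.size * h * np.sqrt(2 * np.pi))


def distribution_overlap(a, b, grid_n: int = 1024) -> OverlapResult:
    """Percent overlap of two frequency distributions.

    Gaussian-kernel densities with per-sample normal-reference (nrd0)
    bandwidths are evaluated on a common grid spanning both samples
    padded by 3 bandwidths, and 100 * integral of min(f_a, f_b) is
    computed by the trapezoidal rule. Samples with zero variance fall
    back to a shared-bin histogram estimate (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have size >= 2")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        warnings.warn(
            "zero-variance sample: falling back to histogram overlap", stacklevel=2
        )
        lo = min(a.min(), b.min()) - 0.5
        hi = max(a.max(), b.max()) + 0.5
        edges = np.linspace(lo, hi, grid_n + 1)
        fa, _ = np.histogram(a, bins=edges, density=True)
        fb, _ = np.histogram(b, bins=edges, density=True)
        width = edges[1] - edges[0]
        pct = 100.0 * float(np.minimum(fa, fb).sum() * width)
        return OverlapResult(pct, method="histogram", grid_n=grid_n, bandwidth_rule="nrd0")
    ha, hb = _bw_nrd0(a), _bw_nrd0(b)
    pad = 3.0 * max(ha, hb)
    grid = np.linspace(min(a.min(), b.min()) - pad, max(a.max(), b.max()) + pad, grid_n)
    fa = _kde_on_grid(a, ha, grid)
    fb = _kde_on_grid(b, hb, grid)
    pct = 100.0 * float(np.trapezoid(np.minimum(fa, fb), grid))
    return OverlapResult(
        overlap_pct=min(pct, 100.0),
        method="kde",
        grid_n=grid_n,
        bandwidth_rule="nrd0",
    )
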