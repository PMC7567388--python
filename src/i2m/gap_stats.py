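"""Replica-technique gap bookkeeping and rank-based statistics.

Each crown specimen is sectioned mesiodistally (MD) and buccolingually
(BL) at the midline; on every section the silicone-film thickness is
read at the marginal area (MA), axial area (AA) and axio-occlusal angle
(AOA) on both lateral sides, plus once at the occlusal area (OA) on the
midline. That yields 4 MA + 4 AA + 4 AOA + 2 OA = 14 records per
specimen; MA records are the marginal gap, the rest the internal gap.

Thickness populations are strongly right-skewed, so the analysis battery
is rank-based: Mann-Whitney U (MD vs BL surfaces), Friedman across the
four point types, and pairwise Wilcoxon signed-rank contrasts. Exact
small-sample p-values are computed from the full null distributions
(count recurrences); large samples and ties fall back to tie-corrected
normal approximations with continuity correction. A lognormal gap
simulator makes the whole stage testable without microscope data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POINTS",
    "SECTIONS",
    "build_schema",
    "schema_counts",
    "simulate_gaps",
    "describe",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman",
    "normality_screen",
    "analyze_gaps",
]

POINTS = ("MA", "AA", "AOA", "OA")
SECTIONS = ("MD", "BL")
LATERAL = {"MD": ("mesial", "distal"), "BL": ("buccal", "lingual")}

#: lognormal medians (um) per point type; chosen so the simulated area
#: means echo the magnitudes reported for replica measurements of
#: 3D-printed interim crowns (MA mean ~ 133 um, OA mean ~ 256 um).
DEFAULT_MEDIANS = {"MA": 86.0, "AA": 110.0, "AOA": 110.0, "OA": 245.0}
#: lognormal shape parameters (sigma of log-thickness) per point type.
DEFAULT_SIGMAS = {"MA": 0.93, "AA": 0.55, "AOA": 0.55, "OA": 0.30}


def _category(point: str) -> str:
    return "marginal" if point == "MA" else "internal"


def build_schema(n_specimens: int) -> pd.DataFrame:
    """Empty measurement table: one row per protocol slot.

    Per specimen and section: MA/AA/AOA on each of the two lateral
    directions plus a single midline OA, giving 14 rows per specimen.
    """
    if n_specimens < 0:
        raise ValueError("n_specimens must be >= 0")
    rows = []
    for spec_id in range(1, n_specimens + 1):
        for section in SECTIONS:
            for direction in LATERAL[section]:
                for point in ("MA", "AA", "AOA"):
                    rows.append((spec_id, section, direction, point, np.nan))
            rows.append((spec_id, section, "midline", "OA", np.nan))
    table = pd.DataFrame(
        rows, columns=["specimen", "section", "direction", "point", "thickness_um"]
    )
    table["category"] = table["point"].map(_category)
    return table


def schema_counts(table: pd.DataFrame) -> dict[str, int]:
    """Record counts by gap category: marginal / internal / total."""
    cat = table["point"].map(_category)
    marginal = int((cat == "marginal").sum())
    internal = int((cat == "internal").sum())
    return {"marginal": marginal, "internal": internal, "total": marginal + internal}


def simulate_gaps(
    schema: pd.DataFrame | int,
    medians: dict[str, float] | None = None,
    sigmas: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill a schema with lognormal thicknesses, seeded and reproducible.

    ``thickness ~ Lognormal(log median_point, sigma_point)``; with
    dispersion 0 every thickness equals its point-type median.
    """
    if isinstance(schema, (int, np.integer)):
        schema = build_schema(int(schema))
    medians = {**DEFAULT_MEDIANS, **(medians or {})}
    sigmas = {**DEFAULT_SIGMAS, **(sigmas or {})}
    for point in POINTS:
        if medians[point] <= 0:
            raise ValueError(f"median for {point} must be > 0")
        if sigmas[point] < 0:
            raise ValueError(f"sigma for {point} must be >= 0")
    rng = np.random.default_rng(seed)
    table = schema.copy()
    mu = table["point"].map(lambda p: np.log(medians[p])).to_numpy(float)
    sg = table["point"].map(sigmas).to_numpy(float)
    table["thickness_um"] = np.exp(mu + sg * rng.standard_normal(len(table)))
    if "category" not in table.columns:
        table["category"] = table["point"].map(_category)
    return table


def describe(table: pd.DataFrame, group_by: str = "category") -> pd.DataFrame:
    """Mean, SD (n-1), median and interquartile range per group.

    ``group_by`` is ``"category"`` (marginal/internal/total),
    ``"point"`` or ``"point_section"``. Quartiles use linear
    interpolation; the IQR is reported both as the width ``q3 - q1`` and
    as the (q1, q3) pair. Groups with a single value report SD as
    missing; empty groups are omitted with a warning.
    """
    table = table.dropna(subset=["thickness_um"])
    if group_by == "category":
        work = table.copy()
        work["group"] = work["point"].map(_category)
        groups = {name: g["thickness_um"] for name, g in work.groupby("group")}
        groups["total"] = work["thickness_um"]
    elif group_by == "point":
        groups = {name: g["thickness_um"] for name, g in table.groupby("point")}
    elif group_by == "point_section":
        groups = {
            f"{p}_{s}": g["thickness_um"]
            for (p, s), g in table.groupby(["point", "section"])
        }
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            warnings.warn(f"group {name!r} is empty; omitted")
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append(
            {
                "group": name,
                "n": x.size,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else np.nan,
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
            }
        )
    if not rows:
        raise ValueError("no nonempty groups")
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# rank tests


@dataclass
class MannWhitneyResult:
    u_x: float
    u_y: float
    p_value: float
    method: str


@dataclass
class WilcoxonResult:
    w_plus: float
    w_minus: float
    statistic: float  # min(W+, W-)
    p_value: float
    method: str
    n_used: int


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class NormalityResult:
    statistic: float
    p_value: float


def _u_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Null counts of the Mann-Whitney U statistic (no ties).

    ``N(u; i, j) = N(u - j; i - 1, j) + N(u; i, j - 1)`` -- the number of
    orderings of i x's among j y's with U = u. Total is C(n1+n2, n1).
    """
    max_u = n1 * n2
    c = np.zeros((n1 + 1, n2 + 1, max_u + 1), dtype=np.int64)
    c[0, :, 0] = 1
    c[:, 0, 0] = 1
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            c[i, j] = c[i, j - 1]
            c[i, j, j:] += c[i - 1, j, : max_u + 1 - j]
    return c[n1, n2]


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test from mid-rank sums.

    Exact p-values come from the full null distribution when both
    samples have at most 10 observations and there are no ties;
    otherwise a normal approximation with tie-corrected variance and
    continuity correction is used. ``u_x + u_y == n1 * n2`` always.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u_x = r1 - n1 * (n1 + 1) / 2
    u_y = n1 * n2 - u_x

    _unique, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if _unique.size == 1:
        warnings.warn("all values identical across both samples; p = 1")
        return MannWhitneyResult(u_x, u_y, 1.0, "degenerate")

    if mode == "exact" and has_ties:
        raise ValueError("exact mode is only defined without ties")
    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and n1 <= 10 and n2 <= 10
    )
    if use_exact:
        dist = _u_count_distribution(n1, n2)
        total = dist.sum()
        u_min = int(round(min(u_x, u_y)))
        count_le = int(dist[: u_min + 1].sum())
        p = min(1.0, 2.0 * count_le / total)
        return MannWhitneyResult(u_x, u_y, float(p), "exact")

    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("zero rank variance; p = 1")
        return MannWhitneyResult(u_x, u_y, 1.0, "degenerate")
    mean = n1 * n2 / 2.0
    z = (abs(u_x - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MannWhitneyResult(u_x, u_y, float(p), "normal")


def _signed_rank_distribution(n: int) -> np.ndarray:
    """Null counts of W+ over the 2^n sign patterns (ranks 1..n)."""
    total = n * (n + 1) // 2
    c = np.zeros(total + 1, dtype=np.int64)
    c[0] = 1
    for r in range(1, n + 1):
        c[r:] = c[r:] + c[:-r]
    return c


def wilcoxon_signed_rank(differences, mode: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |d| are mid-ranked. Exact enumeration
    of the 2^n sign patterns (via the rank-sum count recurrence) when
    n <= 12 without ties in |d|, else a tie-corrected normal
    approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1")
        return WilcoxonResult(0.0, 0.0, 0.0, 1.0, "degenerate", 0)
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    n = d.size
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    _unique, tie_counts = np.unique(absd, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if mode == "exact" and has_ties:
        raise ValueError("exact mode is only defined without ties in |d|")
    use_exact = mode == "exact" or (mode == "auto" and not has_ties and n <= 12)
    if use_exact:
        dist = _signed_rank_distribution(n)
        w_int = int(round(w))
        count_le = int(dist[: w_int + 1].sum())
        p = min(1.0, 2.0 * count_le / 2**n)
        return WilcoxonResult(w_plus, w_minus, w, float(p), "exact", n)

    mean = n * (n + 1) / 4.0
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        warnings.warn("zero rank variance; p = 1")
        return WilcoxonResult(w_plus, w_minus, w, 1.0, "degenerate", n)
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return WilcoxonResult(w_plus, w_minus, w, float(p), "normal", n)


def friedman(matrix) -> FriedmanResult:
    """Friedman chi-square test on a complete block x treatment matrix.

    Within-block mid-ranks, tie-corrected statistic, df = k - 1, upper
    chi-square tail. A matrix that is constant within every block gives
    statistic 0 and p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    n, k = m.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 treatments and >= 2 blocks")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete matrix: non-finite entries")

    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)

    tie_term = 0.0
    for row in m:
        _u, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return FriedmanResult(0.0, k - 1, 1.0)
    stat = stat / correction
    stat = max(stat, 0.0)
    return FriedmanResult(float(stat), k - 1, float(stats.chi2.sf(stat, k - 1)))


def normality_screen(sample) -> NormalityResult:
    """D'Agostino-style omnibus normality test (skewness + kurtosis).

    Advisory only: the analysis battery always proceeds with rank tests
    regardless of the outcome. Requires n >= 8.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"normality screen needs n >= 8, got {x.size}")
    stat, p = stats.normaltest(x)
    return NormalityResult(float(stat), float(p))


# ---------------------------------------------------------------------------
# analysis battery


def specimen_point_means(table: pd.DataFrame) -> pd.DataFrame:
    """Specimen x point-type matrix of mean thicknesses (blocks for
    Friedman / pairs for Wilcoxon)."""
    pivot = table.pivot_table(
        index="specimen", columns="point", values="thickness_um", aggfunc="mean"
    )
    return pivot[list(POINTS)]


def analyze_gaps(table: pd.DataFrame, bonferroni: bool = False) -> dict:
    """The full statistical battery on one gap table.

    Descriptives by category and point type, a normality screen, MD-vs-BL
    Mann-Whitney per point type, Friedman across the four point types on
    specimen means, and pairwise Wilcoxon point contrasts (unadjusted by
    default; Bonferroni on request).
    """
    table = table.dropna(subset=["thickness_um"])
    out: dict = {
        "counts": schema_counts(table),
        "by_category": describe(table, "category").to_dict(orient="index"),
        "by_point": describe(table, "point").to_dict(orient="index"),
    }
    norm = normality_screen(table["thickness_um"])
    out["normality"] = {"statistic": norm.statistic, "p_value": norm.p_value}

    md_bl = {}
    for point in POINTS:
        sub = table[table["point"] == point]
        x = sub.loc[sub["section"] == "MD", "thickness_um"].to_numpy()
        y = sub.loc[sub["section"] == "BL", "thickness_um"].to_numpy()
        if x.size and y.size:
            res = mann_whitney_u(x, y)
            md_bl[point] = {"u": res.u_x, "p_value": res.p_value, "method": res.method}
    out["md_vs_bl"] = md_bl

    means = specimen_point_means(table).dropna()
    if len(means) >= 2:
        fr = friedman(means.to_numpy())
        out["friedman"] = {
            "statistic": fr.statistic,
            "df": fr.df,
            "p_value": fr.p_value,
        }
        pairs = {}
        names = list(means.columns)
        n_pairs = len(names) * (len(names) - 1) // 2
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                res = wilcoxon_signed_rank(
                    means[a].to_numpy() - means[b].to_numpy()
                )
                p = res.p_value * (n_pairs if bonferroni else 1)
                pairs[f"{a}_vs_{b}"] = {
                    "w": res.statistic,
                    "p_value": min(1.0, p),
                    "method": res.method,
                }
        out["pairwise_wilcoxon"] = pairs
    return out
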