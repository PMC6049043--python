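"""Group statistics on subjects x 100-node tract-profile data.

Three layers, mirroring common practice in tractometry studies of two
reading groups:

1. Per tract, a repeated-measures (split-plot) ANCOVA of the FA profile:
   Nodes as the within-subject factor (J = 100 levels), Group between
   subjects, with Age (months) and acquisition Protocol as covariates and
   the Group*Age / Group*Protocol interactions. Within-subject F statistics
   use the sphericity-assumed univariate (trace) form on an orthonormal
   node contrast, giving the familiar df = (J-1, (J-1)*(N-p)).
2. Node-wise unpaired t tests with family-wise-error control via the
   permutation null of the maximum run of same-direction suprathreshold
   nodes (group labels shuffled).
3. Node-wise (partial) correlations between FA and behavioral measures,
   BH-FDR corrected per tract per measure, summarized over contiguous
   significant clusters (r_avg, p_fdr_avg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

WITHIN_TERMS = (
    "Nodes",
    "Nodes:Group",
    "Nodes:Age",
    "Nodes:Protocol",
    "Nodes:Group:Age",
    "Nodes:Group:Protocol",
)
BETWEEN_TERMS = ("Group", "Age", "Protocol", "Group:Age", "Group:Protocol")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ProfileDataset:
    """FA profiles for one tract plus subject covariates.

    ``fa``: (N subjects x J nodes) matrix, no missing values (subjects with
    an absent tract are dropped before construction, never imputed).
    ``covariates``: DataFrame with columns ``group`` (2 levels), ``age``
    (months), ``protocol`` (2 levels) and optionally ``digit_span``.
    ``behavior``: optional DataFrame of named behavioral measures.
    """

    fa: np.ndarray
    covariates: pd.DataFrame
    behavior: pd.DataFrame | None = None
    tract: str = ""

    def __post_init__(self):
        self.fa = np.asarray(self.fa, dtype=float)
        if self.fa.ndim != 2:
            raise ValueError("fa must be (subjects x nodes)")
        if self.fa.shape[0] != len(self.covariates):
            raise ValueError("covariate table does not match subject count")
        if self.fa.shape[0] < 4:
            raise ValueError("need at least 4 subjects")
        if np.isnan(self.fa).any():
            raise ValueError("missing node values are not allowed; drop the subject")
        for col in ("group", "age", "protocol"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates must include {col!r}")

    @property
    def n_subjects(self) -> int:
        return self.fa.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.fa.shape[1]

    @property
    def group_indicator(self) -> np.ndarray:
        """Boolean mask of membership in the first (sorted) group level."""
        levels = np.sort(self.covariates["group"].unique())
        if len(levels) != 2:
            raise ValueError("group must have exactly 2 levels")
        return (self.covariates["group"] == levels[0]).to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long-format (subject, tract, node, fa) table."""
        n, j = self.fa.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), j),
                "tract": self.tract,
                "node": np.tile(np.arange(1, j + 1), n),
                "fa": self.fa.ravel(),
            }
        )


@dataclass
class TermResult:
    """One ANCOVA term: F, degrees of freedom, p, partial eta squared."""

    term: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


@dataclass
class ClusterResult:
    """A contiguous run of same-direction suprathreshold nodes.

    ``direction`` is +1 when group 1 (first sorted level) exceeds group 2
    over the run, -1 for the reverse. Node indices are 1-based inclusive.
    """

    direction: int
    start: int
    end: int
    size: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class CorrelationCluster:
    """Contiguous run of BH-significant node-wise correlations."""

    start: int
    end: int
    r_avg: float
    p_fdr_avg: float
    covariates: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# repeated-measures ANCOVA
# ---------------------------------------------------------------------------


def _sum_to_zero(series: pd.Series, name: str) -> np.ndarray:
    levels = np.sort(series.unique())
    if len(levels) != 2:
        raise ValueError(f"{name} must have exactly 2 levels, got {len(levels)}")
    return np.where(series.to_numpy() == levels[0], 1.0, -1.0)


def between_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Between-subject design: intercept, Group, Age, Protocol and the
    Group*Age / Group*Protocol interactions, under sum-to-zero coding with
    centered age (so main effects stay interpretable next to interactions).
    """
    g = _sum_to_zero(covariates["group"], "group")
    age = covariates["age"].to_numpy(dtype=float)
    age = age - age.mean()
    prot = _sum_to_zero(covariates["protocol"], "protocol")
    X = np.column_stack([np.ones(len(g)), g, age, prot, g * age, g * prot])
    names = ["Intercept", "Group", "Age", "Protocol", "Group:Age", "Group:Protocol"]
    # diagnose singular designs with the offending column's name
    for j, name in enumerate(names[1:], start=1):
        if np.allclose(X[:, j], X[:, j].mean()):
            raise ValueError(f"singular design: column {name!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular between-subject design (collinear columns)")
    return X, names


def _node_contrast(j: int) -> np.ndarray:
    """Orthonormal (J x J-1) contrast spanning the space orthogonal to 1."""
    q, _ = np.linalg.qr(np.ones((j, 1)), mode="complete")
    return q[:, 1:]


def rm_ancova(d: ProfileDataset, alpha_family: float | None = None) -> list[TermResult]:
    """Split-plot ANCOVA of the profile matrix, Type III sums of squares.

    Within-subject terms (Nodes and Nodes x each between term) use the
    sphericity-assumed univariate statistic on an orthonormal node contrast:

        F = [tr(H) / (df_term * (J-1))] / [tr(E) / ((N-p) * (J-1))]

    giving df = (J-1, (J-1)*(N-p)). Between-subject terms are tested on the
    node means with df = (1, N-p). Partial eta squared is
    tr(H) / (tr(H) + tr(E)) per term.
    """
    Y = d.fa
    n, j = Y.shape
    if j < 2:
        raise ValueError("need at least 2 nodes")
    X, names = between_design(d.covariates)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than design columns ({p})")

    XtX_inv = np.linalg.inv(X.T @ X)
    C = _node_contrast(j)

    results: list[TermResult] = []

    # within-subject: project onto the node contrast
    Yc = Y @ C
    B = XtX_inv @ X.T @ Yc
    resid = Yc - X @ B
    trE = float(np.sum(resid**2))
    df2_within = (j - 1) * (n - p)
    for idx, name in enumerate(names):
        trH = float(B[idx] @ B[idx]) / XtX_inv[idx, idx]
        F = (trH / (j - 1)) / (trE / df2_within)
        term = "Nodes" if name == "Intercept" else f"Nodes:{name}"
        results.append(
            TermResult(
                term=term,
                F=F,
                df1=j - 1,
                df2=df2_within,
                p=float(sps.f.sf(F, j - 1, df2_within)),
                eta_p2=trH / (trH + trE),
            )
        )

    # between-subject: node means
    ybar = Y.mean(axis=1)
    b = XtX_inv @ X.T @ ybar
    sse = float(np.sum((ybar - X @ b) ** 2))
    for idx, name in enumerate(names):
        if name == "Intercept":
            continue
        ssh = float(b[idx] ** 2) / XtX_inv[idx, idx]
        F = ssh / (sse / (n - p))
        results.append(
            TermResult(
                term=name,
                F=F,
                df1=1,
                df2=n - p,
                p=float(sps.f.sf(F, 1, n - p)),
                eta_p2=ssh / (ssh + sse),
            )
        )
    return results


def term_table(results: list[TermResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p, "eta_p2": r.eta_p2}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# summary-statistic ANOVA (behavioral tables reported as mean/SD per group)
# ---------------------------------------------------------------------------


def two_group_anova_from_summary(m1, sd1, n1, m2, sd2, n2) -> tuple[float, float]:
    """One-way two-group ANOVA (F, partial eta squared) from summaries.

    Pooled variance s2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    F = (m1-m2)^2 / (s2 (1/n1 + 1/n2)); eta_p2 = F / (F + n1 + n2 - 2).
    Identical to the squared pooled two-sample t.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    s2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if s2 == 0:
        if m1 == m2:
            return 0.0, 0.0
        raise ValueError("zero pooled variance with unequal means: F is infinite")
    F = (m1 - m2) ** 2 / (s2 * (1.0 / n1 + 1.0 / n2))
    return float(F), float(F / (F + n1 + n2 - 2))


# ---------------------------------------------------------------------------
# node-wise t tests and max-cluster-size permutation correction
# ---------------------------------------------------------------------------


def _pooled_t(y: np.ndarray, in_g1: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; positive when group1 > group2."""
    n1 = int(in_g1.sum())
    n2 = y.shape[0] - n1
    y1, y2 = y[in_g1], y[~in_g1]
    m1, m2 = y1.mean(axis=0), y2.mean(axis=0)
    ss = ((y1 - m1) ** 2).sum(axis=0) + ((y2 - m2) ** 2).sum(axis=0)
    s2 = ss / (n1 + n2 - 2)
    denom = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    # zero-variance nodes (up to float rounding) give t = 0 by convention
    floor = 1e-12 * (np.abs(m1) + np.abs(m2) + 1e-300)
    ok = denom > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(ok, (m1 - m2) / np.where(ok, denom, 1.0), 0.0)
    return t


def nodewise_ttest(d: ProfileDataset) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired pooled t per node (no covariates); two-sided p, df = N-2."""
    in_g1 = d.group_indicator
    if in_g1.sum() < 2 or (~in_g1).sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    t = _pooled_t(d.fa, in_g1)
    p = 2 * sps.t.sf(np.abs(t), d.n_subjects - 2)
    return t, p


def _max_run(mask: np.ndarray) -> np.ndarray:
    """Length of the longest True run per row of a 2-D boolean array."""
    mask = np.atleast_2d(mask)
    c = mask.astype(np.int64).cumsum(axis=1)
    # cumsum value frozen at the last False resets the running count
    resets = np.maximum.accumulate(np.where(mask, 0, c), axis=1)
    return (c - resets).max(axis=1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) 0-based inclusive index pairs of True runs in 1-D mask."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def _permutation_indicators(n: int, n1: int, n_perm: int, rng: np.random.Generator):
    """Group-1 membership indicators for permuted labelings.

    Enumerates all label assignments exactly when fewer than ``n_perm``
    exist (with a warning); otherwise draws ``n_perm`` random shuffles.
    Returns (indicators, exact_flag).
    """
    total = comb(n, n1)
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct labelings; enumerating exactly", stacklevel=3
        )
        ind = np.zeros((total, n), dtype=bool)
        for r, cols in enumerate(combinations(range(n), n1)):
            ind[r, list(cols)] = True
        return ind, True
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    ind = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(ind, order, True, axis=1)
    return ind, False


def _t_for_indicators(y: np.ndarray, ind: np.ndarray) -> np.ndarray:
    """Pooled t for many labelings at once. y: (N, J); ind: (R, N) -> (R, J)."""
    n, _ = y.shape
    n1 = int(ind[0].sum())
    n2 = n - n1
    tot = y.sum(axis=0)
    tot2 = (y**2).sum(axis=0)
    s1 = ind @ y
    q1 = ind @ (y**2)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = q1 - n1 * m1**2
    ss2 = (tot2 - q1) - n2 * m2**2
    s2 = (ss1 + ss2) / (n - 2)
    denom = np.sqrt(np.clip(s2, 0, None) * (1.0 / n1 + 1.0 / n2))
    floor = 1e-12 * (np.abs(m1) + np.abs(m2) + 1e-300)
    ok = denom > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(ok, (m1 - m2) / np.where(ok, denom, 1.0), 0.0)
    return t


def permutation_cluster_test(
    d: ProfileDataset,
    n_perm: int = 10000,
    node_alpha: float = 0.05,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Directional max-cluster-size permutation test on node-wise t values.

    Observed clusters are maximal runs of adjacent nodes whose one-tailed
    pooled-t p-value is below ``node_alpha`` in the same direction. For each
    direction (group1 > group2 and the reverse) the null is the distribution
    of the maximum same-direction run length over group-label shuffles;
    cluster p = (1 + #{perm max >= observed size}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    in_g1 = d.group_indicator
    n, n1 = d.n_subjects, int(in_g1.sum())
    df = n - 2
    tcrit = sps.t.ppf(1 - node_alpha, df)

    t_obs = _pooled_t(d.fa, in_g1)
    rng = np.random.default_rng(seed)
    ind, exact = _permutation_indicators(n, n1, n_perm, rng)
    t_perm = _t_for_indicators(d.fa, ind)
    n_eff = ind.shape[0]

    clusters: list[ClusterResult] = []
    for direction in (1, -1):
        obs_mask = t_obs > tcrit if direction == 1 else t_obs < -tcrit
        perm_mask = t_perm > tcrit if direction == 1 else t_perm < -tcrit
        null_max = _max_run(perm_mask)
        for start, end in _runs(obs_mask):
            size = end - start + 1
            if exact:
                pval = float(np.mean(null_max >= size))
            else:
                pval = float((1 + np.sum(null_max >= size)) / (1 + n_eff))
            clusters.append(
                ClusterResult(direction=direction, start=start + 1, end=end + 1, size=size, p=pval)
            )
    return clusters


# ---------------------------------------------------------------------------
# node-wise (partial) correlations with BH-FDR
# ---------------------------------------------------------------------------


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) on [1, Z]."""
    X = np.column_stack([np.ones(y.shape[0]), Z]) if Z.size else np.ones((y.shape[0], 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def nodewise_correlation(
    d: ProfileDataset,
    measure,
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-node correlation of FA with a behavioral measure.

    With covariates, both the node FA values and the measure are
    residualized on them (plus an intercept) and Pearson correlation is
    taken on the residuals; p from t with df = N - 2 - k. An empty covariate
    list gives the plain Pearson correlation. Returns a DataFrame with
    columns node, r, p, p_fdr (BH-adjusted across nodes).
    """
    if isinstance(measure, str):
        if d.behavior is None or measure not in d.behavior.columns:
            raise ValueError(f"measure {measure!r} not in behavior table")
        m = d.behavior[measure].to_numpy(dtype=float)
    else:
        m = np.asarray(measure, dtype=float)
    if m.std() == 0:
        raise ValueError("measure is constant; correlation undefined")
    k = len(covariates)
    n = d.n_subjects
    if n - 2 - k < 2:
        raise ValueError("too few subjects for the requested covariates")

    cols = []
    for c in covariates:
        if c in d.covariates.columns:
            v = d.covariates[c]
        elif d.behavior is not None and c in d.behavior.columns:
            v = d.behavior[c]
        else:
            raise ValueError(f"covariate {c!r} not found")
        if v.dtype == object:
            v = pd.factorize(v)[0]
        cols.append(np.asarray(v, dtype=float))
    Z = np.column_stack(cols) if cols else np.empty((n, 0))

    fa_res = _residualize(d.fa, Z)
    m_res = _residualize(m[:, None], Z)[:, 0]

    fa_c = fa_res - fa_res.mean(axis=0)
    m_c = m_res - m_res.mean()
    denom = np.sqrt((fa_c**2).sum(axis=0) * (m_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, fa_c.T @ m_c / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.clip(1 - r**2, 1e-300, None))
    p = 2 * sps.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"node": np.arange(1, d.n_nodes + 1), "r": r, "p": p, "p_fdr": bh_fdr(p)}
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def summarize_correlation_clusters(
    r: np.ndarray,
    p_fdr: np.ndarray,
    q: float = 0.05,
    covariates: tuple[str, ...] = (),
) -> list[CorrelationCluster]:
    """Contiguous runs of BH-significant nodes with mean r and mean p_fdr."""
    r = np.asarray(r, dtype=float)
    p_fdr = np.asarray(p_fdr, dtype=float)
    out = []
    for start, end in _runs(p_fdr < q):
        sl = slice(start, end + 1)
        out.append(
            CorrelationCluster(
                start=start + 1,
                end=end + 1,
                r_avg=float(r[sl].mean()),
                p_fdr_avg=float(p_fdr[sl].mean()),
                covariates=tuple(covariates),
            )
        )
    return out
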