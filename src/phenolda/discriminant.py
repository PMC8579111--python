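"""Two-class linear discriminant analysis with pseudo-inverse and shuffle null.

This is the multivariate core of the pipeline.  A subjects x variables
feature matrix with two class labels is pre-processed (learning-curve slope
reduction of multi-session variables, skew screening, per-class scaled-MAD
outlier replacement, pooled z-scoring, correlation-based variable dropping)
and fed to a Fisher discriminant computed from the eigen-decomposition of
``pinv(S_W) @ S_B``.  The Moore-Penrose pseudo-inverse admits more variables
than subjects, where the plain inverse of the within-class scatter would not
exist.  Because the two-class between-scatter has rank 1, the second
displayed axis (LD2) is defined as the leading principal axis of the data
after projecting out LD1.  Each variable's contribution to an axis is its
absolute coefficient as a percentage of the axis' absolute-coefficient sum.

The observed contribution ranking is validated against a label-shuffle null:
subjects are repeatedly re-assigned at random to two equally sized classes,
the discriminant recomputed, and the frequency with which each variable (and
the observed top variable sets) occupies the leading ranks is reported with
binomial Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAD_SCALE = 1.4826  # scaled MAD is consistent with the Gaussian SD


@dataclass
class FeatureMatrix:
    """Subjects x variables with two class labels and variable metadata.

    ``data`` is a DataFrame indexed by subject id; ``labels`` maps subjects
    to exactly two class names.  ``var_meta`` (indexed by column name) may
    carry per-variable metadata: ``assay`` tag, ``multi_session`` flag,
    ``group`` (base name shared by a multi-session variable's per-session
    columns), ``session`` index, and a ``tag`` used as correlation-filter
    drop priority (e.g. "speed" vs "distance").
    """

    data: pd.DataFrame
    labels: pd.Series
    var_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate variable names")
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            raise ValueError("every subject needs a class label")
        classes = self.classes
        if len(classes) != 2:
            raise ValueError("exactly two classes required")
        if (self.labels.value_counts() < 2).any():
            raise ValueError("each class needs at least 2 subjects")
        if self.var_meta.empty:
            self.var_meta = pd.DataFrame(index=self.data.columns)

    @property
    def classes(self) -> list:
        return sorted(self.labels.unique().tolist())

    def meta_col(self, name: str, default=None) -> pd.Series:
        if name in self.var_meta.columns:
            return self.var_meta[name].reindex(self.data.columns)
        return pd.Series(default, index=self.data.columns)


@dataclass
class PreprocessReport:
    slope_reduced: dict[str, list[str]] = field(default_factory=dict)
    skew_flagged: dict[str, float] = field(default_factory=dict)
    skew_excluded: list[str] = field(default_factory=list)
    outlier_replacements: list[tuple[str, str, float, float]] = field(
        default_factory=list
    )
    zero_variance_excluded: list[str] = field(default_factory=list)
    correlation_excluded: list[tuple[str, str, float]] = field(default_factory=list)
    initial_variables: int = 0
    final_variables: int = 0


@dataclass
class DiscriminantModel:
    variables: list[str]
    classes: list
    class_means: pd.DataFrame
    s_b: np.ndarray
    s_w: np.ndarray
    eigenvalues: np.ndarray
    axes: pd.DataFrame  # columns LD1, LD2; unit-norm coefficient vectors
    explained_pct: dict[str, float]
    contributions: pd.DataFrame  # % per variable per axis, columns sum to 100
    projections: pd.DataFrame
    labels: pd.Series

    def top_contributors(self, axis: str = "LD1", k: int = 10) -> pd.Series:
        """The k largest contributors to an axis, stable on ties."""
        c = self.contributions[axis]
        order = np.lexsort((np.arange(len(c)), -c.to_numpy()))
        return c.iloc[order[:k]]


@dataclass
class ShuffleReport:
    n_shuffles: int
    seed: int
    rank_freq_pct: pd.DataFrame  # variables x ranks 1..3, % of shuffles
    rank_freq_se_pct: pd.DataFrame
    observed_top: list[str]
    top2_joint_pct: float
    top2_joint_se_pct: float
    top3_joint_pct: float
    top3_joint_se_pct: float


# ---------------------------------------------------------------------------
# univariate workflow
# ---------------------------------------------------------------------------

def grubbs_test(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[int | None, float, float]:
    """Two-sided Grubbs test for a single outlier.

    Returns ``(index_or_None, G, critical)`` where
    G = max|x - mean| / sd and the critical value is the t-based closed form
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{1 - alpha/(2n), n-2}.  At most one point is flagged per call.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    dev = np.abs(x - x.mean())
    g = float(dev.max() / sd)
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    critical = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    idx = int(dev.argmax()) if g > critical else None
    return idx, g, float(critical)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    cohens_d: float


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD convention."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def two_group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    design: str = "independent",
    subjects: np.ndarray | None = None,
    sessions: np.ndarray | None = None,
    alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Group comparison with normality-driven test selection.

    Independent designs: Shapiro-Wilk on each group at ``alpha_normality``;
    both normal -> two-tailed t-test, otherwise two-tailed Mann-Whitney.
    Repeated designs (``subjects``/``sessions`` required) -> mixed
    between x within repeated-measures ANOVA (genotype effect), or a linear
    mixed model when data points are missing (``repeated_with_missing``).
    Cohen's d is always the pooled-SD standardized mean difference (over
    subject means in repeated designs).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups[~pd.isna(groups)]))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    if design == "independent":
        a = values[groups == names[0]]
        b = values[groups == names[1]]
        if len(a) < 3 or len(b) < 3:
            raise ValueError("each group needs n >= 3")
        normal = (
            stats.shapiro(a).pvalue > alpha_normality
            and stats.shapiro(b).pvalue > alpha_normality
        )
        if normal:
            res = stats.ttest_ind(a, b)
            return ComparisonResult("t-test", float(res.statistic),
                                    float(res.pvalue), cohens_d(a, b))
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult("mann-whitney", float(res.statistic),
                                float(res.pvalue), cohens_d(a, b))
    if design not in {"repeated", "repeated_with_missing"}:
        raise ValueError(f"unknown design {design!r}")
    if subjects is None or sessions is None:
        raise ValueError("repeated designs require subjects and sessions")
    df = pd.DataFrame(
        {
            "value": values,
            "group": groups,
            "subject": np.asarray(subjects),
            "session": np.asarray(sessions),
        }
    )
    means = df.dropna().groupby(["subject", "group"], observed=True)["value"].mean()
    a = means.xs(names[0], level="group").to_numpy()
    b = means.xs(names[1], level="group").to_numpy()
    d = cohens_d(a, b)
    if design == "repeated" and not df["value"].isna().any():
        import pingouin as pg

        aov = pg.mixed_anova(
            data=df, dv="value", within="session", between="group",
            subject="subject",
        )
        row = aov[aov["Source"] == "group"].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        return ComparisonResult(
            "repeated-measures-anova", float(row["F"]), float(row[p_col]), d
        )
    import statsmodels.formula.api as smf

    model = smf.mixedlm(
        "value ~ C(group) * C(session)", df.dropna(), groups=df.dropna()["subject"]
    )
    fit = model.fit(reml=True)
    term = [t for t in fit.params.index if t.startswith("C(group)")][0]
    z = float(fit.tvalues[term])
    return ComparisonResult("mixed-model", z, float(fit.pvalues[term]), d)


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def slope_reduce(session_values: np.ndarray) -> float:
    """OLS slope of a subject's values against 1-based session index.

    Interpreted as the subject's learning curve for the variable; NaN
    sessions are omitted (>= 2 finite points required).
    """
    y = np.asarray(session_values, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("slope reduction needs >= 2 session values")
    x, y = x[ok], y[ok]
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm)))


def reduce_multi_session(
    fm: FeatureMatrix,
) -> tuple[FeatureMatrix, dict[str, list[str]]]:
    """Replace each multi-session variable's session columns by its slope."""
    multi = fm.meta_col("multi_session", False).fillna(False).astype(bool)
    groups = fm.meta_col("group")
    sessions = fm.meta_col("session")
    reduced: dict[str, list[str]] = {}
    data = fm.data.copy()
    new_rows: dict[str, dict] = {}
    for base in pd.unique(groups[multi].dropna()):
        cols = [c for c in fm.data.columns if multi[c] and groups[c] == base]
        cols.sort(key=lambda c: sessions.get(c) or 0)
        slopes = fm.data[cols].apply(
            lambda row: slope_reduce(row.to_numpy()), axis=1
        )
        insert_at = data.columns.get_loc(cols[0])
        data = data.drop(columns=cols)
        data.insert(min(insert_at, data.shape[1]), base, slopes)
        row = {c: None for c in fm.var_meta.columns}
        row["multi_session"] = False
        for key in ("assay", "tag"):
            if key in fm.var_meta.columns:
                row[key] = fm.var_meta.loc[cols[0], key]
        if "group" in fm.var_meta.columns:
            row["group"] = base
        new_rows[base] = row
        reduced[base] = cols
    meta = fm.var_meta.drop(index=[c for cols in reduced.values() for c in cols])
    if new_rows:
        meta = pd.concat(
            [meta, pd.DataFrame.from_dict(new_rows, orient="index")]
        )
    meta = meta.reindex(data.columns)
    return FeatureMatrix(data, fm.labels, meta), reduced


def skew_screen(fm: FeatureMatrix, threshold: float = 2.0) -> dict[str, float]:
    """Advisory screen: variables whose distribution is genuinely skewed.

    A variable is flagged when its sample skewness exceeds ``threshold`` in
    magnitude *and* still does so after removing the single most extreme
    point — a lone aberrant value (an outlier, handled later by the
    scaled-MAD rule) collapses under that probe, whereas a heavy-tailed
    distribution keeps its skew.  Flagged variables are reported, not
    silently dropped; the caller decides which to exclude (in the source
    study one heavily skewed learning variable was removed by inspection).
    """
    flagged = {}
    for col in fm.data.columns:
        vals = fm.data[col].dropna().to_numpy()
        if len(vals) < 4:
            continue
        s = float(stats.skew(vals, bias=False))
        if abs(s) <= threshold:
            continue
        worst = np.abs(vals - np.median(vals)).argmax()
        s_drop1 = float(stats.skew(np.delete(vals, worst), bias=False))
        if abs(s_drop1) > threshold:
            flagged[col] = s
    return flagged


def replace_class_outliers(
    fm: FeatureMatrix, threshold: float = 3.0
) -> tuple[FeatureMatrix, list[tuple[str, str, float, float]]]:
    """Per-class scaled-MAD outlier replacement (mean interpolation).

    A value is an outlier when it lies more than ``threshold`` scaled MADs
    (MAD x 1.4826) from its class median for that variable; flagged values
    are replaced by the mean of the non-flagged class members.  When the MAD
    is zero (majority ties), any value differing from the class median is
    flagged.  Non-flagged values are never altered.
    """
    data = fm.data.copy()
    replacements: list[tuple[str, str, float, float]] = []
    for col in data.columns:
        for cls in fm.classes:
            idx = fm.labels[fm.labels == cls].index
            vals = data.loc[idx, col].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if finite.sum() < 3:
                continue
            med = np.median(vals[finite])
            mad = MAD_SCALE * np.median(np.abs(vals[finite] - med))
            if mad == 0:
                out = finite & (vals != med)
            else:
                out = finite & (np.abs(vals - med) > threshold * mad)
            if not out.any():
                continue
            keep = finite & ~out
            if not keep.any():
                continue
            repl = float(vals[keep].mean())
            for subj, orig in zip(np.asarray(idx)[out], vals[out]):
                replacements.append((str(subj), col, float(orig), repl))
            vals[out] = repl
            data.loc[idx, col] = vals
    return FeatureMatrix(data, fm.labels, fm.var_meta.copy()), replacements


def zscore_features(
    fm: FeatureMatrix,
) -> tuple[FeatureMatrix, list[str]]:
    """Pooled (both classes) z-scoring; zero-variance variables are dropped."""
    data = fm.data.copy()
    dropped = []
    for col in data.columns:
        sd = data[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(col)
            continue
        data[col] = (data[col] - data[col].mean()) / sd
    data = data.drop(columns=dropped)
    meta = fm.var_meta.drop(index=dropped, errors="ignore").reindex(data.columns)
    return FeatureMatrix(data, fm.labels, meta), dropped


def filter_correlated(
    fm: FeatureMatrix,
    r_threshold: float = 0.86,
    drop_priority: tuple[str, ...] = ("speed",),
) -> tuple[FeatureMatrix, list[tuple[str, str, float]]]:
    """Greedy, order-stable dropping of strongly correlated variables.

    For each pair with ``|r| >= r_threshold`` (Pearson, pairwise-complete),
    the member whose tag (or name substring) appears in ``drop_priority`` is
    dropped; otherwise the second member of the pair.  In the source design
    speed variables are dropped in favour of the distance variables they
    duplicate.
    """
    corr = fm.data.corr()
    tags = fm.meta_col("tag")
    cols = list(fm.data.columns)
    dropped: dict[str, tuple[str, float]] = {}

    def _priority(name: str) -> bool:
        tag = tags.get(name)
        if isinstance(tag, str) and tag in drop_priority:
            return True
        return any(p in name.lower() for p in drop_priority)

    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[i + 1 :]:
            if a in dropped:
                break
            if b in dropped:
                continue
            r = corr.loc[a, b]
            if not np.isfinite(r) or abs(r) < r_threshold:
                continue
            victim = a if _priority(a) and not _priority(b) else b
            partner = b if victim == a else a
            dropped[victim] = (partner, float(r))
    keep = [c for c in cols if c not in dropped]
    if not keep:
        raise ValueError("correlation filter removed every variable")
    data = fm.data[keep]
    meta = fm.var_meta.reindex(keep)
    exclusions = [(v, partner, r) for v, (partner, r) in dropped.items()]
    return FeatureMatrix(data, fm.labels, meta), exclusions


def preprocess(
    fm: FeatureMatrix,
    skew_threshold: float = 2.0,
    exclude_skewed: bool = False,
    mad_threshold: float = 3.0,
    r_threshold: float = 0.86,
    drop_priority: tuple[str, ...] = ("speed",),
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Full pre-processing chain ahead of the discriminant fit.

    Order: multi-session slope reduction -> skew screen (advisory unless
    ``exclude_skewed``) -> per-class scaled-MAD outlier replacement ->
    pooled z-scoring -> correlation filter.
    """
    report = PreprocessReport(initial_variables=fm.data.shape[1])
    fm, report.slope_reduced = reduce_multi_session(fm)
    report.skew_flagged = skew_screen(fm, skew_threshold)
    if exclude_skewed and report.skew_flagged:
        report.skew_excluded = sorted(report.skew_flagged)
        data = fm.data.drop(columns=report.skew_excluded)
        fm = FeatureMatrix(
            data, fm.labels, fm.var_meta.reindex(data.columns)
        )
    fm, report.outlier_replacements = replace_class_outliers(fm, mad_threshold)
    fm, report.zero_variance_excluded = zscore_features(fm)
    fm, report.correlation_excluded = filter_correlated(
        fm, r_threshold, drop_priority
    )
    report.final_variables = fm.data.shape[1]
    return fm, report


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _scatter_matrices(
    X: np.ndarray, y: np.ndarray, classes: list
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    s_b = np.zeros((X.shape[1], X.shape[1]))
    s_w = np.zeros_like(s_b)
    mus = []
    for cls in classes:
        Xc = X[y == cls]
        mc = Xc.mean(axis=0)
        mus.append(mc)
        d = (mc - mu)[:, None]
        s_b += len(Xc) * (d @ d.T)
        C = Xc - mc
        s_w += C.T @ C
    return s_b, s_w, mus[0], mus[1]


def fit_lda(
    fm: FeatureMatrix, pinv_rcond: float | None = None
) -> DiscriminantModel:
    """Two-class Fisher discriminant via ``pinv(S_W) @ S_B``.

    S_B = sum_c n_c (mu_c - mu)(mu_c - mu)^T; S_W is the pooled within-class
    scatter.  The pseudo-inverse handles the singular S_W that arises when
    variables outnumber subjects minus classes.  LD1 is the unit-norm
    eigenvector with the largest |eigenvalue|; LD2 is the leading principal
    axis of the data after projecting out LD1 (the two-class S_B has rank 1,
    so no second discriminant eigenvector exists in exact arithmetic).
    Explained data variation of an axis is the variance of the subject
    projections on it as a percentage of the total variance; a variable's
    contribution to an axis is 100|w_j| / sum_k |w_k|.
    """
    X = fm.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; preprocess first")
    y = fm.labels.to_numpy()
    classes = fm.classes
    s_b, s_w, mu1, mu2 = _scatter_matrices(X, y, classes)
    if pinv_rcond is None:
        # MATLAB-style cutoff: singular values below max(dim)*eps*sigma_max
        # are numerical zeros of the rank-deficient scatter; numpy's 1e-15
        # default sits below them and would invert null-space noise
        pinv_rcond = max(s_w.shape) * np.finfo(float).eps
    m = np.linalg.pinv(s_w, rcond=pinv_rcond) @ s_b
    eigvals, eigvecs = np.linalg.eig(m)
    eigvals = np.real_if_close(eigvals)
    order = np.argsort(-np.abs(eigvals))
    eigvals = np.real(eigvals[order])
    w1 = np.real(eigvecs[:, order[0]])
    w1 = w1 / np.linalg.norm(w1)
    # orient LD1 so class 1 projects higher than class 2 (display convention)
    if (mu1 - mu2) @ w1 < 0:
        w1 = -w1

    Xc = X - X.mean(axis=0)
    resid = Xc - np.outer(Xc @ w1, w1)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    w2 = vt[0]
    w2 = w2 / np.linalg.norm(w2)
    if w2[np.argmax(np.abs(w2))] < 0:
        w2 = -w2

    total_var = Xc.var(axis=0, ddof=1).sum()
    axes = pd.DataFrame({"LD1": w1, "LD2": w2}, index=fm.data.columns)
    proj = pd.DataFrame(
        {"LD1": X @ w1, "LD2": X @ w2}, index=fm.data.index
    )
    explained = {
        ld: float(100.0 * proj[ld].var(ddof=1) / total_var) for ld in ("LD1", "LD2")
    }
    contributions = axes.abs()
    contributions = 100.0 * contributions / contributions.sum(axis=0)
    means = pd.DataFrame(
        {classes[0]: mu1, classes[1]: mu2}, index=fm.data.columns
    )
    return DiscriminantModel(
        variables=list(fm.data.columns),
        classes=classes,
        class_means=means,
        s_b=s_b,
        s_w=s_w,
        eigenvalues=eigvals,
        axes=axes,
        explained_pct=explained,
        contributions=contributions,
        projections=proj,
        labels=fm.labels.copy(),
    )


def _contribution_ranks(w: np.ndarray) -> np.ndarray:
    """Indices of variables by decreasing |coefficient|, stable on ties."""
    return np.lexsort((np.arange(len(w)), -np.abs(w)))


def shuffles_for_error(p: float, rel_error: float = 0.05) -> int:
    """Shuffles needed so the binomial MC SE is below ``rel_error * p``.

    SE(p_hat) = sqrt(p(1-p)/n); solving SE/p <= rel_error gives
    n >= (1-p) / (p * rel_error^2).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if rel_error <= 0:
        raise ValueError("rel_error must be positive")
    return int(np.ceil((1 - p) / (p * rel_error**2)))


def shuffle_validate(
    fm: FeatureMatrix,
    n_shuffles: int = 200_000,
    seed: int = 0,
) -> ShuffleReport:
    """Label-shuffle null distribution of LD1 contribution ranks.

    Each shuffle assigns the subjects at random to two equally sized classes
    (the subject count must be even), recomputes the discriminant direction
    ``pinv(S_W) @ (mu1 - mu2)`` and records the contribution rank of every
    variable on LD1.  Reported per variable: the percentage of shuffles in
    which it held ranks 1-3; plus the percentage of shuffles in which the
    observed top-2 (top-3) variable sets jointly held ranks 1-2 (1-3).  All
    frequencies carry binomial Monte-Carlo standard errors.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    X = fm.data.to_numpy(dtype=float)
    n, p = X.shape
    if n % 2:
        raise ValueError("shuffle validation needs an even subject count")
    observed = fit_lda(fm)
    obs_order = _contribution_ranks(observed.axes["LD1"].to_numpy())
    observed_top = [fm.data.columns[i] for i in obs_order[:3]]
    top2 = set(obs_order[:2])
    top3 = set(obs_order[:3])

    # S_T is shuffle-invariant; with equal classes S_W = S_T - (n/4) d d^T
    mu = X.mean(axis=0)
    Xc = X - mu
    s_t = Xc.T @ Xc
    half = n // 2
    rng = np.random.default_rng(seed)
    rank_counts = np.zeros((p, 3), dtype=np.int64)
    top2_hits = 0
    top3_hits = 0
    rcond = max(p, 1) * np.finfo(float).eps
    for _ in range(n_shuffles):
        sel = rng.permutation(n)[:half]
        mu1 = X[sel].mean(axis=0)
        d = 2.0 * (mu1 - mu)  # mu1 - mu2 with equal class sizes
        s_w = s_t - (n / 4.0) * np.outer(d, d)
        w = np.linalg.pinv(s_w, rcond=rcond) @ d
        order = _contribution_ranks(w)
        rank_counts[order[0], 0] += 1
        rank_counts[order[1], 1] += 1
        rank_counts[order[2], 2] += 1
        if set(order[:2]) == top2:
            top2_hits += 1
        if set(order[:3]) == top3:
            top3_hits += 1
    freq = 100.0 * rank_counts / n_shuffles
    se = 100.0 * np.sqrt(
        (rank_counts / n_shuffles) * (1 - rank_counts / n_shuffles) / n_shuffles
    )
    ranks = ["rank1", "rank2", "rank3"]
    return ShuffleReport(
        n_shuffles=n_shuffles,
        seed=seed,
        rank_freq_pct=pd.DataFrame(freq, index=fm.data.columns, columns=ranks),
        rank_freq_se_pct=pd.DataFrame(se, index=fm.data.columns, columns=ranks),
        observed_top=observed_top,
        top2_joint_pct=100.0 * top2_hits / n_shuffles,
        top2_joint_se_pct=100.0
        * float(np.sqrt((top2_hits / n_shuffles) * (1 - top2_hits / n_shuffles) / n_shuffles)),
        top3_joint_pct=100.0 * top3_hits / n_shuffles,
        top3_joint_se_pct=100.0
        * float(np.sqrt((top3_hits / n_shuffles) * (1 - top3_hits / n_shuffles) / n_shuffles)),
    )
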