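"""Group-level pre/post inference.

Paired t tests on per-subject change scores (channels, coactivation pairs,
behavioral instruments), Benjamini-Hochberg FDR within each correction
family, Pearson brain-behavior correlations on change scores, sensitivity
analyses (Spearman time-since-injury screens, leave-one-out, ANCOVA), and
the feasibility ledger of valid/missing/invalid recordings.

Coactivation values are Fisher z-transformed before the paired test and the
mean difference is back-transformed for reporting (switchable to raw r).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass
class PairedResult:
    md: float      # mean(post - pre)
    t: float
    p: float
    d: float       # md / SD(diff)
    n: int

    def format(self) -> str:
        return f"(MD={self.md:+.2f}, P={self.p:.3f}, d={self.d:.2f})"


def paired_change_test(pre: np.ndarray, post: np.ndarray) -> PairedResult | None:
    """Paired t on complete pre/post pairs; incomplete subjects dropped.

    Returns None (a missing result) when fewer than 2 complete pairs
    remain; a zero-variance difference yields t=0, p=1 by convention.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(post))
    d = post[ok] - pre[ok]
    n = d.size
    if n < 2:
        logger.warning("paired test skipped: %d complete pairs", n)
        return None
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return PairedResult(md, 0.0, 1.0, 0.0 if md == 0 else math.inf, n)
    t = md / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedResult(md, float(t), float(p), md / sd, n)


def fdr_adjust(p_values, family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (NaN entries pass
    through; each family is corrected separately by the caller)."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise InvalidInputError(f"p values outside [0, 1] in family {family!r}")
    q = np.full_like(p, np.nan)
    if ok.sum() > 0:
        _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = q_ok
    return q


def brain_behavior_correlation(
    neural_change: np.ndarray, behavioral_change: np.ndarray
) -> tuple[float, float, int] | None:
    """Pearson r between change scores with its two-sided p, pairwise
    complete. None when n < 3 or either input is constant."""
    x = np.asarray(neural_change, dtype=float)
    y = np.asarray(behavioral_change, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        logger.warning("correlation skipped: n=%d < 3", n)
        return None
    if x.std() == 0 or y.std() == 0:
        logger.warning("correlation skipped: zero-variance input")
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def group_change_table(
    metric_df: pd.DataFrame,
    family: str,
    fisher_transform: bool = False,
) -> pd.DataFrame:
    """Paired tests across subjects for every (condition, metric id).

    ``metric_df`` is tidy: subject, visit (pre|post), condition, metric_id,
    value. Rows with NaN values count as missing visits (pairwise
    deletion). Output carries MD, t, p, q (BH within condition x family),
    paired d and n; for Fisher-transformed families the reported MD is
    back-transformed to the r scale while t/p/d come from the z scale.
    """
    results = []
    for cond, cdf in metric_df.groupby("condition", sort=False):
        wide = cdf.pivot_table(index="subject", columns=["visit", "metric_id"],
                               values="value")
        metric_ids = sorted(cdf["metric_id"].unique(),
                            key=lambda m: list(cdf["metric_id"]).index(m))
        rows = []
        for mid in metric_ids:
            try:
                pre = wide[("pre", mid)].to_numpy()
                post = wide[("post", mid)].to_numpy()
            except KeyError:
                rows.append((mid, np.nan, np.nan, np.nan, np.nan, 0))
                continue
            if fisher_transform:
                res = paired_change_test(fisher_z(pre), fisher_z(post))
                if res is not None:
                    # report the change back-transformed to the r scale
                    ok = ~(np.isnan(pre) | np.isnan(post))
                    md_r = float(np.tanh(fisher_z(post[ok]).mean())
                                 - np.tanh(fisher_z(pre[ok]).mean()))
                    res = PairedResult(md_r, res.t, res.p, res.d, res.n)
            else:
                res = paired_change_test(pre, post)
            if res is None:
                rows.append((mid, np.nan, np.nan, np.nan, np.nan, 0))
            else:
                rows.append((mid, res.md, res.t, res.p, res.d, res.n))
        sub = pd.DataFrame(rows, columns=["metric_id", "MD", "t", "p", "d", "n"])
        sub.insert(0, "condition", cond)
        sub["q"] = fdr_adjust(sub["p"].to_numpy(), family=f"{family}:{cond}")
        results.append(sub)
    out = pd.concat(results, ignore_index=True)
    out.insert(0, "family", family)
    return out


@dataclass
class QCLedger:
    possible: int
    missing: int
    invalid: int
    valid: int
    valid_pct: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def feasibility_report(session_log: pd.DataFrame) -> QCLedger:
    """Counts of valid/missing/invalid scheduled recordings.

    ``session_log`` needs a ``status`` column in {valid, missing, invalid}
    plus identifying columns; duplicate recording ids are rejected. The
    valid percentage is rounded half-up to an integer.
    """
    id_cols = [c for c in session_log.columns if c != "status"]
    if session_log.duplicated(subset=id_cols).any():
        raise InvalidInputError("duplicate recording ids in session log")
    bad = set(session_log["status"]) - {"valid", "missing", "invalid"}
    if bad:
        raise InvalidInputError(f"unknown statuses: {bad}")
    possible = len(session_log)
    missing = int((session_log["status"] == "missing").sum())
    invalid = int((session_log["status"] == "invalid").sum())
    valid = possible - missing - invalid
    pct = int(math.floor(100.0 * valid / possible + 0.5)) if possible else 0
    return QCLedger(possible, missing, invalid, valid, pct)


@dataclass
class SensitivityReport:
    spearman: pd.DataFrame       # covariate screens, BH-corrected
    leave_one_out: pd.DataFrame  # per-metric t range across folds
    ancova: pd.DataFrame         # covariate coefficients and p


def _spearman_screen(x: np.ndarray, targets: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, y in targets.items():
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.std(y[ok]) == 0:
            rows.append((name, np.nan, np.nan, int(ok.sum())))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append((name, float(rho), float(p), int(ok.sum())))
    df = pd.DataFrame(rows, columns=["target", "rho", "p", "n"])
    df["q"] = fdr_adjust(df["p"].to_numpy(), family="spearman-screen")
    return df


def leave_one_out_paired(pre: np.ndarray, post: np.ndarray) -> pd.DataFrame:
    """Re-run the paired test dropping each subject in turn."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    rows = []
    for drop in range(pre.size):
        keep = np.arange(pre.size) != drop
        res = paired_change_test(pre[keep], post[keep])
        if res is not None:
            rows.append((drop, res.md, res.t, res.p, res.d, res.n))
    return pd.DataFrame(rows, columns=["dropped", "MD", "t", "p", "d", "n"])


def ancova_post_on_baseline(
    post: np.ndarray,
    baseline: np.ndarray,
    time_since_injury: np.ndarray,
    injury_type: np.ndarray,
) -> pd.DataFrame:
    """OLS of the post value on baseline + time since injury + injury type
    (categorical, collapsed). Constant covariates are dropped with a
    warning. Returns the coefficient table."""
    import statsmodels.api as sm

    df = pd.DataFrame({
        "post": np.asarray(post, float),
        "baseline": np.asarray(baseline, float),
        "time_since_injury": np.asarray(time_since_injury, float),
        "injury_type": pd.Categorical(injury_type),
    }).dropna()
    X = pd.DataFrame({"baseline": df["baseline"],
                      "time_since_injury": df["time_since_injury"]})
    dummies = pd.get_dummies(df["injury_type"], prefix="injury", drop_first=True)
    X = pd.concat([X, dummies.astype(float)], axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    for c in const:
        logger.warning("ANCOVA: dropping constant covariate %s", c)
    X = X.drop(columns=const)
    X = sm.add_constant(X)
    if len(df) <= X.shape[1]:
        logger.warning("ANCOVA skipped: %d observations for %d parameters",
                       len(df), X.shape[1])
        return pd.DataFrame(columns=["term", "coef", "se", "t", "p"])
    fit = sm.OLS(df["post"], X).fit()
    return pd.DataFrame({
        "term": fit.params.index,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })


def sensitivity_suite(
    metric_df: pd.DataFrame,
    covariates: pd.DataFrame,
    metrics: list[tuple[str, str]] | None = None,
) -> SensitivityReport:
    """Covariate screens, leave-one-out, and ANCOVA over selected metrics.

    ``metric_df`` is the tidy subject/visit/condition/metric_id/value table;
    ``covariates`` has one row per subject with time_since_injury_d and
    injury_type; ``metrics`` lists (condition, metric_id) pairs to examine
    (default: all).
    """
    if not {"subject", "time_since_injury_d", "injury_type"} <= set(covariates.columns):
        raise InvalidParameterError("covariates need subject, time_since_injury_d, "
                                    "injury_type columns")
    cov = covariates.set_index("subject")
    if metrics is None:
        metrics = list(
            metric_df[["condition", "metric_id"]].drop_duplicates().itertuples(
                index=False, name=None)
        )

    loo_rows = []
    spearman_targets: dict[str, np.ndarray] = {}
    tsi = None
    anc_rows = []
    for cond, mid in metrics:
        sub = metric_df[(metric_df["condition"] == cond)
                        & (metric_df["metric_id"] == mid)]
        wide = sub.pivot_table(index="subject", columns="visit", values="value")
        if not {"pre", "post"} <= set(wide.columns):
            continue
        wide = wide.join(cov, how="left")
        pre = wide["pre"].to_numpy()
        post = wide["post"].to_numpy()
        if tsi is None:
            tsi = wide["time_since_injury_d"].to_numpy()
        spearman_targets[f"{cond}:{mid}:baseline"] = pre
        spearman_targets[f"{cond}:{mid}:change"] = post - pre

        loo = leave_one_out_paired(pre, post)
        if len(loo):
            loo_rows.append((cond, mid, loo["t"].min(), loo["t"].max(),
                             loo["MD"].min(), loo["MD"].max(), len(loo)))
        anc = ancova_post_on_baseline(post, pre,
                                      wide["time_since_injury_d"].to_numpy(),
                                      wide["injury_type"].to_numpy())
        if len(anc):
            anc.insert(0, "metric_id", mid)
            anc.insert(0, "condition", cond)
            anc_rows.append(anc)

    spearman = _spearman_screen(tsi if tsi is not None else np.array([]),
                                spearman_targets)
    loo_df = pd.DataFrame(loo_rows, columns=["condition", "metric_id", "t_min",
                                             "t_max", "MD_min", "MD_max", "folds"])
    ancova = (pd.concat(anc_rows, ignore_index=True) if anc_rows
              else pd.DataFrame(columns=["condition", "metric_id", "term",
                                         "coef", "se", "t", "p"]))
    return SensitivityReport(spearman=spearman, leave_one_out=loo_df, ancova=ancova)
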