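"""Per-subject brain measures: GLM activation betas, prestimulus-baseline
Cohen d, and pairwise functional coactivation over the 8-channel prefrontal
montage.

Channel-to-region layout (2 channels per region):

====== ===================
1-2    right lateral PFC
3-4    right medial PFC
5-6    left medial PFC
7-8    left lateral PFC
====== ===================

Channel pairs are enumerated lexicographically: FC1=(1,2) ... FC7=(1,8),
FC8=(2,3), ..., FC28=(7,8). This enumeration together with the region map
reproduces the anatomical pair labels used in reporting (e.g. FC21=(4,7) is
right medial - left lateral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .hemodynamics import HrfParams, condition_regressor
from .preprocess import FilterParams, HemoglobinSeries, filter_timeseries
from .protocol import TaskDesign

logger = logging.getLogger(__name__)

N_CHANNELS = 8

REGIONS = ("right-lateral", "right-medial", "left-medial", "left-lateral")

#: channel (1-based) -> prefrontal region
DEFAULT_REGION_MAP: dict[int, str] = {
    1: "right-lateral", 2: "right-lateral",
    3: "right-medial", 4: "right-medial",
    5: "left-medial", 6: "left-medial",
    7: "left-lateral", 8: "left-lateral",
}

#: lexicographic unordered-pair enumeration, FC index (1-based) -> (i, j)
FC_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, N_CHANNELS + 1) for j in range(i + 1, N_CHANNELS + 1)
)
N_PAIRS = len(FC_PAIRS)  # 28


def fc_index(i: int, j: int) -> int:
    """1-based FC index of unordered channel pair (i, j)."""
    if i == j or not (1 <= i <= N_CHANNELS and 1 <= j <= N_CHANNELS):
        raise InvalidParameterError(f"invalid channel pair ({i}, {j})")
    a, b = min(i, j), max(i, j)
    return FC_PAIRS.index((a, b)) + 1


def fc_pair_region_label(k: int, region_map: dict[int, str] | None = None) -> str:
    """Anatomical label of FC pair k, e.g. 'right-medial_left-lateral'."""
    rm = region_map or DEFAULT_REGION_MAP
    i, j = FC_PAIRS[k - 1]
    ri, rj = rm[i], rm[j]
    if ri == rj:
        return f"within_{ri}"
    order = {r: n for n, r in enumerate(REGIONS)}
    a, b = sorted((ri, rj), key=order.get)
    return f"{a}_{b}"


@dataclass
class DesignMatrix:
    regressors: np.ndarray      # (time, k)
    column_labels: list[str]
    condition_columns: list[int]

    def __post_init__(self) -> None:
        if self.regressors.shape[1] != len(self.column_labels):
            raise InvalidInputError("column label count mismatch")


@dataclass
class SubjectMetrics:
    """All three measures for one subject-visit."""

    subject_id: str
    visit: str
    conditions: list[str]
    beta: np.ndarray       # (channels, conditions), uM
    cohen_d: np.ndarray    # (channels, conditions)
    fc: dict[str, np.ndarray] = field(default_factory=dict)        # 8x8 per condition
    fc_pairs: dict[str, np.ndarray] = field(default_factory=dict)  # 28-vector
    region_fc: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)


def build_design_matrix(
    design: TaskDesign,
    hrf_params: HrfParams | None = None,
    sampling_rate: float | None = None,
    nuisance: str = "intercept+drift",
    filter_params: FilterParams | None = None,
) -> DesignMatrix:
    """One HRF-convolved, peak-normalized boxcar column per condition plus
    nuisance columns (intercept, linear drift).

    When ``filter_params`` is given, condition columns are passed through the
    same zero-phase band-pass as the data (matched filtering), so betas fit
    to filtered data stay in planted signal units.
    """
    if not design.blocks:
        raise InvalidInputError("empty task design")
    fs = sampling_rate or design.sampling_rate
    labels = design.condition_labels
    cols, names = [], []
    for lab in labels:
        reg = condition_regressor(design, lab, hrf_params)
        if filter_params is not None:
            reg = filter_timeseries(reg, filter_params, fs)
        cols.append(reg)
        names.append(lab)
    n = design.n_samples
    cond_idx = list(range(len(labels)))
    if "intercept" in nuisance:
        cols.append(np.ones(n))
        names.append("intercept")
    if "drift" in nuisance:
        cols.append(np.linspace(-0.5, 0.5, n))
        names.append("drift")
    return DesignMatrix(np.column_stack(cols), names, cond_idx)


def fit_glm(hb: HemoglobinSeries, X: DesignMatrix) -> dict:
    """Per-channel OLS of HbO on the design, valid samples only.

    Returns dict with ``beta`` (channels x conditions), descriptive
    ``t`` values and residual variance. Channels with too few valid samples
    or a rank-deficient masked design yield NaN rows, not errors.
    """
    n_ch, n_t = hb.hbo.shape
    k = X.regressors.shape[1]
    n_cond = len(X.condition_columns)
    beta = np.full((n_ch, n_cond), np.nan)
    tval = np.full((n_ch, n_cond), np.nan)
    resid_var = np.full(n_ch, np.nan)
    for c in range(n_ch):
        m = hb.valid_mask[c]
        if m.sum() < k + 2:
            logger.warning("channel %d: only %d valid samples for GLM", c + 1, m.sum())
            continue
        Xm = X.regressors[m]
        if np.linalg.matrix_rank(Xm) < k:
            logger.warning("channel %d: rank-deficient design after masking", c + 1)
            continue
        y = hb.hbo[c, m]
        coef, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ coef
        dof = m.sum() - k
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(Xm.T @ Xm)
        se = np.sqrt(np.diag(cov))
        beta[c] = coef[X.condition_columns]
        with np.errstate(divide="ignore", invalid="ignore"):
            tval[c] = coef[X.condition_columns] / se[X.condition_columns]
        resid_var[c] = s2
    return {"beta": beta, "t": tval, "resid_var": resid_var}


def block_effect_size(
    hb: HemoglobinSeries,
    design: TaskDesign,
    condition: str,
    baseline_window_s: float = 10.0,
    denominator: str = "pooled",
) -> np.ndarray:
    """Cohen d per channel: (condition mean - prestimulus baseline mean) over
    the pooled SD of the two intervals (``denominator='baseline'`` switches
    to baseline-only SD). Masked samples are excluded."""
    if denominator not in ("pooled", "baseline"):
        raise InvalidParameterError(f"unknown denominator {denominator!r}")
    fs = hb.sampling_rate
    cond_mask = design.sample_mask(condition)[: hb.hbo.shape[1]]
    onset, _ = design.condition_span(condition)
    b0 = max(int(round((onset - baseline_window_s) * fs)), 0)
    b1 = int(round(onset * fs))
    base_mask = np.zeros_like(cond_mask)
    base_mask[b0:b1] = True

    n_ch = hb.hbo.shape[0]
    d = np.full(n_ch, np.nan)
    for c in range(n_ch):
        v = hb.valid_mask[c]
        cond = hb.hbo[c, cond_mask & v]
        base = hb.hbo[c, base_mask & v]
        if base.size < 5 or cond.size < 5:
            logger.warning(
                "channel %d, condition %s: insufficient baseline/condition "
                "samples after masking", c + 1, condition,
            )
            continue
        diff = cond.mean() - base.mean()
        if denominator == "pooled":
            n1, n2 = cond.size, base.size
            sd = np.sqrt(
                ((n1 - 1) * cond.var(ddof=1) + (n2 - 1) * base.var(ddof=1))
                / (n1 + n2 - 2)
            )
        else:
            sd = base.std(ddof=1)
        d[c] = diff / sd if sd > 0 else np.nan
    return d


def coactivation_matrix(
    hb: HemoglobinSeries,
    design: TaskDesign,
    condition: str,
    min_samples: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of HbO between every unordered channel pair within the
    condition's blocks. Returns the 8x8 matrix and the 28-vector in
    lexicographic pair order."""
    cond_mask = design.sample_mask(condition)[: hb.hbo.shape[1]]
    n_ch = hb.hbo.shape[0]
    fc = np.full((n_ch, n_ch), np.nan)
    np.fill_diagonal(fc, 1.0)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            m = cond_mask & hb.valid_mask[i] & hb.valid_mask[j]
            if m.sum() < min_samples:
                logger.warning("pair (%d,%d): <%d jointly valid samples",
                               i + 1, j + 1, min_samples)
                continue
            x, y = hb.hbo[i, m], hb.hbo[j, m]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                logger.warning("pair (%d,%d): constant channel", i + 1, j + 1)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            fc[i, j] = fc[j, i] = r
    pairs = np.array([fc[i - 1, j - 1] for i, j in FC_PAIRS])
    return fc, pairs


def region_pair_fc(
    fc: np.ndarray, region_map: dict[int, str] | None = None
) -> dict[tuple[str, str], float]:
    """Average inter-region channel-pair correlations (4 pairs per
    cross-region entry, the single intra-region pair within a region).
    Missing entries propagate as NaN-excluded means; an all-missing cell is
    NaN."""
    rm = region_map or DEFAULT_REGION_MAP
    out: dict[tuple[str, str], float] = {}
    for a_i, ra in enumerate(REGIONS):
        for rb in REGIONS[a_i:]:
            chans_a = [c for c, r in rm.items() if r == ra]
            chans_b = [c for c, r in rm.items() if r == rb]
            if ra == rb:
                vals = [fc[chans_a[0] - 1, chans_a[1] - 1]]
            else:
                vals = [fc[i - 1, j - 1] for i in chans_a for j in chans_b]
            arr = np.array(vals, dtype=float)
            good = ~np.isnan(arr)
            out[(ra, rb)] = float(arr[good].mean()) if good.any() else float("nan")
    return out


def compute_subject_metrics(
    hb: HemoglobinSeries,
    design: TaskDesign,
    subject_id: str = "S00",
    visit: str = "pre",
    hrf_params: HrfParams | None = None,
    filter_params: FilterParams | None = None,
    baseline_window_s: float = 10.0,
    d_denominator: str = "pooled",
) -> SubjectMetrics:
    """GLM betas, Cohen d, and per-condition coactivation for one recording."""
    X = build_design_matrix(design, hrf_params, hb.sampling_rate,
                            filter_params=filter_params)
    glm = fit_glm(hb, X)
    conditions = design.condition_labels
    d = np.column_stack([
        block_effect_size(hb, design, cond, baseline_window_s, d_denominator)
        for cond in conditions
    ])
    fc, fc_pairs, region = {}, {}, {}
    for cond in conditions:
        mat, vec = coactivation_matrix(hb, design, cond)
        fc[cond] = mat
        fc_pairs[cond] = vec
        region[cond] = region_pair_fc(mat)
    return SubjectMetrics(
        subject_id=subject_id, visit=visit, conditions=conditions,
        beta=glm["beta"], cohen_d=d, fc=fc, fc_pairs=fc_pairs, region_fc=region,
    )
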