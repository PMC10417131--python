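"""Prognostic hazard-ratio maps and the ΔHR risk score.

For every metagene pixel, samples are split into a high-expression group
(centralized metagene expression greater than zero, or greater than one
within-pixel standard deviation) and the rest; the per-pixel hazard
ratio is exp(beta) from a univariate Cox proportional-hazards fit of the
group indicator against overall survival (Efron tie handling). Pixels
with too small a group, or non-convergent fits, are masked.

The ΔHR score of a sample is the mean expression over the genes of the
maximum-HR metagene minus the mean over the genes of the minimum-HR
metagene; ranking samples by ΔHR and splitting at the top/bottom 50% or
25% yields high- and low-risk groups whose Kaplan-Meier curves and
log-rank test quantify the score's prognostic power. A per-patient
summary of lesion-level ΔHR scores quantifies intra-patient versus
inter-patient heterogeneity.

The per-pixel Cox fits use a vectorized Newton solver written for the
special case of a single binary covariate (thousands of pixels share one
risk-set structure); it is validated against lifelines' CoxPHFitter in
the test suite. Kaplan-Meier estimation and the log-rank test come from
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from somscape.preprocessing import ExpressionMatrix
    from somscape.som_portrayal import SOMResults


# ---------------------------------------------------------------------------
# vectorized univariate binary-covariate Cox (Efron ties)
# ---------------------------------------------------------------------------
def _cox_binary_efron(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit beta for many binary covariates sharing one survival outcome.

    Parameters
    ----------
    x : (n_samples, n_covariates) 0/1 array
    time, event : (n_samples,) arrays

    Returns
    -------
    beta, se, converged : (n_covariates,) arrays. Monotone-likelihood fits
    (a group without events, or all events on one side) diverge and are
    reported as non-converged.
    """
    x = np.asarray(x, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    n, p = x.shape
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]

    ev_times, first = np.unique(time[event], return_index=True)
    # per distinct event time: total deaths d_j, deaths with x=1, at-risk with x=1
    d_j = np.array([np.sum(event & (time == t)) for t in ev_times], dtype=np.int64)
    d1 = np.vstack([x[event & (time == t)].sum(axis=0) for t in ev_times])  # (J, p)
    # suffix sums give risk-set counts (time sorted ascending)
    x_suffix = np.cumsum(x[::-1], axis=0)[::-1]
    risk_start = np.searchsorted(time, ev_times, side="left")
    n1 = x_suffix[risk_start]  # (J, p)
    nR = (n - risk_start)[:, None]  # total at risk
    n0 = nR - n1
    d0 = d_j[:, None] - d1

    # one term per (event time, l) with l = 0..d_j-1
    j_idx = np.repeat(np.arange(len(ev_times)), d_j)
    frac = np.concatenate([np.arange(d) / d for d in d_j]) if len(d_j) else np.empty(0)
    c0 = n0[j_idx] - frac[:, None] * d0[j_idx]  # (T, p)
    c1 = n1[j_idx] - frac[:, None] * d1[j_idx]
    d1_total = d1.sum(axis=0)

    beta = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        a = np.exp(np.clip(beta, -500, 500))
        denom = c0 + c1 * a
        with np.errstate(divide="ignore", invalid="ignore"):
            score = d1_total - (c1 * a / denom).sum(axis=0)
            info = (c0 * c1 * a / denom**2).sum(axis=0)
        step = np.where(info > 1e-12, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        beta = np.clip(beta, -50.0, 50.0)
        converged = np.abs(step) < tol
        if converged.all():
            break
    # monotone likelihoods drift to the clip boundary; treat as failed
    diverged = (np.abs(beta) > 20) | ~np.isfinite(beta) | (info <= 1e-12)
    converged = converged & ~diverged
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(converged, 1.0 / np.sqrt(info), np.nan)
    beta = np.where(converged, beta, np.nan)
    return beta, se, converged


# ---------------------------------------------------------------------------
# HR maps
# ---------------------------------------------------------------------------
@dataclass
class HRMap:
    """Per-pixel hazard ratios of metagene overexpression.

    ``hr`` holds NaN at masked pixels; ``mask`` is True wherever the
    high-expression arm (or its complement) fell below the minimum group
    size or the fit did not converge.
    """

    hr: np.ndarray  # (height, width)
    se_log: np.ndarray
    n_high: np.ndarray
    mask: np.ndarray
    threshold_mode: str
    min_group_size: int

    def unmasked_hr(self) -> np.ndarray:
        return self.hr[~self.mask]


def hr_map(
    model: "SOMResults",
    survival: pd.DataFrame,
    threshold_mode: str = "gt-mean",
    min_group_size: int = 5,
) -> HRMap:
    """Per-pixel Cox hazard ratio of metagene overexpression vs the rest.

    ``threshold_mode="gt-mean"`` selects samples with centralized metagene
    expression > 0; ``"gt-1sd"`` selects those > one within-pixel standard
    deviation. Pixels where either arm has fewer than ``min_group_size``
    samples, or where the fit fails, are masked.
    """
    if threshold_mode not in ("gt-mean", "gt-1sd"):
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    if min_group_size < 2:
        raise ValueError("min_group_size must be >= 2")
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    missing = [s for s in model.samples if s not in surv.index]
    if missing:
        raise ValueError(f"survival table missing samples: {missing[:5]}")
    surv = surv.loc[model.samples]
    if (surv["event"] == 0).all():
        raise ValueError("all samples censored; hazard ratios are not estimable")

    proto = model.prototypes.to_numpy()  # (pixels, samples)
    if threshold_mode == "gt-mean":
        indicator = (proto > 0).T.astype(float)
    else:
        sd = proto.std(axis=1, ddof=1, keepdims=True)
        indicator = (proto > sd).T.astype(float)

    n_high = indicator.sum(axis=0)
    n = indicator.shape[0]
    size_ok = (n_high >= min_group_size) & (n - n_high >= min_group_size)

    beta = np.full(model.n_metagenes, np.nan)
    se = np.full(model.n_metagenes, np.nan)
    conv = np.zeros(model.n_metagenes, dtype=bool)
    cols = np.flatnonzero(size_ok)
    if len(cols):
        b, s, c = _cox_binary_efron(
            indicator[:, cols], surv["os_time"].to_numpy(), surv["event"].to_numpy()
        )
        beta[cols], se[cols], conv[cols] = b, s, c

    mask = ~(size_ok & conv)
    hr = np.where(mask, np.nan, np.exp(beta))
    shape = (model.height, model.width)
    return HRMap(
        hr=hr.reshape(shape),
        se_log=se.reshape(shape),
        n_high=n_high.reshape(shape).astype(int),
        mask=mask.reshape(shape),
        threshold_mode=threshold_mode,
        min_group_size=min_group_size,
    )


# ---------------------------------------------------------------------------
# ΔHR score
# ---------------------------------------------------------------------------
@dataclass
class PrognosticScore:
    """The maxHR/minHR pixel pair, their gene lists, and per-sample ΔHR."""

    max_pixel: int
    min_pixel: int
    max_genes: list[str]
    min_genes: list[str]
    scores: pd.Series | None = None


def _padded_gene_list(model: "SOMResults", pixel: int, min_genes: int) -> list[str]:
    """Genes of the pixel, padded ring-by-ring from the 8-neighborhood until
    exactly ``min_genes`` genes are collected (no padding if already there)."""
    genes = model.genes_of_pixels([pixel])
    if len(genes) >= min_genes:
        return genes
    row, col = divmod(pixel, model.width)
    radius = 1
    while len(genes) < min_genes and radius < max(model.width, model.height):
        ring = []
        for r in range(row - radius, row + radius + 1):
            for c in range(col - radius, col + radius + 1):
                if max(abs(r - row), abs(c - col)) != radius:
                    continue
                if 0 <= r < model.height and 0 <= c < model.width:
                    ring.append(r * model.width + c)
        for p in sorted(ring):
            for g in model.genes_of_pixels([p]):
                if g not in genes:
                    genes.append(g)
                    if len(genes) == min_genes:
                        return genes
        radius += 1
    return genes


def extreme_metagenes(
    hrmap: HRMap, model: "SOMResults", min_genes: int = 20
) -> PrognosticScore:
    """Locate the unmasked pixels of maximum and minimum HR.

    Ties resolve to the lower linear pixel index. Gene lists are the genes
    assigned to each extreme pixel, padded with 8-neighborhood genes up to
    ``min_genes``.
    """
    hr = hrmap.hr.ravel()
    valid = ~hrmap.mask.ravel()
    if not valid.any():
        raise ValueError("HR map is fully masked; no extreme metagenes")
    idx = np.flatnonzero(valid)
    max_pixel = int(idx[np.argmax(hr[idx])])
    min_pixel = int(idx[np.argmin(hr[idx])])
    return PrognosticScore(
        max_pixel=max_pixel,
        min_pixel=min_pixel,
        max_genes=_padded_gene_list(model, max_pixel, min_genes),
        min_genes=_padded_gene_list(model, min_pixel, min_genes),
    )


def delta_hr_score(
    matrix: "ExpressionMatrix",
    skeleton: PrognosticScore | None = None,
    max_genes: list[str] | None = None,
    min_genes: list[str] | None = None,
) -> pd.Series:
    """ΔHR(sample) = mean expression over maxHR genes - mean over minHR genes.

    Gene lists come from ``skeleton`` or may be passed directly (e.g. spot
    gene lists for the Δspot variant). Swapping the lists negates the score
    exactly.
    """
    if skeleton is not None:
        max_genes = skeleton.max_genes
        min_genes = skeleton.min_genes
    if not max_genes or not min_genes:
        raise ValueError("both gene lists must be nonempty")
    for name, genes in (("maxHR", max_genes), ("minHR", min_genes)):
        absent = [g for g in genes if g not in matrix.values.index]
        if absent:
            raise ValueError(f"{name} genes absent from the matrix: {absent[:5]}")
    hi = matrix.values.loc[max_genes].mean(axis=0)
    lo = matrix.values.loc[min_genes].mean(axis=0)
    score = (hi - lo).rename("delta_hr")
    if skeleton is not None:
        skeleton.scores = score
    return score


# ---------------------------------------------------------------------------
# risk groups and heterogeneity
# ---------------------------------------------------------------------------
@dataclass
class RiskSplit:
    labels: pd.Series  # 'high' / 'low' / 'mid'
    km_curves: dict  # group -> DataFrame(time, survival)
    logrank_statistic: float
    p_value: float
    percentile: float


def split_risk_groups(
    scores: pd.Series, survival: pd.DataFrame, percentile: float = 25.0
) -> RiskSplit:
    """Top/bottom p% split by ΔHR with Kaplan-Meier curves and log-rank test.

    ``percentile`` in (0, 50]; ties in the score break by sample-ID order so
    the split is deterministic. The high group is the top p% (worst
    predicted prognosis).
    """
    if not 0 < percentile <= 50:
        raise ValueError("percentile must be in (0, 50]")
    scores = pd.Series(scores)
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    missing = [s for s in scores.index if s not in surv.index]
    if missing:
        raise ValueError(f"survival table missing samples: {missing[:5]}")
    n = len(scores)
    k = int(n * percentile / 100)
    if k < 2:
        raise ValueError(f"risk groups of size {k} are too small")
    order = scores.to_frame("score").sort_values(
        ["score"], kind="stable"
    )
    order = order.iloc[np.lexsort((order.index.to_numpy(), order["score"].to_numpy()))]
    low_ids = list(order.index[:k])
    high_ids = list(order.index[-k:])
    labels = pd.Series("mid", index=scores.index)
    labels[low_ids] = "low"
    labels[high_ids] = "high"

    km_curves = {}
    for group, ids in (("high", high_ids), ("low", low_ids)):
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[ids, "os_time"], surv.loc[ids, "event"], label=group)
        sf = kmf.survival_function_
        km_curves[group] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[group].to_numpy()}
        )
    lr = logrank_test(
        surv.loc[high_ids, "os_time"],
        surv.loc[low_ids, "os_time"],
        event_observed_A=surv.loc[high_ids, "event"],
        event_observed_B=surv.loc[low_ids, "event"],
    )
    return RiskSplit(
        labels=labels,
        km_curves=km_curves,
        logrank_statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
        percentile=percentile,
    )


def patient_heterogeneity(scores: pd.Series, patients: pd.Series) -> tuple[pd.DataFrame, dict]:
    """Per-patient mean and SD of lesion-level ΔHR scores.

    Returns the per-patient table ranked by ascending mean (SD missing for
    single-lesion patients) and a summary dict with the range of patient
    means and the mean within-patient SD — the inter- versus intra-patient
    heterogeneity contrast.
    """
    scores = pd.Series(scores)
    patients = pd.Series(patients).reindex(scores.index)
    df = pd.DataFrame({"score": scores, "patient": patients})
    table = (
        df.groupby("patient")["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else np.nan, n="count")
        .sort_values("mean")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    multi = table["sd"].dropna()
    summary = {
        "range_of_patient_means": float(table["mean"].max() - table["mean"].min()),
        "mean_within_patient_sd": float(multi.mean()) if len(multi) else np.nan,
        "n_patients": int(len(table)),
        "n_multi_lesion_patients": int(len(multi)),
    }
    return table, summary


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------
class PrognosticModel:
    """Survival layer over a fitted SOM portrayal.

    Parameters
    ----------
    som : SOMResults
    matrix : ExpressionMatrix
        Centralized expression used for the ΔHR gene-list means (usually
        the matrix the SOM was trained on).
    survival : pandas.DataFrame
        Columns sample, os_time, event (optionally patient).
    """

    def __init__(self, som: "SOMResults", matrix: "ExpressionMatrix", survival: pd.DataFrame):
        self.som = som
        self.matrix = matrix
        self.survival = survival

    def fit(
        self,
        threshold_mode: str = "gt-mean",
        min_group_size: int = 5,
        min_genes: int = 20,
        spot_gene_lists: tuple[list[str], list[str]] | None = None,
    ) -> "PrognosticResults":
        """Build the HR map, the extreme-metagene skeleton, and ΔHR scores.

        ``spot_gene_lists=(risk_genes, protective_genes)`` switches the
        score to the Δspot variant (spot gene lists replace the extreme
        pixels' lists; the HR map is still computed).
        """
        hrm = hr_map(self.som, self.survival, threshold_mode, min_group_size)
        skeleton = extreme_metagenes(hrm, self.som, min_genes=min_genes)
        if spot_gene_lists is not None:
            scores = delta_hr_score(
                self.matrix, max_genes=list(spot_gene_lists[0]), min_genes=list(spot_gene_lists[1])
            )
            skeleton.scores = scores
        else:
            scores = delta_hr_score(self.matrix, skeleton)
        return PrognosticResults(model=self, hrmap=hrm, skeleton=skeleton, scores=scores)


@dataclass
class PrognosticResults:
    model: PrognosticModel
    hrmap: HRMap
    skeleton: PrognosticScore
    scores: pd.Series

    def split_risk_groups(self, percentile: float = 25.0) -> RiskSplit:
        return split_risk_groups(self.scores, self.model.survival, percentile)

    def patient_heterogeneity(self, patients: pd.Series | None = None):
        if patients is None:
            surv = self.model.survival
            if "patient" not in surv.columns:
                raise ValueError("no patient IDs available")
            patients = surv.set_index("sample")["patient"]
        return patient_heterogeneity(self.scores, patients)

    def score_table(self) -> pd.DataFrame:
        ranked = self.scores.sort_values(kind="stable")
        return pd.DataFrame(
            {"delta_hr": ranked, "rank": np.arange(1, len(ranked) + 1)}
        )

    def summary(self) -> str:
        hrm = self.hrmap
        valid = hrm.unmasked_hr()
        lines = [
            "Prognostic map results",
            "======================",
            f"threshold mode:   {hrm.threshold_mode}",
            f"unmasked pixels:  {valid.size} / {hrm.hr.size}",
            f"HR range:         {valid.min():.3f} .. {valid.max():.3f}",
            f"maxHR pixel:      {self.skeleton.max_pixel} "
            f"({len(self.skeleton.max_genes)} genes)",
            f"minHR pixel:      {self.skeleton.min_pixel} "
            f"({len(self.skeleton.min_genes)} genes)",
            f"ΔHR score range:  {self.scores.min():.3f} .. {self.scores.max():.3f}",
        ]
        return "\n".join(lines)
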