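"""Signature discovery: univariate Cox screening, FDR shortlisting,
bidirectional stepwise multivariate Cox selection, and the Schoenfeld
proportional-hazards check.

Screening fits one Cox model per gene on the training split; genes at
Benjamini-Hochberg FDR <= 0.05 (default) enter a bidirectional stepwise
search over multivariate Cox models scored by partial-likelihood AIC.
The selected genes with their multivariate coefficients form the
signature whose linear predictor is the patient risk score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _coxlik
from .profiles import ProfileKind, ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR_CUTOFF = 0.05


@dataclass(frozen=True)
class CoxScreenResult:
    """Univariate Cox output for one gene."""

    gene: str
    coefficient: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the hazard ratio")


@dataclass(frozen=True)
class Signature:
    """Ordered (gene, coefficient) pairs; the risk score is their dot product."""

    genes: tuple[str, ...]
    coefficients: tuple[float, ...]
    profile_kind: ProfileKind | None = None
    cancer_label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be distinct")

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=list(self.genes), name="coefficient")


def align_survival(matrix: ProfileMatrix, clinical) -> tuple[np.ndarray, np.ndarray]:
    """Durations and event indicators aligned to the matrix patient order."""
    by_id = {}
    for c in clinical:
        if c.patient_id in by_id:
            raise ValueError(f"duplicate clinical record for {c.patient_id}")
        by_id[c.patient_id] = c
    missing = [p for p in matrix.patients if p not in by_id]
    if missing:
        raise ValueError(f"no clinical record for patient(s): {missing[:5]}")
    t = np.array([by_id[p].time for p in matrix.patients], dtype=float)
    e = np.array([by_id[p].event for p in matrix.patients], dtype=bool)
    return t, e


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_cox_screen(
    matrix: ProfileMatrix,
    clinical,
    ties: str = "efron",
) -> list[CoxScreenResult]:
    """Per-gene single-covariate Cox fits with BH-adjusted p-values.

    The p-value is the partial-likelihood-ratio test against the null
    model, which stays calibrated for the sparse, heavily skewed columns
    typical of mutation profiles (the Wald test is anti-conservative
    there); confidence intervals are the usual Wald intervals.  Genes
    whose fit does not converge (degenerate or separated columns) are
    retained with p = 1 and ``converged=False`` so downstream gene
    bookkeeping stays exact.
    """
    t, e = align_survival(matrix, clinical)
    if e.sum() < 2:
        raise ValueError("univariate screen needs >= 2 observed events")

    beta, se, ll, converged = _coxlik.fit_univariate_batch(matrix.values, t, e, ties=ties)
    ll0 = _coxlik.null_loglik(t, e, ties=ties)
    z975 = stats.norm.ppf(0.975)
    lr_stat = np.maximum(2.0 * (ll - ll0), 0.0)
    p = np.where(converged, stats.chi2.sf(lr_stat, df=1), 1.0)
    q = bh_adjust(p)

    results = []
    for j, gene in enumerate(matrix.genes):
        if converged[j]:
            b = float(beta[j])
            lo = float(np.exp(b - z975 * se[j]))
            hi = float(np.exp(b + z975 * se[j]))
        else:
            b, lo, hi = 0.0, 0.0, np.inf
        results.append(
            CoxScreenResult(
                gene=gene,
                coefficient=b,
                hr=float(np.exp(b)),
                ci_low=lo,
                ci_high=hi,
                p=float(p[j]),
                q=float(q[j]),
                converged=bool(converged[j]),
            )
        )
    n_flagged = int((~converged).sum())
    if n_flagged:
        logger.info("univariate_cox_screen: %d gene(s) flagged non-estimable", n_flagged)
    return results


def screen_to_frame(results) -> pd.DataFrame:
    """Tabular view of screen results (one row per gene)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "coefficient": [r.coefficient for r in results],
            "HR": [r.hr for r in results],
            "Lower .95": [r.ci_low for r in results],
            "Upper .95": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "converged": [r.converged for r in results],
        }
    ).set_index("gene")


def shortlist(results, q_cutoff: float = DEFAULT_FDR_CUTOFF) -> list[str]:
    """Genes significant at the FDR cutoff (inclusive), ascending q."""
    hits = [r for r in results if r.q <= q_cutoff]
    hits.sort(key=lambda r: (r.q, r.p, r.gene))
    if not hits:
        logger.warning("shortlist: no gene passes FDR <= %.3g", q_cutoff)
    return [r.gene for r in hits]


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop later columns that are linear combinations of earlier ones."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    return x[:, keep], [names[j] for j in keep], dropped


def _fit_subset(x, t, e, ties):
    beta, cov, ll, ok = _coxlik.fit_cox(x, t, e, ties=ties)
    aic = -2.0 * ll + 2.0 * x.shape[1]
    return beta, cov, ll, aic, ok


def model_aic(matrix: ProfileMatrix, clinical, genes, ties: str = "efron") -> float:
    """Partial-likelihood AIC of the multivariate Cox model on ``genes``.

    An empty gene list gives the null model's AIC.
    """
    t, e = align_survival(matrix, clinical)
    if not genes:
        return -2.0 * _coxlik.null_loglik(t, e, ties=ties)
    cols = [matrix.genes.index(g) for g in genes]
    _, _, _, aic, _ = _fit_subset(matrix.values[:, cols], t, e, ties)
    return aic


def stepwise_cox(
    matrix: ProfileMatrix,
    clinical,
    candidates,
    ties: str = "efron",
    start: str = "full",
) -> Signature:
    """Bidirectional stepwise multivariate Cox selection by AIC.

    Starting from the full candidate model (or the empty model with
    ``start='empty'``), repeatedly applies the single add-or-drop move
    that most improves the partial-likelihood AIC, until no move improves
    it.  Dropping to the empty model is a legal move but the empty model
    can never be returned as an improvement over a fitting single gene
    unless its AIC is genuinely lower.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("stepwise_cox needs a non-empty candidate list")
    missing = [g for g in candidates if g not in matrix.genes]
    if missing:
        raise ValueError(f"candidate gene(s) not in profile matrix: {missing}")
    t, e = align_survival(matrix, clinical)

    cols = {g: matrix.genes.index(g) for g in candidates}
    x_all = matrix.values[:, [cols[g] for g in candidates]]
    x_all, candidates, dropped = _drop_collinear(x_all, candidates)
    if dropped:
        logger.warning("stepwise_cox: dropped collinear candidate(s): %s", dropped)
    if not candidates:
        raise ValueError("all candidate columns are degenerate/collinear")
    col_of = {g: j for j, g in enumerate(candidates)}

    null_aic = -2.0 * _coxlik.null_loglik(t, e, ties=ties)
    cache: dict[frozenset, float] = {frozenset(): null_aic}

    def aic_of(genes: frozenset) -> float:
        if genes not in cache:
            x = x_all[:, sorted(col_of[g] for g in genes)]
            try:
                _, _, _, aic, ok = _fit_subset(x, t, e, ties)
                cache[genes] = aic if ok else np.inf
            except np.linalg.LinAlgError:
                cache[genes] = np.inf
        return cache[genes]

    current = frozenset(candidates) if start == "full" else frozenset()
    current_aic = aic_of(current)
    if not np.isfinite(current_aic) and start == "full":
        raise ValueError(f"full candidate model does not fit: {sorted(current)}")

    while True:
        moves = [current - {g} for g in current]
        moves += [current | {g} for g in candidates if g not in current]
        best, best_aic = None, current_aic
        for m in moves:
            a = aic_of(m)
            if a < best_aic - 1e-10:
                best, best_aic = m, a
        if best is None:
            break
        current, current_aic = best, best_aic

    if not current:
        logger.warning("stepwise_cox: AIC prefers the empty model; empty signature")
        return Signature(genes=(), coefficients=(), profile_kind=matrix.kind)

    selected = sorted(current, key=lambda g: col_of[g])
    x = x_all[:, [col_of[g] for g in selected]]
    beta, _, _, _, ok = _fit_subset(x, t, e, ties)
    if not ok:
        raise ValueError(f"final model failed to converge: {selected}")
    return Signature(
        genes=tuple(selected),
        coefficients=tuple(float(b) for b in beta),
        profile_kind=matrix.kind,
    )


@dataclass(frozen=True)
class PHCheck:
    """Scaled Schoenfeld-residual diagnostics for a fitted signature.

    Reported, never used to alter the signature automatically.
    """

    gene_pvalues: dict[str, float]
    global_statistic: float
    global_p: float
    df: int


def ph_check(signature: Signature, matrix: ProfileMatrix, clinical, time_transform: str = "rank") -> PHCheck:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Per-gene tests come from lifelines' ``proportional_hazard_test``;
    the global chi-square combines the Schoenfeld residuals across all
    signature genes, as R ``survival::cox.zph`` does.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    if len(signature) == 0:
        raise ValueError("cannot PH-check an empty signature")
    t, e = align_survival(matrix, clinical)
    df = matrix.to_frame()[list(signature.genes)].copy()
    df["_time"] = t
    df["_event"] = e.astype(int)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    res = proportional_hazard_test(cph, df, time_transform=time_transform)
    per_gene = {g: float(res.summary.loc[g, "p"]) for g in signature.genes}

    # global Grambsch-Therneau statistic from unscaled Schoenfeld residuals:
    # T = d * u' V u / sum((g - gbar)^2), u = sum_k (g_k - gbar) s_k
    sres = cph.compute_residuals(df, kind="schoenfeld")
    times_by_pid = pd.Series(t, index=df.index)
    ev_times = times_by_pid.loc[sres.index].to_numpy()
    order = np.argsort(ev_times, kind="mergesort")
    s = sres[list(signature.genes)].to_numpy()[order]
    tt = ev_times[order]
    if time_transform == "rank":
        gt = stats.rankdata(tt, method="average")
    elif time_transform == "identity":
        gt = tt.astype(float)
    else:
        raise ValueError("time_transform must be 'rank' or 'identity'")
    gt = gt - gt.mean()
    d = tt.size
    u = gt @ s
    v = cph.variance_matrix_.loc[list(signature.genes), list(signature.genes)].to_numpy()
    denom = float(gt @ gt)
    stat = d * float(u @ v @ u) / denom if denom > 0 else 0.0
    p_global = float(stats.chi2.sf(stat, df=len(signature)))
    return PHCheck(gene_pvalues=per_gene, global_statistic=stat, global_p=p_global, df=len(signature))
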