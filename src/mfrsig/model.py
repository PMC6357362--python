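"""Model/Results interface over the discovery and evaluation stages.

:class:`SignatureCoxModel` bundles a patient x gene profile matrix with
overall-survival data; :meth:`SignatureCoxModel.fit` runs the univariate
Cox screen, the FDR shortlist and the bidirectional stepwise multivariate
Cox selection, and returns a :class:`SignatureCoxResults` carrying the
selected signature, its hazard ratios with confidence intervals, the
proportional-hazards diagnostics and a ``summary()`` table.  Risk scoring,
stratification and Kaplan-Meier evaluation hang off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discovery, evaluation
from .discovery import PHCheck, Signature
from .profiles import ProfileKind, ProfileMatrix, build_profile, filter_rare_genes, log2_transform

logger = logging.getLogger(__name__)


class SignatureCoxModel:
    """Prognostic gene-signature discovery on one training cohort.

    Parameters
    ----------
    profile
        Training-split profile matrix (already rare-gene-filtered and, for
        continuous kinds, log2-transformed).
    clinical
        Clinical records covering every profile patient.
    fdr_cutoff
        Benjamini-Hochberg threshold for the univariate shortlist.
    ties
        Tie handling for the Cox partial likelihood, ``"efron"`` (default)
        or ``"breslow"``.
    start
        Stepwise starting point, ``"full"`` (default) or ``"empty"``.
    """

    def __init__(
        self,
        profile: ProfileMatrix,
        clinical,
        fdr_cutoff: float = discovery.DEFAULT_FDR_CUTOFF,
        ties: str = "efron",
        start: str = "full",
    ) -> None:
        self.profile = profile
        self.clinical = list(clinical)
        self.fdr_cutoff = fdr_cutoff
        self.ties = ties
        self.start = start
        # validate alignment early
        discovery.align_survival(profile, self.clinical)

    @classmethod
    def from_mutations(
        cls,
        records,
        clinical,
        kind: ProfileKind | str = ProfileKind.MFR,
        rare_min_fraction: float = 0.01,
        log2: bool = True,
        **kwargs,
    ) -> "SignatureCoxModel":
        """Build the model straight from missense mutation records.

        Convenience constructor for single-cohort use: profiles are built
        over the clinical patients, rare genes filtered on the same
        cohort, and continuous kinds log2-transformed.
        """
        clinical = list(clinical)
        kind = ProfileKind(kind)
        patients = tuple(c.patient_id for c in clinical)
        prof = build_profile(records, patients, kind)
        prof = filter_rare_genes(prof, patients, rare_min_fraction)
        if log2 and kind in (ProfileKind.TMF, ProfileKind.MFR):
            prof = log2_transform(prof)
        return cls(prof, clinical, **kwargs)

    def fit(self) -> "SignatureCoxResults":
        """Screen, shortlist and stepwise-select the signature."""
        screen = discovery.univariate_cox_screen(self.profile, self.clinical, ties=self.ties)
        shortlisted = discovery.shortlist(screen, q_cutoff=self.fdr_cutoff)
        if not shortlisted:
            signature = Signature(genes=(), coefficients=(), profile_kind=self.profile.kind)
            return SignatureCoxResults(self, screen, shortlisted, signature, None, None)
        signature = discovery.stepwise_cox(
            self.profile, self.clinical, shortlisted, ties=self.ties, start=self.start
        )
        if len(signature) == 0:
            return SignatureCoxResults(self, screen, shortlisted, signature, None, None)
        try:
            ph = discovery.ph_check(signature, self.profile, self.clinical)
        except Exception:
            logger.warning("PH check failed to fit; diagnostics omitted", exc_info=True)
            ph = None
        table = _signature_table(signature, self.profile, self.clinical)
        return SignatureCoxResults(self, screen, shortlisted, signature, table, ph)


def _signature_table(signature: Signature, profile: ProfileMatrix, clinical) -> pd.DataFrame:
    """Final-model hazard ratios and 95% CIs.

    Uses a lifelines refit; if lifelines' Newton iterations fail on a
    nearly-separated column, the in-package solver's estimates (which use
    step-halving) are reported instead.
    """
    from lifelines import CoxPHFitter

    t, e = discovery.align_survival(profile, clinical)
    genes = list(signature.genes)
    df = profile.to_frame()[genes].copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        s = cph.summary
        out = pd.DataFrame(
            {
                "coefficient": s["coef"],
                "HR": s["exp(coef)"],
                "Lower .95": s["exp(coef) lower 95%"],
                "Upper .95": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        ).loc[genes]
    except Exception:  # lifelines ConvergenceError and kin
        logger.warning("lifelines refit failed; reporting in-package Cox estimates")
        from scipy import stats

        from . import _coxlik

        cols = [profile.genes.index(g) for g in genes]
        beta, cov, _, _ = _coxlik.fit_cox(profile.values[:, cols], t, e)
        se = np.sqrt(np.diag(cov))
        z = stats.norm.ppf(0.975)
        out = pd.DataFrame(
            {
                "coefficient": beta,
                "HR": np.exp(beta),
                "Lower .95": np.exp(beta - z * se),
                "Upper .95": np.exp(beta + z * se),
                "p": 2 * stats.norm.sf(np.abs(beta) / se),
            },
            index=genes,
        )
    out.index.name = "Gene"
    return out


@dataclass
class SignatureCoxResults:
    """Fitted signature with diagnostics and evaluation helpers."""

    model: SignatureCoxModel
    screen: list
    shortlisted: list
    signature: Signature
    signature_table: pd.DataFrame | None
    ph: PHCheck | None

    @property
    def converged(self) -> bool:
        return len(self.signature) > 0

    @property
    def params(self) -> pd.Series:
        return self.signature.as_series()

    @property
    def screen_frame(self) -> pd.DataFrame:
        return discovery.screen_to_frame(self.screen)

    @property
    def aic(self) -> float:
        return discovery.model_aic(
            self.model.profile, self.model.clinical, list(self.signature.genes), ties=self.model.ties
        )

    # ---- evaluation -------------------------------------------------

    def risk_scores(self, profile: ProfileMatrix | None = None) -> dict[str, float]:
        return evaluation.risk_scores(self.signature, profile or self.model.profile)

    def training_threshold(self, percentile: float = evaluation.DEFAULT_PERCENTILE) -> float:
        return evaluation.percentile_threshold(self.risk_scores().values(), percentile)

    def evaluate(
        self,
        profile: ProfileMatrix,
        clinical,
        threshold: float | None = None,
        split_label: str = "validation",
        percentile: float = evaluation.DEFAULT_PERCENTILE,
    ) -> evaluation.RiskStratification:
        """Stratify a split at the training-percentile threshold and log-rank test it."""
        if threshold is None:
            threshold = self.training_threshold(percentile)
        return evaluation.evaluate_split(self.signature, profile, clinical, threshold, split_label)

    def kaplan_meier(self, stratification: evaluation.RiskStratification, clinical) -> dict:
        """KM curve per risk group of a stratification."""
        curves = {}
        for label in ("high", "low"):
            members = [p for p, g in stratification.groups.items() if g == label]
            if members:
                curves[label] = evaluation.km_estimate(members, clinical)
        return curves

    def plot_km(self, stratification, clinical, ax=None, title: str | None = None):
        """Plot high- vs low-risk Kaplan-Meier curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.kaplan_meier(stratification, clinical).items():
            ax.step(curve.times, curve.survival, where="post", label=f"{label} risk")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        if title is None:
            title = f"log-rank p = {stratification.logrank_p:.4g} ({stratification.split_label.value})"
        ax.set_title(title)
        return ax

    # ---- reporting --------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = []
        kind = self.model.profile.kind.value
        n, g = self.model.profile.shape
        lines.append("Somatic-mutation prognostic signature (Cox PH)")
        lines.append("=" * 52)
        lines.append(f"profile kind: {kind:>10}    patients: {n}    genes: {g}")
        n_events = sum(1 for c in self.model.clinical if c.event)
        lines.append(
            f"events: {n_events}    FDR cutoff: {self.model.fdr_cutoff}"
            f"    shortlisted genes: {len(self.shortlisted)}"
        )
        if not self.converged:
            lines.append("-" * 52)
            lines.append("no gene passed selection; empty signature")
            return "\n".join(lines)
        lines.append(f"selected signature: {len(self.signature)} gene(s), AIC = {self.aic:.2f}")
        lines.append("-" * 52)
        table = self.signature_table.copy()
        lines.append(table.to_string(float_format=lambda v: f"{v:.4f}"))
        if self.ph is not None:
            lines.append("-" * 52)
            lines.append(
                f"PH check (Schoenfeld, global): chi2 = {self.ph.global_statistic:.3f}"
                f" on {self.ph.df} df, p = {self.ph.global_p:.4f}"
            )
        return "\n".join(lines)
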