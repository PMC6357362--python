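"""Cox screening, BH adjustment, stepwise selection, PH diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfrsig.discovery import (
    Signature,
    bh_adjust,
    model_aic,
    ph_check,
    shortlist,
    stepwise_cox,
    univariate_cox_screen,
)
from mfrsig.profiles import ProfileKind
from mfrsig.synthetic import SimulationConfig, generate_cohort, gene_name
from mfrsig import build_profile, log2_transform

from conftest import brute_force_bh, gaussian_survival_cohort, make_clinical, make_profile


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.005, 0.02, 0.2]), [0.015, 0.03, 0.2])

    def test_ties_and_identity_bound(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.01]), [0.01, 0.01])
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestUnivariateScreen:
    def test_parameter_recovery_known_effect(self):
        # one covariate truly doubling the hazard, n = 500
        prof, clin = gaussian_survival_cohort(3, n=500, n_genes=3, beta=[np.log(2), 0, 0])
        res = {r.gene: r for r in univariate_cox_screen(prof, clin)}
        assert 1.6 <= res["G000"].hr <= 2.5
        assert res["G000"].q < 0.05

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        prof, clin = gaussian_survival_cohort(11, n=150, n_genes=4, beta=[0.5, -0.5, 0, 0])
        res = univariate_cox_screen(prof, clin)
        t = np.array([c.time for c in clin])
        e = np.array([c.event for c in clin])
        for j, r in enumerate(res):
            df = pd.DataFrame({"x": prof.values[:, j], "t": t, "e": e.astype(int)})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert r.coefficient == pytest.approx(float(cph.params_.iloc[0]), abs=1e-4)
            assert np.log(r.hr) == pytest.approx(r.coefficient)
            se = float(cph.standard_errors_.iloc[0])
            assert r.ci_low == pytest.approx(np.exp(r.coefficient - 1.959964 * se), rel=1e-3)

    def test_degenerate_column_flagged_not_dropped(self):
        prof, clin = gaussian_survival_cohort(5, n=80, n_genes=2)
        vals = prof.values.copy()
        vals[:, 1] = 0.0
        prof2 = make_profile(vals, kind=prof.kind, log2_applied=True)
        res = univariate_cox_screen(prof2, clin)
        assert len(res) == 2
        flagged = res[1]
        assert not flagged.converged and flagged.p == 1.0 and flagged.hr == 1.0

    def test_permutation_invariance(self):
        prof, clin = gaussian_survival_cohort(6, n=60, n_genes=3, beta=[0.4, 0, 0])
        res = univariate_cox_screen(prof, clin)
        perm = np.random.default_rng(0).permutation(60)
        prof2 = make_profile(
            prof.values[perm], kind=prof.kind, log2_applied=True,
            patients=[prof.patients[i] for i in perm],
        )
        res2 = univariate_cox_screen(prof2, clin)
        for a, b in zip(res, res2):
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-10)
            assert a.q == pytest.approx(b.q, abs=1e-12)

    def test_gene_order_invariance_of_q(self):
        prof, clin = gaussian_survival_cohort(8, n=80, n_genes=4, beta=[0.6, -0.6, 0, 0])
        res = {r.gene: r.q for r in univariate_cox_screen(prof, clin)}
        rev = make_profile(
            prof.values[:, ::-1], kind=prof.kind, log2_applied=True,
            genes=list(prof.genes)[::-1], patients=prof.patients,
        )
        res_rev = {r.gene: r.q for r in univariate_cox_screen(rev, clin)}
        for g in res:
            assert res[g] == pytest.approx(res_rev[g], abs=1e-12)

    def test_no_events_rejected(self):
        prof = make_profile(np.random.default_rng(0).normal(size=(10, 2)))
        clin = make_clinical(range(1, 11), [False] * 10)
        with pytest.raises(ValueError):
            univariate_cox_screen(prof, clin)


class TestShortlist:
    def _results(self, qs):
        prof, clin = gaussian_survival_cohort(1, n=40, n_genes=len(qs))
        base = univariate_cox_screen(prof, clin)
        import dataclasses

        return [dataclasses.replace(r, q=q) for r, q in zip(base, qs)]

    def test_boundary_inclusive_and_sorted(self):
        res = self._results([0.051, 0.01, 0.05])
        assert shortlist(res) == ["G001", "G002"]

    def test_degenerate_outcomes(self):
        assert shortlist(self._results([0.2, 0.9])) == []
        assert len(shortlist(self._results([0.2, 0.9]), q_cutoff=1.0)) == 2


class TestStepwise:
    def test_single_candidate_keeps_univariate_fit(self):
        prof, clin = gaussian_survival_cohort(2, n=200, n_genes=2, beta=[0.8, 0])
        uni = {r.gene: r for r in univariate_cox_screen(prof, clin)}
        sig = stepwise_cox(prof, clin, ["G000"])
        assert sig.genes == ("G000",)
        assert sig.coefficients[0] == pytest.approx(uni["G000"].coefficient, abs=1e-6)

    def test_collinear_candidate_dropped(self):
        prof, clin = gaussian_survival_cohort(4, n=150, n_genes=2, beta=[0.7, 0])
        vals = np.column_stack([prof.values, 2.0 * prof.values[:, 0]])
        prof2 = make_profile(vals, log2_applied=True, genes=["G000", "G001", "G000_DUP"])
        sig = stepwise_cox(prof2, clin, ["G000", "G000_DUP"])
        assert "G000" in sig.genes and "G000_DUP" not in sig.genes

    def test_matches_exhaustive_enumeration(self):
        # 6 candidates, 2 with real effects: greedy bidirectional search
        # must land on the global AIC minimum found by enumeration
        prof, clin = gaussian_survival_cohort(9, n=250, n_genes=6, beta=[0.7, -0.7, 0, 0, 0, 0])
        genes = list(prof.genes)
        best_set, best_aic = None, np.inf
        for r in range(1, 7):
            for combo in itertools.combinations(genes, r):
                a = model_aic(prof, clin, list(combo))
                if a < best_aic:
                    best_set, best_aic = frozenset(combo), a
        sig = stepwise_cox(prof, clin, genes)
        assert frozenset(sig.genes) == best_set

    def test_never_worse_than_full_or_best_single(self):
        for seed in (21, 22, 23):
            prof, clin = gaussian_survival_cohort(seed, n=120, n_genes=5, beta=[0.6, 0.4, 0, 0, 0])
            genes = list(prof.genes)
            sig = stepwise_cox(prof, clin, genes)
            aic_sel = model_aic(prof, clin, list(sig.genes))
            assert aic_sel <= model_aic(prof, clin, genes) + 1e-9
            best_single = min(model_aic(prof, clin, [g]) for g in genes)
            assert aic_sel <= best_single + 1e-9

    def test_empty_candidates_rejected(self):
        prof, clin = gaussian_survival_cohort(1, n=40, n_genes=2)
        with pytest.raises(ValueError):
            stepwise_cox(prof, clin, [])


class TestPHCheck:
    def test_empty_signature_rejected(self):
        prof, clin = gaussian_survival_cohort(1, n=40, n_genes=2)
        with pytest.raises(ValueError):
            ph_check(Signature((), ()), prof, clin)

    def test_detects_sign_reversing_effect(self):
        # hazard effect reverses mid-follow-up: global p should be small
        # in the clear majority of replicates
        rejected = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_patients=500, n_genes=5,
                signature_genes=((gene_name(0), 0.8), (gene_name(2), 0.6)),
                background_mutation_rate=0.2, signature_prevalence=0.5,
                time_varying_effects=True, seed=seed,
            )
            records, clinical, _ = generate_cohort(cfg)
            pats = tuple(c.patient_id for c in clinical)
            prof = log2_transform(build_profile(records, pats, ProfileKind.MFR))
            sig = Signature((gene_name(0), gene_name(2)), (0.0, 0.0))
            rejected += ph_check(sig, prof, clinical).global_p < 0.05
        assert rejected >= 6

    def test_reports_every_gene(self):
        prof, clin = gaussian_survival_cohort(13, n=200, n_genes=3, beta=[0.5, -0.5, 0])
        sig = stepwise_cox(prof, clin, list(prof.genes))
        check = ph_check(sig, prof, clin)
        assert set(check.gene_pvalues) == set(sig.genes)
        assert 0 <= check.global_p <= 1 and check.df == len(sig)
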