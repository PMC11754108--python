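"""Destabilization calling, Fisher/MCC statistics and clinical evaluation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

import domstab as ds
from domstab.qc import NormalizedFitness
from domstab.stability import (
    StabilityCall,
    call_destabilizing,
    evaluate_classifier,
    fisher_or,
    mcc_from_counts,
    resample_mcc,
    summarize_stability_classes,
)


def nf(f, sigma=0.05, domain="D1", pos=1, wt="A", mut="V"):
    return NormalizedFitness(
        domain_id=domain, position=pos, wt_aa=wt, mut_aa=mut,
        variant_class="missense", f_norm=f, sigma_norm=sigma,
        scale_factor=1.0, offset=0.0,
    )


class TestDestabilizationCalling:
    def test_neutral_variant_never_destabilizing(self):
        calls = call_destabilizing([nf(0.0)])
        assert calls[0].p == pytest.approx(0.5)
        assert calls[0].stability_class == "stable"

    def test_extreme_z_is_strong(self):
        variants = [nf(-0.5, 0.05, pos=i + 1) for i in range(5)]
        calls = call_destabilizing(variants)
        assert all(c.stability_class == "strong" for c in calls)
        assert calls[0].z == pytest.approx(-10.0)

    def test_mild_vs_strong_partition(self):
        variants = [nf(-0.2, 0.01, pos=1), nf(-0.5, 0.01, pos=2),
                    nf(0.1, 0.01, pos=3)]
        calls = call_destabilizing(variants)
        assert [c.stability_class for c in calls] == \
            ["mild", "strong", "stable"]

    def test_zero_sigma_errors(self):
        with pytest.raises(ValueError, match="sigma_norm"):
            call_destabilizing([nf(-0.5, 0.0)])

    def test_null_calibration(self):
        """Under a pure null the fraction called destabilizing stays below
        the nominal FDR plus Monte-Carlo slack."""
        rng = np.random.default_rng(0)
        sigma = 0.1
        variants = [nf(float(rng.normal(0, sigma)), sigma, pos=i + 1)
                    for i in range(10_000)]
        calls = call_destabilizing(variants, fdr_threshold=0.1)
        frac = np.mean([c.destabilizing for c in calls])
        se = np.sqrt(0.1 * 0.9 / 10_000)
        assert frac <= 0.1 + 3 * se

    def test_q_ge_p(self):
        rng = np.random.default_rng(1)
        variants = [nf(float(rng.normal(0, 0.1)), 0.1, pos=i + 1)
                    for i in range(200)]
        calls = call_destabilizing(variants)
        assert all(c.q >= c.p for c in calls)


def synthetic_calls_and_annotations(counts):
    """Build calls + annotations realizing exact per-label class counts.

    counts: {label: (n_stable, n_mild, n_strong)}
    """
    calls, anns = [], []
    pos = 0
    for label, (n_stable, n_mild, n_strong) in counts.items():
        for cls, n in (("stable", n_stable), ("mild", n_mild),
                       ("strong", n_strong)):
            for _ in range(n):
                pos += 1
                f = {"stable": 0.0, "mild": -0.2, "strong": -0.5}[cls]
                calls.append(
                    StabilityCall("D1", pos, "A", "V", f, 0.05, 0.0, 0.5,
                                  0.5, cls)
                )
                anns.append(
                    ds.ClinicalAnnotation(
                        "D1", pos, "A", "V", label,
                        allele_frequency=1e-3 if label == "population"
                        else None,
                    )
                )
    return calls, anns


class TestSummarize:
    def test_reproduces_reference_clinical_percentages(self):
        """380/621 destabilizing (61%) and 303/621 strong (49%) pathogenic;
        129/322 (40%) and 50/322 (16%) for benign."""
        calls, anns = synthetic_calls_and_annotations(
            {"pathogenic": (241, 77, 303), "benign": (193, 79, 50)}
        )
        table = summarize_stability_classes(calls, anns)
        path = table[table.label == "pathogenic"].iloc[0]
        ben = table[table.label == "benign"].iloc[0]
        assert path["n"] == 621 and ben["n"] == 322
        assert path["pct_destabilizing"] == pytest.approx(100 * 380 / 621)
        assert path["pct_strong"] == pytest.approx(100 * 303 / 621)
        assert ben["pct_destabilizing"] == pytest.approx(100 * 129 / 322)
        assert ben["pct_strong"] == pytest.approx(100 * 50 / 322)

    def test_percentages_sum_to_100(self):
        calls, anns = synthetic_calls_and_annotations(
            {"pathogenic": (3, 2, 5), "benign": (4, 0, 1)}
        )
        table = summarize_stability_classes(calls, anns)
        for _, row in table.iterrows():
            if row["n"]:
                total = row["pct_stable"] + row["pct_mild"] + \
                    row["pct_strong"]
                assert total == pytest.approx(100.0)

    def test_single_variant_group(self):
        calls, anns = synthetic_calls_and_annotations({"vus": (0, 1, 0)})
        table = summarize_stability_classes(calls, anns)
        row = table[table.label == "vus"].iloc[0]
        assert row["n"] == 1
        assert row["pct_destabilizing"] == pytest.approx(100.0)

    def test_empty_group_no_division(self):
        calls, anns = synthetic_calls_and_annotations({"vus": (1, 0, 0)})
        table = summarize_stability_classes(calls, anns)
        row = table[table.label == "benign"].iloc[0]
        assert row["n"] == 0
        assert np.isnan(row["pct_destabilizing"])


def brute_force_fisher_p(table):
    """Exact two-tailed p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    obs = hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= obs * (1 + 1e-7):
            p += px
    return min(p, 1.0)


class TestFisher:
    def test_symmetric_table(self):
        orr, p, _ = fisher_or([[10, 10], [10, 10]])
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cells_haldane_correction(self):
        orr, p, _ = fisher_or([[5, 0], [0, 5]])
        assert orr == pytest.approx(121.0)  # (5.5*5.5)/(0.5*0.5)
        assert p == pytest.approx(2 / 252)  # both extreme tables

    def test_matches_exhaustive_enumeration(self):
        """p equals brute-force enumeration for margins up to 15."""
        rng = np.random.default_rng(2)
        for _ in range(300):
            r1 = int(rng.integers(1, 16))
            r2 = int(rng.integers(1, 16))
            c1 = int(rng.integers(0, r1 + r2 + 1))
            a = int(rng.integers(max(0, c1 - r2), min(r1, c1) + 1))
            table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
            _, p, _ = fisher_or(table)
            assert p == pytest.approx(brute_force_fisher_p(table),
                                      rel=1e-9, abs=1e-12)

    def test_invalid_cells(self):
        with pytest.raises(ValueError):
            fisher_or([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_or([[1.5, 2], [3, 4]])


class TestMCC:
    def test_matches_sklearn_oracle(self):
        """Closed-form MCC equals sklearn's on 200 random tables."""
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            assert mcc_from_counts(tp, fp, tn, fn) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_perfect_separation(self):
        calls, anns = synthetic_calls_and_annotations(
            {"pathogenic": (0, 0, 20), "benign": (20, 0, 0)}
        )
        ev = evaluate_classifier(calls, anns)
        assert ev.mcc == pytest.approx(1.0)

    def test_random_predictions_near_zero(self):
        rng = np.random.default_rng(4)
        calls, anns = [], []
        for i in range(2000):
            cls = "strong" if rng.uniform() < 0.5 else "stable"
            label = "pathogenic" if rng.uniform() < 0.5 else "benign"
            calls.append(
                StabilityCall("D1", i + 1, "A", "V", 0.0, 0.05, 0, 0.5,
                              0.5, cls))
            anns.append(ds.ClinicalAnnotation("D1", i + 1, "A", "V", label))
        ev = evaluate_classifier(calls, anns)
        assert abs(ev.mcc) < 0.05

    def test_single_class_reported_as_nan(self):
        calls, anns = synthetic_calls_and_annotations(
            {"pathogenic": (5, 0, 5)}
        )
        ev = evaluate_classifier(calls, anns)
        assert np.isnan(ev.mcc)
        assert ev.reason


class TestROC:
    def test_auc_equals_mann_whitney(self):
        """ROC AUC equals the Mann-Whitney U normalization."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        scores, anns = {}, []
        for i in range(300):
            label = "pathogenic" if i % 3 == 0 else "benign"
            key = ("D1", i + 1, "A", "V")
            scores[key] = float(rng.normal(1.0 if label == "pathogenic"
                                           else 0.0))
            anns.append(ds.ClinicalAnnotation(*key, label))
        ev = evaluate_classifier(scores, anns)
        pos = [scores[a.key] for a in anns if a.label == "pathogenic"]
        neg = [scores[a.key] for a in anns if a.label == "benign"]
        u = mannwhitneyu(pos, neg).statistic
        assert ev.auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_population_variants_respect_af_floor(self):
        anns = [
            ds.ClinicalAnnotation("D1", 1, "A", "V", "pathogenic"),
            ds.ClinicalAnnotation("D1", 2, "A", "V", "population",
                                  allele_frequency=1e-3),
            ds.ClinicalAnnotation("D1", 3, "A", "V", "population",
                                  allele_frequency=1e-6),  # below floor
        ]
        calls = [
            StabilityCall("D1", 1, "A", "V", -0.5, 0.05, 0, 0, 0, "strong"),
            StabilityCall("D1", 2, "A", "V", 0.0, 0.05, 0, 0.5, 0.5,
                          "stable"),
            StabilityCall("D1", 3, "A", "V", 0.0, 0.05, 0, 0.5, 0.5,
                          "stable"),
        ]
        ev = evaluate_classifier(calls, anns, af_floor=1e-5)
        assert ev.n == 2  # the rare population variant is excluded


class TestResampleMCC:
    @staticmethod
    def _fixture(sigma):
        rng = np.random.default_rng(6)
        variants, anns = [], []
        for i in range(200):
            patho = i % 2 == 0
            f = -0.6 if patho else 0.0
            variants.append(nf(f + float(rng.normal(0, 0.02)), sigma,
                               pos=i + 1))
            anns.append(
                ds.ClinicalAnnotation("D1", i + 1, "A", "V",
                                      "pathogenic" if patho else "benign")
            )
        return variants, anns

    def test_tiny_sigma_gives_zero_sd(self):
        variants, anns = self._fixture(1e-6)
        assert resample_mcc(variants, anns, n=5, seed=0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        variants, anns = self._fixture(0.2)
        a = resample_mcc(variants, anns, n=5, seed=3)
        b = resample_mcc(variants, anns, n=5, seed=3)
        assert a == b

    def test_sd_increases_with_sigma(self):
        v1, anns = self._fixture(0.05)
        v10, _ = self._fixture(0.5)
        sd1 = resample_mcc(v1, anns, n=10, seed=1)
        sd10 = resample_mcc(v10, anns, n=10, seed=1)
        assert sd10 > sd1

    def test_requires_two_resamples(self):
        variants, anns = self._fixture(0.1)
        with pytest.raises(ValueError, match="n >= 2"):
            resample_mcc(variants, anns, n=1)
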