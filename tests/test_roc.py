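"""ROC curves, AUC, Youden point, DeLong test, partition evaluation."""

import warnings

import numpy as np
import pytest

import ovadx as ox
from ovadx.roc import auc_mann_whitney, evaluate_by_partition


def brute_force_auc(scores, labels):
    """All positive/negative pairs, ties worth half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive threshold scan (score >= t calls positive)."""
    best = None
    y = np.asarray(labels)
    for t in [-np.inf] + sorted(set(scores)):
        pred = np.asarray(scores) >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-15:
            best = (j, t, sens, spec)
    return best[1:]


class TestROCCurve:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        r = ox.roc_curve(scores, labels)
        assert r.auc == 1.0
        _, sens, spec = r.youden_point
        assert sens == 1.0 and spec == 1.0

    def test_constant_scores_give_half(self):
        assert ox.roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=20) / 4  # many ties
        labels = rng.integers(0, 2, size=20)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            brute_force_auc(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_sensitivity_non_increasing_in_threshold(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        r = ox.roc_curve(scores, labels)
        assert (np.diff(r.sensitivities) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ox.roc_curve([0.1, 0.2], [1, 1])

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestYouden:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=25) / 5
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        r = ox.roc_curve(scores, labels)
        t, sens, spec = ox.youden_operating_point(r)
        bt, bsens, bspec = brute_force_youden(scores.tolist(), labels.tolist())
        assert sens + spec == pytest.approx(bsens + bspec, abs=1e-12)
        assert t == bt  # lowest-threshold tie-break matches scan order

    def test_reversed_scores_symmetry(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        j1 = sum(ox.roc_curve(scores, labels).youden_point[1:]) - 1
        j2 = sum(ox.roc_curve(-scores, 1 - labels).youden_point[1:]) - 1
        assert j1 == pytest.approx(j2, abs=1e-12)


class TestDeLong:
    def test_identical_scores_z_zero_p_one(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        res = ox.delong_test(scores, scores, labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        r1 = ox.delong_test(a, b, labels)
        r2 = ox.delong_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            ox.delong_test([0.1, 0.2], [0.3], [0, 1])

    def test_variance_agrees_with_paired_bootstrap(self):
        """DeLong variance of the AUC difference vs a 2000-resample paired
        bootstrap, within 15% relative."""
        rng = np.random.default_rng(42)
        n = 150
        latent = rng.standard_normal(n)
        labels = (latent + rng.standard_normal(n) > 0).astype(int)
        labels[:2] = [0, 1]
        a = latent + 0.8 * rng.standard_normal(n)
        b = 0.5 * latent + rng.standard_normal(n)
        res = ox.delong_test(a, b, labels)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) < 2:
                continue
            boot.append(auc_mann_whitney(a[idx], labels[idx])
                        - auc_mann_whitney(b[idx], labels[idx]))
        boot_var = np.var(boot, ddof=1)
        assert res.var_diff == pytest.approx(boot_var, rel=0.15)

    def test_agrees_with_r_proc_reference(self, tmp_path):
        """Cross-check z and p against pROC's roc.test (DeLong) in R."""
        import subprocess

        rng = np.random.default_rng(3)
        n = 80
        latent = rng.standard_normal(n)
        labels = (latent > 0).astype(int)
        labels[:2] = [0, 1]
        a = latent + rng.standard_normal(n)
        b = rng.standard_normal(n)
        res = ox.delong_test(a, b, labels)
        data = tmp_path / "scores.csv"
        np.savetxt(data, np.column_stack([labels, a, b]), delimiter=",",
                   header="y,a,b", comments="")
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"d <- read.csv('{data}')\n"
            "r <- roc.test(roc(d$y, d$a, quiet=TRUE, direction='<'),"
            " roc(d$y, d$b, quiet=TRUE, direction='<'),"
            " method='delong', paired=TRUE)\n"
            "cat(r$statistic, r$p.value)\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        z_ref, p_ref = float(out[0]), float(out[1])
        assert res.z == pytest.approx(z_ref, abs=1e-6)
        assert res.p == pytest.approx(p_ref, abs=1e-6)


class TestEvaluateByPartition:
    def test_single_tag_equals_plain_curve(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        res = evaluate_by_partition(scores, labels, ["all"] * 30)
        assert res["all"].auc == ox.roc_curve(scores, labels).auc

    def test_untagged_rows_shared_across_partitions(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        tags = ["early", "early", "late", None, None, None]
        res = evaluate_by_partition(scores, labels, tags)
        assert set(res) == {"early", "late"}
        assert res["early"].auc == 1.0 and res["late"].auc == 1.0

    def test_single_class_partition_skipped_with_warning(self):
        scores = np.array([0.9, 0.1, 0.8, 0.7])
        labels = np.array([1, 0, 1, 1])
        with pytest.warns(UserWarning, match="single class"):
            res = evaluate_by_partition(scores, labels,
                                        ["g1", "g1", "cases-only", "cases-only"])
        assert "cases-only" not in res and "g1" in res


class TestNullCalibration:
    def test_delong_z_standard_normal_under_null(self):
        """Simulated null (two uninformative score vectors): the z statistic
        should be approximately N(0,1) — KS check, loose bound."""
        from scipy import stats

        rng = np.random.default_rng(99)
        zs = []
        n = 500
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        for _ in range(200):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            zs.append(ox.delong_test(a, b, labels).z)
        _, p = stats.kstest(zs, "norm")
        assert p > 0.01
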