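"""Nearest-centroid classifier: fitting, scoring, and its invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sigaudit as sa
from sigaudit.cohorts import SigauditError

from conftest import pairwise_auc


def brute_force_fit(values, labels):
    """Independent plain-Python refit: standardize each gene over all
    samples (sample sd), average within class.  Returns (means, sds,
    centroid_pos, centroid_neg) as lists."""
    means, sds, cpos, cneg = [], [], [], []
    n = len(labels)
    for row in values:
        m = sum(row) / n
        sd = math.sqrt(sum((v - m) ** 2 for v in row) / (n - 1))
        z = [(v - m) / sd for v in row]
        pos = [z[i] for i in range(n) if labels[i] == 1]
        neg = [z[i] for i in range(n) if labels[i] == 0]
        means.append(m)
        sds.append(sd)
        cpos.append(sum(pos) / len(pos))
        cneg.append(sum(neg) / len(neg))
    return means, sds, cpos, cneg


def brute_force_scores(model_tuple, values, eps=1e-12):
    """Independent scorer: euclidean distances in standardized space."""
    means, sds, cpos, cneg = model_tuple
    n = len(values[0])
    out = []
    for j in range(n):
        z = [(values[g][j] - means[g]) / sds[g] for g in range(len(means))]
        d_pos = math.sqrt(sum((z[g] - cpos[g]) ** 2 for g in range(len(z))))
        d_neg = math.sqrt(sum((z[g] - cneg[g]) ** 2 for g in range(len(z))))
        out.append((d_neg - d_pos) / (d_neg + d_pos + eps))
    return out


class TestFit:
    def test_worked_fixture_matches_hand_arithmetic(self, worked_cohort):
        """g1=[1,3,5,7] has mean 4, sd sqrt(20/3); g2=[2,0,2,4] mean 2,
        sd sqrt(8/3).  Responder centroid = (-2/s1, -1/s2), non-responder
        = (+2/s1, +1/s2)."""
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        s1, s2 = math.sqrt(20 / 3), math.sqrt(8 / 3)
        assert model.genes_used == ("g1", "g2")
        assert model.means == pytest.approx([4.0, 2.0], abs=1e-15)
        assert model.sds == pytest.approx([s1, s2], abs=1e-15)
        assert model.centroid_pos == pytest.approx([-2 / s1, -1 / s2], abs=1e-14)
        assert model.centroid_neg == pytest.approx([2 / s1, 1 / s2], abs=1e-14)
        # cross-check against the generic brute-force refit
        bf = brute_force_fit(worked_cohort.values.tolist(), [1, 1, 0, 0])
        assert model.centroid_pos == pytest.approx(bf[2], abs=1e-14)
        assert model.centroid_neg == pytest.approx(bf[3], abs=1e-14)

    def test_constant_within_class_centroids(self):
        """Genes constant within class map each class onto the
        standardized image of its constant."""
        cohort = sa.ExpressionCohort(
            "const", ["g1", "g2"], ["a", "b", "c", "d"],
            np.array([[3.0, 3.0, 1.0, 1.0], [0.0, 0.0, 4.0, 4.0]]),
            np.array([1, 1, 0, 0]),
        )
        model = sa.CentroidClassifier(
            cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        # standardized image of the class constants
        z1 = (3.0 - 2.0) / np.std([3, 3, 1, 1], ddof=1)
        z2 = (0.0 - 2.0) / np.std([0, 0, 4, 4], ddof=1)
        assert model.centroid_pos == pytest.approx([z1, z2], abs=1e-14)
        assert model.centroid_neg == pytest.approx([-z1, -z2], abs=1e-14)

    def test_signature_intersection(self, worked_cohort):
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g2", "gX", "gY", "g1", "gZ"])
        ).fit()
        assert model.genes_used == ("g2", "g1")  # signature order kept

    def test_disjoint_signature_rejected(self, worked_cohort):
        with pytest.raises(SigauditError, match="no genes"):
            sa.CentroidClassifier(
                worked_cohort, sa.GeneSignature("sig", ["nope"])
            ).fit()

    def test_zero_variance_gene_dropped(self, worked_cohort):
        cohort = sa.ExpressionCohort(
            "zv", ["g1", "flat"], worked_cohort.samples,
            np.array([[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 2.0, 2.0]]),
            worked_cohort.labels,
        )
        model = sa.CentroidClassifier(
            cohort, sa.GeneSignature("sig", ["g1", "flat"])
        ).fit()
        assert model.genes_used == ("g1",)
        assert model.genes_dropped_zero_sd == ("flat",)


class TestScore:
    def test_worked_fixture_scores_match_brute_force(self, worked_cohort):
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        expected = brute_force_scores(
            brute_force_fit(worked_cohort.values.tolist(), [1, 1, 0, 0]),
            worked_cohort.values.tolist(),
        )
        assert model.score(worked_cohort) == pytest.approx(expected, abs=1e-12)

    def test_sample_at_positive_centroid_scores_one(self, worked_cohort):
        """Raw profile (2, 1) standardizes exactly onto the responder
        centroid, so d_pos = 0 and s -> 1; the hard call is responder."""
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        probe = sa.ExpressionCohort(
            "probe", ["g1", "g2"], ["p", "q"],
            np.array([[2.0, 6.0], [1.0, 3.0]]),  # q = centroid_neg image
            np.array([1, 0]),
        )
        s = model.score(probe)
        assert s[0] == pytest.approx(1.0, abs=1e-9)
        assert s[1] == pytest.approx(-1.0, abs=1e-9)
        assert model.predict(probe).tolist() == [1, 0]

    def test_equidistant_sample_scores_zero(self, worked_cohort):
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        probe = sa.ExpressionCohort(
            "mid", ["g1", "g2"], ["m", "x"],
            np.array([[4.0, 1.0], [2.0, 0.0]]),  # m = the raw gene means
            np.array([1, 0]),
        )
        s = model.score(probe)
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert model.predict(probe)[0] == 0  # ties go to non-responder

    def test_missing_genes_dropped_with_warning(self, worked_cohort):
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        g1_only = sa.ExpressionCohort(
            "g1only", ["g1"], ["a", "b"],
            np.array([[2.0, 6.0]]), np.array([1, 0]),
        )
        with pytest.warns(UserWarning, match="1 of 2 model genes"):
            s = model.score(g1_only)
        # with g2 gone the score is the 1-d calculation on g1 alone
        bf = brute_force_fit([[1.0, 3.0, 5.0, 7.0]], [1, 1, 0, 0])
        assert s == pytest.approx(
            brute_force_scores(bf, [[2.0, 6.0]]), abs=1e-12
        )

    def test_all_genes_missing_is_an_error(self, worked_cohort):
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        other = sa.ExpressionCohort(
            "other", ["h1"], ["a", "b"], np.array([[0.0, 1.0]]),
            np.array([1, 0]),
        )
        with pytest.raises(SigauditError, match="shares no genes"):
            model.score(other)


class TestInvariances:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, scale):
        """Rescaling one gene's raw values everywhere leaves every score
        unchanged — standardization absorbs the units."""
        rng = np.random.default_rng(7)
        values = rng.normal(size=(4, 12))
        labels = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0, 0, 1])
        base = sa.ExpressionCohort(
            "c", ["g1", "g2", "g3", "g4"], [f"s{i}" for i in range(12)],
            values, labels,
        )
        scaled_values = values.copy()
        scaled_values[2, :] *= scale
        scaled = sa.ExpressionCohort(
            "c", base.genes, base.samples, scaled_values, labels
        )
        sig = sa.GeneSignature("sig", base.genes)
        s0 = sa.CentroidClassifier(base, sig).fit().score(base)
        s1 = sa.CentroidClassifier(scaled, sig).fit().score(scaled)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_label_swap_negates_scores(self, worked_cohort):
        sig = sa.GeneSignature("sig", ["g1", "g2"])
        s = sa.CentroidClassifier(worked_cohort, sig).fit().score(worked_cohort)
        flipped = sa.ExpressionCohort(
            "flip", worked_cohort.genes, worked_cohort.samples,
            worked_cohort.values, 1 - worked_cohort.labels,
        )
        s_flip = sa.CentroidClassifier(flipped, sig).fit().score(flipped)
        assert s_flip == pytest.approx(-s, abs=1e-12)

    def test_separable_training_data_gives_resubstitution_auc_one(self):
        cohort = sa.ExpressionCohort(
            "sep", ["g1", "g2"], ["a", "b", "c", "d", "e", "f"],
            np.array(
                [[5.0, 5.1, 4.9, 1.0, 1.1, 0.9],
                 [0.0, 0.2, -0.1, 3.0, 3.1, 2.9]]
            ),
            np.array([1, 1, 1, 0, 0, 0]),
        )
        model = sa.CentroidClassifier(
            cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        roc = sa.compute_roc(model.score(cohort), cohort.labels)
        assert roc.auc == 1.0

    def test_correlation_metric_scores_by_profile_shape(self):
        """Under correlation distance a sample proportional to the
        responder centroid profile scores positive regardless of offset."""
        rng = np.random.default_rng(3)
        values = rng.normal(size=(6, 10))
        labels = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        cohort = sa.ExpressionCohort(
            "c", [f"g{i}" for i in range(6)], [f"s{i}" for i in range(10)],
            values, labels,
        )
        sig = sa.GeneSignature("sig", cohort.genes)
        model = sa.CentroidClassifier(cohort, sig, "correlation").fit()
        # probe expression whose standardized image is centroid_pos + offset
        raw = model.means + model.sds * (model.centroid_pos + 5.0)
        probe = sa.ExpressionCohort(
            "p", cohort.genes, ["x", "y"],
            np.column_stack([raw, raw]), np.array([1, 0]),
        )
        assert (model.score(probe) > 0).all()

    def test_roundtrip_serialization(self, worked_cohort):
        model = sa.CentroidClassifier(
            worked_cohort, sa.GeneSignature("sig", ["g1", "g2"])
        ).fit()
        clone = sa.CentroidClassifierResults.from_json(model.to_json())
        assert clone.genes_used == model.genes_used
        assert clone.score(worked_cohort) == pytest.approx(
            model.score(worked_cohort), abs=0
        )

    def test_resubstitution_auc_matches_pairwise_oracle(self, null_config):
        cohort = sa.generate_cohorts(null_config)[0]
        sig = sa.GeneSignature("sig", cohort.genes[:60])
        model = sa.CentroidClassifier(cohort, sig).fit()
        scores = model.score(cohort)
        auc = sa.compute_roc(scores, cohort.labels).auc
        assert auc == pytest.approx(
            pairwise_auc(scores.tolist(), cohort.labels.tolist()), abs=1e-12
        )
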