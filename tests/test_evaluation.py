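import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screensim import (
    CRISPRN,
    Gene,
    GeneClass,
    KDResponse,
    LibraryConfig,
    auprc,
    build_library,
    signal_noise,
    theoretical_phenotypes,
    top_overlap,
)
from screensim.evaluation import _pr_points


def brute_force_auprc(scores, labels):
    """Oracle: walk every distinct threshold, count TP/FP directly, then
    integrate the PR points trapezoidally with the recall-0 anchor."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    total_pos = labels.sum()
    points = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = np.sum(pred & labels)
        points.append((tp / total_pos, tp / pred.sum()))
    r = [0.0] + [pt[0] for pt in points]
    p = [points[0][1]] + [pt[1] for pt in points]
    area = 0.0
    for i in range(1, len(r)):
        area += (r[i] - r[i - 1]) * (p[i] + p[i - 1]) / 2
    return area


class TestAuprc:
    def test_perfect_ranking(self):
        scores = [5, 4, 3, 2, 1]
        labels = [1, 1, 0, 0, 0]
        assert auprc(scores, labels) == pytest.approx(1.0)

    def test_all_tied_gives_prevalence(self):
        labels = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        assert auprc(np.ones(10), labels) == pytest.approx(0.2)

    def test_matches_brute_force_on_random_instances(self):
        """Vectorized estimator equals threshold-walking oracle on 100
        random instances of up to 20 genes (with score ties)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 21)
            labels = np.zeros(n, bool)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if labels.all():
                labels[rng.integers(n)] = False
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, rng.random()], n)
            assert auprc(scores, labels) == pytest.approx(
                brute_force_auprc(scores, labels)
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auprc([1, 2], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_area_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        labels = rng.random(n) < 0.3
        if not labels.any():
            labels[0] = True
        if labels.all():
            labels[-1] = False
        area = auprc(rng.normal(size=n), labels)
        assert 0.0 <= area <= 1.0

    def test_recall_reaches_one(self):
        rng = np.random.default_rng(0)
        recall, _ = _pr_points(rng.normal(size=30), rng.random(30) < 0.4)
        assert recall[-1] == pytest.approx(1.0)


def toy_genome(phenotypes):
    genes = []
    for i, l in enumerate(phenotypes):
        cls = (
            GeneClass.WILDTYPE
            if l == 0
            else GeneClass.POSITIVE_HIT
            if l > 0
            else GeneClass.NEGATIVE_HIT
        )
        genes.append(Gene(i, cls, float(l), KDResponse("linear")))
    return genes


class TestTopOverlap:
    def test_identity_and_disjoint(self):
        genome = toy_genome([0.9, -0.8, 0.7, 0.0, 0.0, 0.0])
        perfect = pd.DataFrame({"gene_id": [0, 1, 2, 3, 4, 5], "rank": [1, 2, 3, 4, 5, 6]})
        assert top_overlap(perfect, genome, n=3) == 1.0
        inverted = pd.DataFrame({"gene_id": [3, 4, 5, 0, 1, 2], "rank": [1, 2, 3, 4, 5, 6]})
        assert top_overlap(inverted, genome, n=3) == 0.0

    def test_partial_overlap(self):
        genome = toy_genome([1.0, 0.9, 0.8, 0.7, 0.6, 0, 0, 0, 0, 0])
        called = pd.DataFrame(
            {"gene_id": [0, 1, 2, 3, 9, 4, 5, 6, 7, 8], "rank": range(1, 11)}
        )
        assert top_overlap(called, genome, n=5) == pytest.approx(0.8)

    def test_row_order_invariance(self):
        genome = toy_genome([0.9, -0.8, 0.7, 0.0])
        called = pd.DataFrame({"gene_id": [2, 0, 1, 3], "rank": [3, 1, 2, 4]})
        shuffled = called.sample(frac=1, random_state=0)
        assert top_overlap(called, genome, n=2) == top_overlap(shuffled, genome, n=2)

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_overlap(pd.DataFrame({"gene_id": [0], "rank": [1]}), toy_genome([0.5]), n=2)


def guide_frame(gene_ids, classes, log2fc):
    n = len(log2fc)
    arr = np.asarray(log2fc, dtype=float)
    return pd.DataFrame(
        {
            "guide_id": np.arange(n),
            "gene_id": gene_ids,
            "class": classes,
            "log2fc": arr,
            "dropped": np.isnan(arr),
        }
    )


class TestSignalNoise:
    def test_unit_signal_when_log2fc_equals_theoretical(self):
        df = guide_frame(
            [0, 0, 1, 1, 2, 2],
            ["positive_hit"] * 2 + ["negative_hit"] * 2 + ["negative_control"] * 2,
            [0.5, 0.7, -0.4, -0.6, 0.1, -0.1],
        )
        theo = np.array([0.5, 0.7, -0.4, -0.6, 0.0, 0.0])
        signal, noise, snr = signal_noise(df, theo)
        assert signal == pytest.approx(1.0)
        assert noise == pytest.approx(np.std([0.1, -0.1], ddof=1))
        assert snr == pytest.approx(signal / noise)

    def test_equal_control_phenotypes_give_missing_snr(self):
        df = guide_frame(
            [0, 0, 1, 1],
            ["positive_hit"] * 2 + ["negative_control"] * 2,
            [0.5, 0.7, 0.2, 0.2],
        )
        signal, noise, snr = signal_noise(df, np.array([0.5, 0.7, 0.0, 0.0]))
        assert noise == 0.0
        assert np.isnan(snr)

    def test_dropped_guides_excluded_from_signal(self):
        df = guide_frame(
            [0, 0, 1, 1],
            ["positive_hit"] * 2 + ["negative_control"] * 2,
            [1.0, np.nan, 0.3, -0.3],
        )
        signal, _, _ = signal_noise(df, np.array([0.5, 0.5, 0.0, 0.0]))
        assert signal == pytest.approx(2.0)


class TestTheoreticalPhenotypes:
    def test_crispri_uses_guide_efficiency(self, small_genome, small_library):
        theo = theoretical_phenotypes(small_genome, small_library)
        g = small_genome[int(small_library.gene_id[0])]
        from screensim import cell_phenotype

        assert theo[0] == pytest.approx(cell_phenotype(g, small_library.efficiency[0]))

    def test_crisprn_active_guides_average_outcome_mix(self, small_genome, crisprn_library):
        from screensim import cell_phenotype

        theo = theoretical_phenotypes(small_genome, crisprn_library)
        active = np.flatnonzero(crisprn_library.efficiency == 1.0)
        i = active[0]
        g = small_genome[int(crisprn_library.gene_id[i])]
        expected = (
            cell_phenotype(g, 0.0) / 9
            + 4 * cell_phenotype(g, 0.5) / 9
            + 4 * cell_phenotype(g, 1.0) / 9
        )
        assert theo[i] == pytest.approx(expected)
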