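"""Rank-based group comparison and discriminant classification."""

import numpy as np
import pytest

from phycotox.stats import (
    LdaConfig,
    TreatmentDataset,
    kruskal_letters,
    lda_classify,
)
from phycotox.synthetic import SimulationConfig, generate_ojip

SIX = [str(t) for t in (0, 10, 50, 100, 250, 500)]


def scalar_dataset(groups: dict[str, list[float]]) -> TreatmentDataset:
    treatments = list(groups)
    labels = np.concatenate([[t] * len(v) for t, v in groups.items()])
    values = np.concatenate([groups[t] for t in treatments])
    return TreatmentDataset(treatments, labels, values[:, None])


class TestKruskalLetters:
    def test_identical_groups_share_one_letter(self):
        r = kruskal_letters(scalar_dataset({"a": [1, 2, 3], "b": [1, 2, 3]}))
        assert r.statistic == pytest.approx(0.0)
        assert r.letters == {"a": "a", "b": "a"}

    def test_three_separated_groups_get_three_letters(self):
        """Hand-checkable rank arithmetic: pooled ranks are 1..9 exactly, mean
        ranks 2/5/8, S^2 = 7.5, H = 7.2; all pairwise mean-rank gaps exceed
        the Bonferroni rank-LSD (2.75)."""
        r = kruskal_letters(scalar_dataset({
            "a": [1, 2, 3], "b": [101, 102, 103], "c": [201, 202, 203]}))
        assert r.statistic == pytest.approx(7.2)
        assert sorted(r.letters.values()) == ["a", "b", "c"]
        assert r.mean_ranks == {"a": 2.0, "b": 5.0, "c": 8.0}

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = {t: list(rng.normal(float(i), 1.0, 8)) for i, t in enumerate(SIX)}
        r1 = kruskal_letters(scalar_dataset(groups))
        r2 = kruskal_letters(scalar_dataset(
            {t: list(np.exp(np.asarray(v))) for t, v in groups.items()}))
        assert r1.letters == r2.letters
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_nonsignificant_omnibus_gates_posthoc(self):
        rng = np.random.default_rng(10)
        groups = {t: list(rng.normal(0.0, 1.0, 6)) for t in SIX}
        r = kruskal_letters(scalar_dataset(groups))
        if r.pvalue >= 0.05:
            assert set(r.letters.values()) == {"a"}
            assert r.different == {}

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            scalar_dataset({"a": [1.0], "b": [1, 2, 3]})

    def test_letters_deterministic_and_in_dose_order(self):
        groups = {"0": [1, 2, 3], "10": [1.5, 2.5, 3.5], "50": [101, 102, 103]}
        r1 = kruskal_letters(scalar_dataset(groups))
        r2 = kruskal_letters(scalar_dataset(groups))
        assert r1.letters == r2.letters
        assert r1.letters["0"].startswith("a")

    def test_null_rejection_rate_near_alpha(self):
        rej = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            groups = {t: list(rng.standard_normal(18)) for t in SIX}
            rej += kruskal_letters(scalar_dataset(groups)).pvalue < 0.05
        # binomial 99% CI around 0.05 for 400 sims
        assert 0.022 <= rej / n_sims <= 0.078


class TestLdaClassify:
    def test_perfectly_separated_classes_are_classified_exactly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((10, 2)),
                       rng.standard_normal((10, 2)) + 200.0])
        y = np.array(["a"] * 10 + ["b"] * 10)
        r = lda_classify(TreatmentDataset(["a", "b"], y, X))
        assert r.resub_accuracy == 1.0
        assert r.loo_accuracy == 1.0

    def test_single_class_raises(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            lda_classify(TreatmentDataset(["a", "a"], np.array(["a"] * 10), X))

    def test_confusion_rows_sum_to_class_sizes(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((8, 4)) + i for i in range(3)])
        y = np.repeat(["a", "b", "c"], 8)
        r = lda_classify(TreatmentDataset(["a", "b", "c"], y, X))
        assert (r.confusion.sum(axis=1) == 8).all()

    def test_curve_dataset_reduction_and_grouping_separation(self):
        """Default-effect OJIP cohort: the three imposed curve-shape groupings
        (control+10, 50-100, 250-500 here collapse as {0},{10,50,100},{250,500}
        by amplitude/efficiency profile) must be distinguished with LOO
        accuracy >= 0.8 at the grouping level."""
        cfg = SimulationConfig(seed=42)
        transients, _ = generate_ojip(cfg)
        grid = transients[0].times_us
        X = np.vstack([np.interp(grid, t.times_us, t.values) for t in transients])
        y = np.array([t.treatment for t in transients])
        r = lda_classify(TreatmentDataset(SIX, y, X, grid=grid))
        gmap = {"0": "ctl", "10": "low", "50": "low", "100": "low",
                "250": "high", "500": "high"}
        total = r.confusion.to_numpy().sum()
        correct = sum(r.confusion.loc[t, p]
                      for t in SIX for p in SIX if gmap[t] == gmap[p])
        assert correct / total >= 0.8
        # grouping centroids occupy distinct regions on LD1
        proj = r.projections
        cent = {g: proj.loc[proj.treatment.map(gmap) == g, "LD1"].mean()
                for g in ("ctl", "low", "high")}
        spread = {g: proj.loc[proj.treatment.map(gmap) == g, "LD1"].std()
                  for g in ("ctl", "low", "high")}
        vals = sorted(cent.values())
        assert min(np.diff(vals)) > max(spread.values())

    def test_label_permutation_drops_accuracy_to_chance(self):
        cfg = SimulationConfig(seed=42)
        transients, _ = generate_ojip(cfg)
        grid = transients[0].times_us
        X = np.vstack([np.interp(grid, t.times_us, t.values) for t in transients])
        y = np.array([t.treatment for t in transients])
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(6):
            r = lda_classify(TreatmentDataset(SIX, rng.permutation(y), X))
            accs.append(r.loo_accuracy)
        assert np.mean(accs) == pytest.approx(1.0 / 6.0, abs=0.05)
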