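"""Dose-group inference: rank-based multiple comparison and discriminant
classification.

``kruskal_letters`` reproduces the nonparametric workflow common in
ecotoxicology when normality/homoscedasticity fail: a tie-corrected
Kruskal-Wallis omnibus test gates pairwise comparisons of mean ranks by
Fisher's least-significant-difference criterion with Bonferroni-adjusted
alpha, summarized as a compact letter display (groups sharing a letter are
not significantly different).

``lda_classify`` performs linear discriminant analysis of treatment groups
from per-sample feature vectors (scalar endpoints or whole curves resampled
onto a common grid).  Because curve datasets have many more grid points than
samples, features are standardized and, when dimensionality >= sample count
(or always, if configured), reduced by a deterministic variance-ranked
principal-component projection before the discriminant fit.  Both
resubstitution and leave-one-out accuracies are reported; leave-one-out is
the conservative headline figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "TreatmentDataset",
    "GroupComparisonResult",
    "DiscriminantResult",
    "LdaConfig",
    "kruskal_letters",
    "lda_classify",
]


@dataclass
class TreatmentDataset:
    """Replicate-structured container binding samples to ordered dose labels.

    ``features`` is (n_samples, n_features); scalar endpoints use a single
    column.  ``grid`` optionally stores the common abscissa (time, wavelength)
    of curve features.
    """

    treatments: list[str]  # ordered dose levels
    labels: np.ndarray  # per-sample treatment label
    features: np.ndarray  # (n_samples, n_features)
    grid: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per sample required")
        if len(self.treatments) < 2:
            raise ValueError("need at least 2 treatments")
        present = set(self.labels.tolist())
        missing = [t for t in self.treatments if t not in present]
        if missing:
            raise ValueError(f"no samples for treatments {missing}")
        for t in self.treatments:
            if int(np.sum(self.labels == t)) < 2:
                raise ValueError(f"treatment {t!r} has fewer than 2 replicates")

    def group_values(self) -> list[np.ndarray]:
        """Per-treatment arrays (scalar endpoint: first feature column)."""
        return [self.features[self.labels == t, 0] for t in self.treatments]


@dataclass
class GroupComparisonResult:
    treatments: list[str]
    statistic: float
    pvalue: float
    alpha: float
    bonferroni_alpha: float
    mean_ranks: dict[str, float]
    #: (i, j) -> significantly different?
    different: dict[tuple[str, str], bool]
    letters: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatments,
                "mean_rank": [self.mean_ranks[t] for t in self.treatments],
                "letters": [self.letters[t] for t in self.treatments],
            }
        )


def _compact_letters(
    treatments: list[str], different: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from a single letter covering all treatments; every significantly
    different pair splits the letter groups that contain both; redundant
    (subset) groups are absorbed.  Letters are assigned alphabetically in the
    given treatment order, which makes the display deterministic.
    """
    groups: list[set[str]] = [set(treatments)]
    pairs = [(a, b) for i, a in enumerate(treatments) for b in treatments[i + 1:]
             if different.get((a, b), False)]
    for a, b in pairs:
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb: drop any group contained in another
        groups = []
        for g in new_groups:
            if not any(g < h or (g == h and h in groups) for h in new_groups if h is not g):
                if g not in groups:
                    groups.append(g)
    # order groups by first member's treatment index for stable lettering
    order = {t: i for i, t in enumerate(treatments)}
    groups.sort(key=lambda g: min(order[t] for t in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {t: "" for t in treatments}
    for letter, g in zip(alphabet, groups):
        for t in treatments:
            if t in g:
                letters[t] += letter
    return letters


def kruskal_letters(
    dataset: TreatmentDataset, alpha: float = 0.05
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus test with rank-LSD post hoc and letter display.

    The pairwise criterion compares mean ranks: treatments i, j differ when

        |R̄_i − R̄_j| > t_{1−α'/2, N−k} · sqrt( S² · (N−1−H)/(N−k) · (1/n_i + 1/n_j) )

    with S² the variance of the pooled (tie-averaged) ranks, H the KW
    statistic, and α' the Bonferroni-adjusted level α / C(k,2).  Pairwise
    testing only runs when the omnibus test rejects at ``alpha`` (the KW
    gate); otherwise all treatments share one letter.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups = dataset.group_values()
    k = len(groups)
    ns = np.array([g.size for g in groups])
    N = int(ns.sum())

    H, p = sstats.kruskal(*groups)
    pooled = np.concatenate(groups)
    ranks = sstats.rankdata(pooled)
    split = np.split(ranks, np.cumsum(ns)[:-1])
    mean_ranks = {t: float(r.mean()) for t, r in zip(dataset.treatments, split)}
    # rank variance with tie correction built in (ranks are tie-averaged)
    s2 = float((np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1))

    n_pairs = k * (k - 1) // 2
    a_adj = alpha / n_pairs
    df = N - k
    tcrit = sstats.t.ppf(1.0 - a_adj / 2.0, df)
    different: dict[tuple[str, str], bool] = {}
    if p < alpha:
        for i in range(k):
            for j in range(i + 1, k):
                ti, tj = dataset.treatments[i], dataset.treatments[j]
                lsd = tcrit * np.sqrt(
                    s2 * (N - 1 - H) / (N - k) * (1.0 / ns[i] + 1.0 / ns[j])
                )
                different[(ti, tj)] = abs(mean_ranks[ti] - mean_ranks[tj]) > lsd

    letters = _compact_letters(dataset.treatments, different)
    return GroupComparisonResult(
        treatments=list(dataset.treatments),
        statistic=float(H),
        pvalue=float(p),
        alpha=alpha,
        bonferroni_alpha=a_adj,
        mean_ranks=mean_ranks,
        different=different,
        letters=letters,
    )


@dataclass(frozen=True)
class LdaConfig:
    n_components: int = 10  # variance-ranked reduction target
    standardize: bool = True
    #: reduce only when n_features >= n_samples ("auto") or always ("always")
    reduce: str = "auto"
    shrinkage_fallback: bool = True


@dataclass
class DiscriminantResult:
    treatments: list[str]
    projections: pd.DataFrame  # sample_id, treatment, LD1, LD2
    resub_accuracy: float
    loo_accuracy: float
    per_class_loo_accuracy: dict[str, float]
    confusion: pd.DataFrame  # rows = true class (LOO)
    ellipses: dict[str, dict[str, float]]
    notes: list[str] = field(default_factory=list)


def _fixed_sign_pca(n_components: int) -> PCA:
    return PCA(n_components=n_components, svd_solver="full", random_state=0)


def _make_pipeline(cfg: LdaConfig, n_samples: int, n_features: int,
                   n_classes: int, notes: list[str]) -> Pipeline:
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    if cfg.reduce == "always" or (cfg.reduce == "auto" and n_features >= n_samples):
        ncomp = min(cfg.n_components, n_features, n_samples - n_classes)
        steps.append(("reduce", _fixed_sign_pca(ncomp)))
        note = f"variance-ranked reduction to {ncomp} components applied"
        if note not in notes:
            notes.append(note)
    steps.append(("lda", LinearDiscriminantAnalysis(solver="svd")))
    return Pipeline(steps)


def lda_classify(dataset: TreatmentDataset, config: LdaConfig | None = None) -> DiscriminantResult:
    """Linear discriminant classification of treatment groups.

    Fits the discriminant axes on the full dataset for the 2-D projection and
    group ellipses, reports resubstitution accuracy, and recomputes the whole
    pipeline (standardization, reduction, discriminant) inside every
    leave-one-out fold for the cross-validated accuracy, per-class accuracies
    and confusion matrix.  A singular within-class scatter triggers a
    shrinkage (lsqr/auto) refit, noted in ``notes``.
    """
    config = config or LdaConfig()
    X, y = dataset.features, dataset.labels
    classes = list(dataset.treatments)
    if len(set(y.tolist())) < 2:
        raise ValueError("single class: discriminant analysis undefined")
    notes: list[str] = []

    def fit(Xtr, ytr) -> Pipeline:
        pipe = _make_pipeline(config, Xtr.shape[0], Xtr.shape[1], len(classes), notes)
        try:
            pipe.fit(Xtr, ytr)
        except np.linalg.LinAlgError:
            if not config.shrinkage_fallback:
                raise
            pipe.set_params(lda=LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"))
            pipe.fit(Xtr, ytr)
            if "shrinkage fallback applied" not in notes:
                notes.append("shrinkage fallback applied")
        return pipe

    full = fit(X, y)
    resub = float(np.mean(full.predict(X) == y))

    # leave-one-out with per-fold refit
    n = X.shape[0]
    loo_pred = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        loo_pred[i] = fit(X[mask], y[mask]).predict(X[i][None, :])[0]
    loo = float(np.mean(loo_pred == y))

    per_class = {
        t: float(np.mean(loo_pred[y == t] == t)) for t in classes
    }
    conf = pd.DataFrame(
        [[int(np.sum((y == t) & (loo_pred == p))) for p in classes] for t in classes],
        index=classes, columns=classes,
    )

    # 2-D projection on the first two discriminant axes of the full fit
    lda_step: LinearDiscriminantAnalysis = full.named_steps["lda"]
    Z = full[:-1].transform(X) if len(full.steps) > 1 else X
    proj = lda_step.transform(Z)
    if proj.shape[1] == 1:
        proj = np.column_stack([proj, np.zeros(n)])
    proj = proj[:, :2]
    ids = dataset.sample_ids or [f"s{i}" for i in range(n)]
    projections = pd.DataFrame(
        {"sample_id": ids, "treatment": y, "LD1": proj[:, 0], "LD2": proj[:, 1]}
    )

    ellipses: dict[str, dict[str, float]] = {}
    for t in classes:
        P = proj[y == t]
        center = P.mean(axis=0)
        cov = np.cov(P.T) if P.shape[0] > 1 else np.eye(2)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
        ellipses[t] = {
            "center_x": float(center[0]),
            "center_y": float(center[1]),
            "semi_axis_major": float(np.sqrt(max(evals[-1], 0.0))),
            "semi_axis_minor": float(np.sqrt(max(evals[0], 0.0))),
            "angle_deg": angle,
        }

    return DiscriminantResult(
        treatments=classes,
        projections=projections,
        resub_accuracy=resub,
        loo_accuracy=loo,
        per_class_loo_accuracy=per_class,
        confusion=conf,
        ellipses=ellipses,
        notes=notes,
    )
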