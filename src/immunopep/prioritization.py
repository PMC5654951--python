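"""Evaluation harness for neoantigen prioritization.

Implements per-feature Wilcoxon rank-sum scans, affinity-ranked recovery
curves with the database-presence protein filter, and the half-split
SVM-regression cross-validation: the control and immunogenic candidate lists
are each split into random halves, a radial-basis-kernel SVM regressor is
trained on one half (targets +1 for immunogenic, -1 for control), the other
half is ranked by predicted value, and the number of immunogenic candidates
among the top-k ranked test candidates is the performance of that repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .peptidome_db import PeptidomeDB

logger = logging.getLogger(__name__)

#: non-MS feature groups used for the with/without-MS comparison
GROUP_FEATURES: dict[str, list[str]] = {
    "1": ["mutAffinity", "mutPeptideStability", "rnaExpr"],
    "2": ["mutAffinity", "mutPeptideStability", "rnaExpr", "wtAffinity", "wtPeptideStability"],
    "3": ["mutAffinity", "mutPeptideStability", "rnaExpr", "diffAffinity", "diffPeptideStability"],
}

MS_FEATURES = ["exactMatchScore_I", "matchScore_I", "nrMatchingPeptides_I"]

# LIBSVM-style defaults, pinned for reproducibility:
# cost C=1, epsilon=0.1, RBF kernel width gamma = 1/n_features
SVM_COST = 1.0
SVM_EPSILON = 0.1


@dataclass(frozen=True)
class FeatureGroupSpec:
    """A named base-feature group plus an optional set of MS features."""

    group_id: str = "1"
    ms_features: tuple[str, ...] = ()
    custom_features: tuple[str, ...] = ()

    @property
    def features(self) -> list[str]:
        if self.group_id == "custom":
            base = list(self.custom_features)
        else:
            if self.group_id not in GROUP_FEATURES:
                raise ValueError(
                    f"unknown feature group {self.group_id!r}; expected 1, 2, 3 or custom"
                )
            base = list(GROUP_FEATURES[self.group_id])
        return base + [f for f in self.ms_features if f not in base]


@dataclass(frozen=True)
class CVResult:
    """Cross-validation summary: mean/sd of immunogenic hits in the top-k."""

    mean_top_k: float
    sd_top_k: float
    n_repeats: int
    top_k: int
    seed: int
    features: tuple[str, ...] = ()
    standardized: bool = True


def ensure_derived_features(candidates: pd.DataFrame) -> pd.DataFrame:
    """Add diffAffinity and diffPeptideStability columns if absent."""
    df = candidates.copy()
    if "diffAffinity" not in df.columns and {"mutAffinity", "wtAffinity"} <= set(df.columns):
        df["diffAffinity"] = df["mutAffinity"] - df["wtAffinity"]
    if "diffPeptideStability" not in df.columns and {
        "mutPeptideStability",
        "wtPeptideStability",
    } <= set(df.columns):
        df["diffPeptideStability"] = df["mutPeptideStability"] - df["wtPeptideStability"]
    return df


def wilcoxon_feature_scan(candidates: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Two-sided rank-sum discriminability of each feature, as -log10 p.

    Compares immunogenic versus control candidates; a larger value means the
    feature separates the groups better.  A feature constant across all
    candidates has no separation and scores 0.
    """
    df = ensure_derived_features(candidates)
    labels = df["immunogenic"].astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need at least one immunogenic and one control candidate")
    rows = []
    for feat in features:
        if feat not in df.columns:
            raise KeyError(f"unknown feature {feat!r}")
        pos = df.loc[labels, feat].to_numpy(float)
        neg = df.loc[~labels, feat].to_numpy(float)
        if np.ptp(np.concatenate([pos, neg])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
        rows.append((feat, p, -np.log10(max(p, np.finfo(float).tiny))))
    return pd.DataFrame(rows, columns=["feature", "p_value", "neg_log10_p"])


def rank_by_feature(
    candidates: pd.DataFrame, feature: str, direction: str = "asc"
) -> np.ndarray:
    """Recovery curve: immunogenic count among the first r feature-ranked candidates.

    Ascending order for affinities (low nM = strong binder = good).  Sorting
    is stable, so tied candidates keep their input order; the final value of
    the curve equals the total immunogenic count.
    """
    df = ensure_derived_features(candidates)
    if feature not in df.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    ranked = df.sort_values(feature, ascending=(direction == "asc"), kind="stable")
    return np.cumsum(ranked["immunogenic"].astype(bool).to_numpy())


def protein_presence_filter(
    candidates: pd.DataFrame, db: PeptidomeDB
) -> tuple[pd.DataFrame, int, int]:
    """Drop candidates whose source protein has no mapped class-I database peptide.

    Returns (filtered table, retained count, total count).
    """
    class1 = db.class1_peptides
    present = {
        pid
        for pid, placements in db.placements_by_protein.items()
        if any(pep in class1 for (pep, _, _) in placements)
    }
    mask = candidates["protein_id"].isin(present)
    retained = candidates[mask].reset_index(drop=True)
    return retained, int(mask.sum()), int(len(candidates))


def _half_split(rng: np.random.Generator, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split; with odd counts the extra element goes to training."""
    perm = rng.permutation(indices)
    n_test = len(perm) // 2
    return perm[n_test:], perm[:n_test]  # train, test


def svm_cv_evaluate(
    candidates: pd.DataFrame,
    spec: FeatureGroupSpec,
    n_repeats: int = 2000,
    top_k: int = 20,
    seed: int = 0,
    standardize: bool = True,
) -> CVResult:
    """Half-split SVM-regression cross-validation, repeated ``n_repeats`` times.

    Candidates are first sorted canonically by candidate_id so the result is
    invariant to input order.  Each repeat splits the immunogenic and control
    lists into random halves, trains an RBF-kernel SVM regressor (C=1,
    epsilon=0.1, gamma=1/n_features) on the training half with targets +1
    (immunogenic) / -1 (control), ranks the test half by predicted value
    descending, and counts immunogenic candidates in the top ``top_k``.
    Features are standardized with training-half mean/sd by default (no
    leakage).  Ties in the predicted value are broken by the repeat's random
    draw order, so a completely uninformative feature yields
    random-equivalent ranking; everything is reproducible given the seed.
    """
    features = spec.features
    df = ensure_derived_features(candidates)
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise KeyError(f"candidate table lacks feature column(s) {missing}")
    df = df.sort_values("candidate_id", kind="stable").reset_index(drop=True)

    n_nan = int(df[features].isna().any(axis=1).sum())
    if n_nan:
        logger.warning("dropping %d candidate row(s) with missing feature values", n_nan)
        df = df.dropna(subset=features).reset_index(drop=True)

    X = df[features].to_numpy(dtype=float)
    y = df["immunogenic"].astype(bool).to_numpy()
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("need at least 2 immunogenic and 2 control candidates")

    rng = np.random.default_rng(seed)
    gamma = 1.0 / len(features)
    counts = np.empty(n_repeats, dtype=np.int64)
    for rep in range(n_repeats):
        pos_train, pos_test = _half_split(rng, pos_idx)
        neg_train, neg_test = _half_split(rng, neg_idx)
        train = np.concatenate([pos_train, neg_train])
        # random test order = deterministic, seed-driven tie-break of the ranking
        test = rng.permutation(np.concatenate([pos_test, neg_test]))

        X_train, X_test = X[train], X[test]
        if standardize:
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd
        targets = np.where(y[train], 1.0, -1.0)
        model = SVR(kernel="rbf", C=SVM_COST, epsilon=SVM_EPSILON, gamma=gamma)
        model.fit(X_train, targets)
        pred = model.predict(X_test)
        order = np.argsort(-pred, kind="stable")
        top = test[order[: min(top_k, len(test))]]
        counts[rep] = int(y[top].sum())

    return CVResult(
        mean_top_k=float(counts.mean()),
        sd_top_k=float(counts.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
        top_k=top_k,
        seed=seed,
        features=tuple(features),
        standardized=standardize,
    )


def improvement(base: CVResult, augmented: CVResult) -> float | None:
    """Relative gain in mean top-k recovery, as a percentage of the base.

    None (missing) when the base mean is zero.
    """
    if base.top_k != augmented.top_k:
        raise ValueError("CV results compare different top_k values")
    if base.mean_top_k == 0:
        return None
    return 100.0 * (augmented.mean_top_k - base.mean_top_k) / base.mean_top_k


def evaluate_with_without_ms(
    candidates: pd.DataFrame,
    group_id: str = "1",
    ms_features: tuple[str, ...] = ("exactMatchScore_I", "matchScore_I"),
    n_repeats: int = 2000,
    top_k: int = 20,
    seed: int = 0,
    standardize: bool = True,
) -> dict:
    """Paired comparison of a feature group without and with the MS features.

    The two runs share the same seed, hence the same sequence of random
    splits (a paired comparison).
    """
    base_spec = FeatureGroupSpec(group_id=group_id)
    aug_spec = FeatureGroupSpec(group_id=group_id, ms_features=tuple(ms_features))
    base = svm_cv_evaluate(candidates, base_spec, n_repeats, top_k, seed, standardize)
    aug = svm_cv_evaluate(candidates, aug_spec, n_repeats, top_k, seed, standardize)
    return {
        "without_ms": base,
        "with_ms": aug,
        "improvement_pct": improvement(base, aug),
    }
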