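"""Ensemble SNP feature selection by classification and regression trios.

Two trios of techniques vote on every marker:

* classification (target = phenotypic interval labels):
  (i) L1-penalized linear support-vector classification — any non-zero
  coefficient across the class-wise weight vectors; (ii) per-marker one-way
  ANOVA F-test at p < 0.05; (iii) gradient tree boosting with importance
  above the mean importance;
* regression (target = the trait values): (i) L1-penalized linear
  support-vector regression, (ii) Pearson correlation test at p < 0.05,
  (iii) gradient tree boosting for regression.

A marker enters the 2-of-3 set (C2 / R2) or the 3-of-3 set (C3 / R3)
according to its vote count, and the joint marker sets are plain set
algebra: ICR2 = C2 ∩ R2, CR2 = C2 ∪ R2, CR3 = C3 ∪ R3.  No multiple-testing
correction is applied to the p < 0.05 screens — they are votes, not tests.

Scalability note: the boosting technique defaults to random feature
subsampling at each split (``max_features="sqrt"``), which keeps a
21,000-marker run tractable on one CPU; ``gtb_max_features=None`` restores
exact all-feature splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.feature_selection import f_classif
from sklearn.linear_model import SGDRegressor
from sklearn.svm import LinearSVC

from .genodata import GenotypeMatrix, TraitVector

__all__ = [
    "FSConfig",
    "FSVotes",
    "MarkerSet",
    "fs_votes_classification",
    "fs_votes_regression",
    "threshold_votes",
    "combine_marker_sets",
    "joint_marker_sets",
]

_COEF_TOL = 1e-8


@dataclass
class FSConfig:
    """Tunables of the two trios (all defaults follow the protocol)."""

    p_cutoff: float = 0.05
    l1_C: float = 1.0  # inverse penalty strength of the L1 linear models
    gtb_max_features: str | int | float | None = "sqrt"
    gtb_n_estimators: int = 100


@dataclass
class FSVotes:
    """Per-marker boolean votes from one trio of techniques."""

    task: str  # classification | regression
    markers: list[str]
    votes: pd.DataFrame  # index = markers, one bool column per technique

    def __post_init__(self) -> None:
        if self.votes.shape[1] != 3:
            raise ValueError("a trio has exactly three techniques")

    @property
    def counts(self) -> np.ndarray:
        return self.votes.to_numpy().sum(axis=1)


@dataclass
class MarkerSet:
    """A named marker subset with its provenance vote counts."""

    name: str
    ids: list[str]
    universe: tuple[str, ...]
    votes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, marker: str) -> bool:
        return marker in set(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.ids, "votes": [self.votes.get(m, 0) for m in self.ids]})


def _as_matrix(Z):
    if isinstance(Z, GenotypeMatrix):
        return Z.values, list(Z.markers)
    Z = np.asarray(Z, dtype=float)
    return Z, [f"m{j}" for j in range(Z.shape[1])]


def _as_target(y):
    if isinstance(y, TraitVector):
        return y.normalized if y.normalized is not None else y.values
    return np.asarray(y)


def _pearson_pvalues(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-values of per-marker Pearson correlations (t transform, n-2 d.f.)."""
    n = y.size
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    sd_z = Zc.std(axis=0)
    sd_y = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Zc.T @ yc) / (n * sd_z * sd_y)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(r)] = 1.0  # constant markers never vote
    return p


def fs_votes_classification(Z, labels, seed: int = 0, config: FSConfig | None = None) -> FSVotes:
    """Run the classification trio against interval labels."""
    config = config or FSConfig()
    Zm, marker_ids = _as_matrix(Z)
    lab = np.asarray(labels)
    if np.unique(lab).size < 2:
        raise ValueError("classification feature selection needs at least two classes")
    if np.isnan(Zm).any():
        raise ValueError("genotype matrix contains missing values; impute first")

    svc = LinearSVC(penalty="l1", dual=False, C=config.l1_C, max_iter=5000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter on noisy markers
        svc.fit(Zm, lab)
    l1_vote = (np.abs(svc.coef_) > _COEF_TOL).any(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant markers yield NaN F, handled below
        _, pvals = f_classif(Zm, lab)
    anova_vote = np.nan_to_num(pvals, nan=1.0) < config.p_cutoff

    gtb = GradientBoostingClassifier(
        n_estimators=config.gtb_n_estimators,
        max_features=config.gtb_max_features,
        random_state=seed,
    )
    gtb.fit(Zm, lab)
    imp = gtb.feature_importances_
    gtb_vote = imp > imp.mean()

    votes = pd.DataFrame(
        {"l1_svc": l1_vote, "anova_f": anova_vote, "gtb": gtb_vote}, index=marker_ids
    )
    return FSVotes(task="classification", markers=marker_ids, votes=votes)


def fs_votes_regression(Z, y, seed: int = 0, config: FSConfig | None = None) -> FSVotes:
    """Run the regression trio against the (normalized) trait values."""
    config = config or FSConfig()
    Zm, marker_ids = _as_matrix(Z)
    yv = _as_target(y).astype(float)
    if np.ptp(yv) == 0:
        raise ValueError("regression feature selection needs a non-constant response")
    if np.isnan(Zm).any():
        raise ValueError("genotype matrix contains missing values; impute first")
    n = yv.size

    # L1 linear SVR: epsilon-insensitive loss + L1 penalty (alpha = 1/(C*n))
    svr = SGDRegressor(
        loss="epsilon_insensitive",
        penalty="l1",
        alpha=1.0 / (config.l1_C * n),
        max_iter=2000,
        tol=1e-4,
        random_state=seed,
    )
    svr.fit(Zm, yv)
    l1_vote = np.abs(svr.coef_) > _COEF_TOL

    pearson_vote = _pearson_pvalues(Zm, yv) < config.p_cutoff

    gtb = GradientBoostingRegressor(
        n_estimators=config.gtb_n_estimators,
        max_features=config.gtb_max_features,
        random_state=seed,
    )
    gtb.fit(Zm, yv)
    imp = gtb.feature_importances_
    gtb_vote = imp > imp.mean()

    votes = pd.DataFrame(
        {"l1_svr": l1_vote, "pearson": pearson_vote, "gtb": gtb_vote}, index=marker_ids
    )
    return FSVotes(task="regression", markers=marker_ids, votes=votes)


def threshold_votes(votes: FSVotes, min_votes: int) -> MarkerSet:
    """Keep markers backed by at least ``min_votes`` techniques (2 or 3)."""
    if min_votes not in (2, 3):
        raise ValueError("min_votes must be 2 or 3")
    counts = votes.counts
    keep = counts >= min_votes
    ids = [m for m, k in zip(votes.markers, keep) if k]
    if not ids:
        warnings.warn(
            f"no marker reached {min_votes} votes in the {votes.task} trio", stacklevel=2
        )
    name = ("C" if votes.task == "classification" else "R") + str(min_votes)
    return MarkerSet(
        name=name,
        ids=ids,
        universe=tuple(votes.markers),
        votes={m: int(c) for m, c in zip(votes.markers, counts)},
    )


def combine_marker_sets(c: MarkerSet, r: MarkerSet, rule: str) -> MarkerSet:
    """ICR2 = intersection, CR2 / CR3 = union, of the C and R sets."""
    if set(c.universe) != set(r.universe):
        raise ValueError("marker sets come from different marker universes")
    rule = rule.upper()
    cs, rs = set(c.ids), set(r.ids)
    if rule == "ICR2":
        members = cs & rs
    elif rule in ("CR2", "CR3"):
        members = cs | rs
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    ids = [m for m in c.universe if m in members]  # universe order
    votes = {m: max(c.votes.get(m, 0), r.votes.get(m, 0)) for m in ids}
    return MarkerSet(name=rule, ids=ids, universe=c.universe, votes=votes)


def joint_marker_sets(Z, y, labels, seed: int = 0, config: FSConfig | None = None) -> dict[str, MarkerSet]:
    """All named marker sets from one run of both trios.

    Returns C2, C3, R2, R3, ICR2, CR2 and CR3 keyed by name.  The C3F / R3F
    constructions reuse C3 / R3 as fixed-effect blocks and are assembled by
    the evaluation layer.
    """
    cv = fs_votes_classification(Z, labels, seed=seed, config=config)
    rv = fs_votes_regression(Z, y, seed=seed, config=config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sets = {
            "C2": threshold_votes(cv, 2),
            "C3": threshold_votes(cv, 3),
            "R2": threshold_votes(rv, 2),
            "R3": threshold_votes(rv, 3),
        }
    sets["ICR2"] = combine_marker_sets(sets["C2"], sets["R2"], "ICR2")
    sets["CR2"] = combine_marker_sets(sets["C2"], sets["R2"], "CR2")
    sets["CR3"] = combine_marker_sets(sets["C3"], sets["R3"], "CR3")
    return sets
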