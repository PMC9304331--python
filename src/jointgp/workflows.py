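"""High-level joint-learning workflows used by the simulation study.

Convenience compositions of the pipeline stages: sample a dataset from a
simulated breeding program, define phenotypic intervals, run both
feature-selection trios, and contrast kernel genomic prediction on all
markers against the CR3-selected subset under 10-fold cross-validation
(the reference protocol: FS on the full sample, then CV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breedsim import SimulatedDataset, sample_dataset
from .evaluation import CVPlan, run_cv
from .featsel import FSConfig, MarkerSet, joint_marker_sets
from .gibbs import GPModelSpec
from .intervals import ClusteringScheme, define_intervals

__all__ = ["JointLearningResult", "select_markers_for_sample", "smgk_accuracy_contrast"]


@dataclass
class JointLearningResult:
    """Marker sets and (optionally) SM-GK accuracies for one sampled dataset."""

    n: int
    sets: dict[str, MarkerSet]
    interval_k: int
    r_all: float | None = None
    r_cr3: float | None = None

    @property
    def reduction_pct(self) -> float:
        """Percentage of the marker panel removed by CR3 selection."""
        universe = len(self.sets["CR3"].universe)
        return 100.0 * (1.0 - len(self.sets["CR3"]) / universe)

    @property
    def accuracy_ratio(self) -> float:
        return self.r_cr3 / self.r_all


def select_markers_for_sample(
    ds: SimulatedDataset,
    n: int,
    seed: int = 0,
    cluster_method: str = "wardWSD",
    fs_config: FSConfig | None = None,
):
    """Sample ``n`` PYT lines and run the full joint FS stage.

    Returns ``(genotypes, trait, JointLearningResult)``; accuracies are left
    unset until :func:`smgk_accuracy_contrast` fills them in.
    """
    g, y = sample_dataset(ds, n, seed=seed)
    assignment = define_intervals(y, ClusteringScheme(method=cluster_method, seed=seed))
    sets = joint_marker_sets(g, y, assignment.labels, seed=seed, config=fs_config)
    return g, y, JointLearningResult(n=n, sets=sets, interval_k=assignment.k)


def smgk_accuracy_contrast(
    g,
    y,
    result: JointLearningResult,
    n_iter: int = 4_000,
    burn_in: int = 500,
    seed: int = 0,
    k_folds: int = 10,
    repeats: int = 1,
) -> JointLearningResult:
    """10-fold CV Pearson R of SM-GK on all markers vs the CR3 subset."""
    spec = GPModelSpec(kind="smgk", n_iter=n_iter, burn_in=burn_in, seed=seed)
    plan = CVPlan(scheme="kfold", k=k_folds, repeats=repeats, seed=seed)
    result.r_all = run_cv(spec, g, y, plan, label="smgk/all").mean_r
    cr3 = result.sets["CR3"]
    if len(cr3) == 0:
        raise ValueError("CR3 marker set is empty; cannot contrast accuracies")
    g_cr3 = g.subset_markers(cr3.ids)
    result.r_cr3 = run_cv(spec, g_cr3, y, plan, label="smgk/CR3").mean_r
    return result
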