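"""Model/Results facade over the full discrimination pipeline.

:class:`CnvDiscriminationModel` bundles a labeled signal panel with the
selection and evaluation settings; :meth:`~CnvDiscriminationModel.fit`
runs MI filtering, mRMR ranking, the two-stage incremental feature
selection for each requested classifier, and (for the rule learner) trains
a final annotated decision list on the optimal feature subset. The
returned :class:`CnvDiscriminationResults` carries the curves, selected
points, survivors, ranking and rules, and renders a summary table with one
row per classifier: first-stage highest point, turning point, second-stage
optimum (each as MCC with the subset size), and the number of rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import LabeledDataset, RuleList, SignalKind, SignalMatrix, SNPMarker
from .ifs import TwoStageIFSReport, two_stage_ifs
from .relevance import DiscretizationScheme, RankedFeatures, mi_filter, mrmr_rank
from .ruleminer import RuleLearnerConfig, annotate_rule_list, learn_ruleset

__all__ = ["CnvDiscriminationModel", "CnvDiscriminationResults"]


class CnvDiscriminationModel:
    """CNV-signal class discrimination via mRMR + IFS + SVM/rule learning.

    Parameters
    ----------
    dataset
        Labeled signal panel (LRR or BAF) to analyze.
    mi_threshold
        Features with label MI at or below this (bits) are discarded.
    discretization
        Binning scheme feeding the MI estimates.
    mrmr_variant, top_n
        mRMR criterion form and how deep to rank; ``top_n=None`` ranks
        min(100, survivors) features, which bounds the IFS scan.
    classifiers
        Any of ``"svm"`` (one-vs-rest linear margin) and ``"ripper"``
        (ordered rule list).
    smote_policy
        Where minority oversampling happens relative to CV.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        *,
        mi_threshold: float = 0.01,
        discretization: DiscretizationScheme | None = None,
        mrmr_variant: str = "MID",
        top_n: int | None = None,
        classifiers: Sequence[str] = ("svm", "ripper"),
        smote_policy: str = "train_folds_only",
        stage1_step: int = 10,
        turning_delta: float = 0.05,
        cv_folds: int = 10,
        ripper_config: RuleLearnerConfig | None = None,
    ):
        self.dataset = dataset
        self.mi_threshold = mi_threshold
        self.discretization = discretization or DiscretizationScheme()
        self.mrmr_variant = mrmr_variant
        self.top_n = top_n
        self.classifiers = tuple(classifiers)
        self.smote_policy = smote_policy
        self.stage1_step = stage1_step
        self.turning_delta = turning_delta
        self.cv_folds = cv_folds
        self.ripper_config = ripper_config or RuleLearnerConfig()

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        labels: Sequence[str],
        signal_kind: SignalKind | str,
        class_names: Sequence[str] | None = None,
        markers: Sequence[SNPMarker] | None = None,
        **kwargs,
    ) -> "CnvDiscriminationModel":
        """Build from a samples x markers DataFrame (index = sample ids)."""
        if markers is None:
            markers = [SNPMarker(str(c)) for c in values.columns]
        matrix = SignalMatrix(
            [str(i) for i in values.index], list(markers), values.to_numpy(float),
            signal_kind,
        )
        if class_names is None:
            class_names = tuple(dict.fromkeys(str(x) for x in labels))
        return cls(LabeledDataset(matrix, list(labels), tuple(class_names)), **kwargs)

    def fit(self, seed: int = 0, n_jobs: int = 1) -> "CnvDiscriminationResults":
        """Run the full selection pipeline; deterministic given ``seed``."""
        survivors = mi_filter(self.dataset, self.discretization, self.mi_threshold)
        if survivors.empty:
            raise RuntimeError(
                f"no features exceed the MI threshold {self.mi_threshold}; "
                "nothing to select from"
            )
        top_n = self.top_n if self.top_n is not None else min(100, len(survivors))
        ranked = mrmr_rank(
            self.dataset,
            self.discretization,
            survivors=list(survivors.index),
            variant=self.mrmr_variant,
            top_n=top_n,
        )
        reports: dict[str, TwoStageIFSReport] = {}
        for clf in self.classifiers:
            reports[clf] = two_stage_ifs(
                self.dataset,
                ranked,
                classifier=clf,
                smote_policy=self.smote_policy,
                stage1_step=self.stage1_step,
                delta=self.turning_delta,
                seed=seed,
                cv_k=self.cv_folds,
                n_jobs=n_jobs,
                ripper_config=self.ripper_config,
            )
        rules = None
        if "ripper" in reports:
            from dataclasses import replace

            cfg = replace(self.ripper_config, seed=seed)
            rules = learn_ruleset(
                self.dataset, cfg, feature_subset=reports["ripper"].optimal_features
            )
            rules = annotate_rule_list(rules, self.dataset)
        return CnvDiscriminationResults(
            model=self, seed=seed, survivors=survivors, ranked=ranked,
            reports=reports, rules=rules,
        )


@dataclass
class CnvDiscriminationResults:
    """Fit artifacts: survivors, ranking, IFS reports, final rules."""

    model: CnvDiscriminationModel
    seed: int
    survivors: pd.Series  # MI (bits) of features passing the filter, panel order
    ranked: RankedFeatures
    reports: dict[str, TwoStageIFSReport]
    rules: RuleList | None

    def summary(self) -> pd.DataFrame:
        """One row per classifier, mirroring the pipeline's report layout."""
        rows = []
        for clf, rep in self.reports.items():
            row = rep.summary_row()
            row["n_rules"] = len(self.rules) if (clf == "ripper" and self.rules) else np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("classifier")

    def summary_text(self) -> str:
        """Human-readable summary: ``MCC (k)`` per selection stage."""
        lines = [
            f"{'classifier':<10} {'1st-stage highest':>20} {'turning point':>20} "
            f"{'2nd-stage optimum':>20} {'rules':>6}"
        ]
        for clf, rep in self.reports.items():
            h, t, o = rep.stage1_highest, rep.turning_point, rep.optimum
            n_rules = str(len(self.rules)) if (clf == "ripper" and self.rules) else "-"
            lines.append(
                f"{clf:<10} {h[1]:>12.4f} ({h[0]:>4}) {t[1]:>12.4f} ({t[0]:>4}) "
                f"{o[1]:>12.4f} ({o[0]:>4}) {n_rules:>6}"
            )
        return "\n".join(lines)

    def optimal_features(self, classifier: str = "svm") -> list[str]:
        return list(self.reports[classifier].optimal_features)

    def plot_ifs(self, classifier: str | None = None, ax=None):
        """Plot MCC vs subset size for both IFS stages of one classifier."""
        import matplotlib.pyplot as plt

        clf = classifier or next(iter(self.reports))
        rep = self.reports[clf]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(rep.stage1.ks, rep.stage1.mccs, "o-", label="stage 1 (coarse)")
        ax.plot(rep.stage2.ks, rep.stage2.mccs, ".-", alpha=0.7, label="stage 2 (fine)")
        ax.axvline(rep.turning_point[0], ls="--", color="gray", label="turning point")
        ax.scatter([rep.optimum[0]], [rep.optimum[1]], marker="*", s=150, color="red",
                   zorder=5, label="optimum")
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("cross-validated multiclass MCC")
        ax.set_title(f"incremental feature selection ({clf})")
        ax.legend()
        return ax
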