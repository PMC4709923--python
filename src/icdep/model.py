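"""Model / Results front end for the residual-dependency analysis.

:class:`ResidualDependenceICA` bundles the full procedure applied to one
image sequence: spatial ICA at a chosen model order, pairwise
mutual-information distances between the component maps, and Ward
hierarchical clustering of those distances.  ``fit()`` returns a
:class:`ResidualDependenceResults` carrying the decomposition, the distance
matrices, the linkage tree, per-component diagnostics (and, when ground
truth is available, ROC/AUC scores and the split-merge assessment), plus a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster, evaluate, ica, midist
from .synthdata import GroundTruth, ImageSequence, SimulationConfig, simulate


class ResidualDependenceICA:
    """Residual-dependency model of a (simulated or real) fMRI sequence.

    Parameters
    ----------
    seq:
        The image sequence (2D slice x time plus in-brain mask).
    model_order:
        Number of independent components to extract after PCA reduction.
    distance_methods:
        MI-distance estimators to run, a subset of {"histogram", "kde"}.
    ground_truth:
        Optional simulation ground truth; enables ROC/AUC validation.
    """

    def __init__(
        self,
        seq: ImageSequence,
        model_order: int = 10,
        distance_methods: tuple[str, ...] = ("histogram",),
        ground_truth: GroundTruth | None = None,
        histogram_config: midist.HistogramEstimatorConfig | None = None,
        kde_config: midist.KDEEstimatorConfig | None = None,
    ):
        self.seq = seq
        self.model_order = model_order
        self.distance_methods = tuple(distance_methods)
        self.ground_truth = ground_truth
        self.histogram_config = histogram_config
        self.kde_config = kde_config
        for m in self.distance_methods:
            if m not in ("histogram", "kde"):
                raise ValueError(f"unknown distance method {m!r}")

    @classmethod
    def from_simulation(
        cls,
        config: SimulationConfig,
        model_order: int = 10,
        distance_methods: tuple[str, ...] = ("histogram",),
        **kwargs,
    ) -> "ResidualDependenceICA":
        seq, truth = simulate(config)
        return cls(
            seq,
            model_order=model_order,
            distance_methods=distance_methods,
            ground_truth=truth,
            **kwargs,
        )

    def fit(self, seed: int = 0, **fastica_kwargs) -> "ResidualDependenceResults":
        decomposition = ica.decompose(
            self.seq, self.model_order, seed=seed, **fastica_kwargs
        )
        distances: dict[str, midist.DistanceMatrix] = {}
        trees: dict[str, cluster.LinkageTree] = {}
        for method in self.distance_methods:
            cfg = self.histogram_config if method == "histogram" else self.kde_config
            dm = midist.pairwise_distances(decomposition, method=method, config=cfg)
            distances[method] = dm
            trees[method] = cluster.ward_linkage(dm)
        labels = None
        merge_reports: dict[str, evaluate.MergeReport] = {}
        if self.ground_truth is not None:
            labels = evaluate.assign_components(
                decomposition, self.ground_truth, mask=self.seq.mask
            )
            for method, tree in trees.items():
                merge_reports[method] = evaluate.merge_assessment(tree, labels)
        return ResidualDependenceResults(
            model=self,
            seed=seed,
            decomposition=decomposition,
            distances=distances,
            trees=trees,
            labels=labels,
            merge_reports=merge_reports,
        )


@dataclass
class ResidualDependenceResults:
    """Fitted decomposition, distances, clustering and diagnostics."""

    model: ResidualDependenceICA
    seed: int
    decomposition: ica.ICADecomposition
    distances: dict[str, midist.DistanceMatrix]
    trees: dict[str, cluster.LinkageTree]
    labels: list[evaluate.ComponentLabel] | None = None
    merge_reports: dict[str, evaluate.MergeReport] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.decomposition.n_components

    def component_table(self) -> pd.DataFrame:
        if self.labels is not None:
            return evaluate.component_table(self.labels)
        rows = [{"IC": i} for i in range(self.n_components)]
        return pd.DataFrame(rows)

    def best_auc(self, roi: int) -> float:
        """Best AUC over components against ROI ``roi`` (1-based)."""
        if self.labels is None:
            raise ValueError("no ground truth attached to the model")
        return max(lab.roi_aucs[roi] for lab in self.labels)

    def zmap(self, index: int, threshold: float = 2.0) -> ica.ZMap:
        return ica.component_zmap(
            self.decomposition.maps[index], component_index=index, threshold=threshold
        )

    def plot_dendrogram(self, method: str | None = None, path=None, ax=None):
        method = method or self.model.distance_methods[0]
        return cluster.render_dendrogram(self.trees[method], path=path, ax=ax)

    def summary(self) -> str:
        model = self.model
        lines = [
            "Residual-dependency ICA results",
            "=" * 45,
            f"scans: {self.decomposition.mixing_timecourses.shape[0]}"
            f"    in-mask voxels: {self.decomposition.maps.shape[1]}",
            f"model order: {self.n_components}    seed: {self.seed}",
            f"FastICA attempts: {self.decomposition.convergence_info['attempts']}"
            f" (iterations: {self.decomposition.convergence_info['iterations']})",
            f"distance estimators: {', '.join(model.distance_methods)}",
            "",
        ]
        table = self.component_table()
        lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        for method, tree in self.trees.items():
            heights = [m[2] for m in tree.merges]
            lines.append("")
            lines.append(
                f"[{method}] merge heights: first={heights[0]:.4f}"
                f" last={heights[-1]:.4f} (nats^2/2 scale)"
            )
            report = self.merge_reports.get(method)
            if report is not None:
                if report.no_split:
                    lines.append(f"[{method}] no split ROI (one component per ROI)")
                else:
                    lines.append(
                        f"[{method}] split ROIs {report.split_rois}: same-ROI components "
                        + ("merge before" if report.merged_first else "do NOT merge before")
                        + " cross-ROI task components"
                    )
        return "\n".join(lines)
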