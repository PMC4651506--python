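"""Core containers: study design and the genes-by-samples expression matrix.

The pipeline's central object is an :class:`ExpressionMatrix`, a log2-scale
genes × samples table together with a mapping of each sample to its
gestational stage (e.g. ``D12`` … ``D114``, three biological replicates per
stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StudyDesign", "ExpressionMatrix", "DEFAULT_DESIGN"]


@dataclass(frozen=True)
class StudyDesign:
    """An ordered set of stages with a fixed replicate count and a baseline.

    Parameters
    ----------
    stage_labels : ordered stage identifiers (≥ 2).
    replicates_per_stage : biological replicates per stage (≥ 2).
    baseline_stage : the calibrator stage all later stages are compared to.
    """

    stage_labels: tuple[str, ...] = ("D12", "D15", "D30", "D60", "D90", "D114")
    replicates_per_stage: int = 3
    baseline_stage: str = "D12"

    def __post_init__(self) -> None:
        if len(self.stage_labels) < 2:
            raise ValueError("a study design needs at least 2 stages")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ValueError("stage labels must be unique")
        if self.replicates_per_stage < 2:
            raise ValueError("replicates_per_stage must be >= 2")
        if self.baseline_stage not in self.stage_labels:
            raise ValueError(
                f"baseline stage {self.baseline_stage!r} not among stages"
            )

    @property
    def n_samples(self) -> int:
        return len(self.stage_labels) * self.replicates_per_stage

    def sample_ids(self) -> list[str]:
        return [
            f"{stage}_r{i + 1}"
            for stage in self.stage_labels
            for i in range(self.replicates_per_stage)
        ]

    def stage_of_sample(self) -> dict[str, str]:
        return {s: s.rsplit("_r", 1)[0] for s in self.sample_ids()}


DEFAULT_DESIGN = StudyDesign()


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression values with stage-labelled samples.

    ``values`` rows are genes (unique ids), columns are samples; every
    sample id must appear in ``stage_of_sample`` and no entry may be
    missing.
    """

    values: pd.DataFrame
    stage_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [c for c in self.values.columns if c not in self.stage_of_sample]
        if missing:
            raise ValueError(f"samples without a stage assignment: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stages in order of first appearance across the sample columns."""
        seen: list[str] = []
        for s in self.values.columns:
            stage = self.stage_of_sample[s]
            if stage not in seen:
                seen.append(stage)
        return seen

    def samples_of_stage(self, stage: str) -> list[str]:
        cols = [c for c in self.values.columns if self.stage_of_sample[c] == stage]
        if not cols:
            raise KeyError(f"unknown stage {stage!r}")
        return cols

    def stage_means(self) -> pd.DataFrame:
        """Average replicates within each stage → genes × stages matrix."""
        out = {st: self.values[self.samples_of_stage(st)].mean(axis=1) for st in self.stages}
        return pd.DataFrame(out)

    def subset(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise KeyError(f"unknown genes: {unknown[:5]}")
        return ExpressionMatrix(self.values.loc[genes], dict(self.stage_of_sample))

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)
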