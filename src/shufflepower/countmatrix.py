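"""Count-matrix container shared by every pipeline stage.

A :class:`CountMatrix` bundles an integer annotation × sample count table
with two pieces of metadata: a two-level diet factor over samples
(reference level ``CD``, treatment level ``HFD``) and an annotation-class
label per row (``protein_coding``, ``miRNA``, ``piRNA``, ``repeat`` or any
user-defined class).  All statistical stages consume and return this type.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_LEVEL = "CD"
TREATMENT_LEVEL = "HFD"


@dataclass
class CountMatrix:
    """Integer counts for annotations × samples with design metadata.

    Parameters
    ----------
    counts
        DataFrame with annotation ids as index, sample ids as columns and
        non-negative integer entries.
    groups
        Series indexed by sample id mapping each sample to its diet group.
        Exactly two levels with at least two samples each.
    classes
        Series indexed by annotation id mapping each annotation to its
        class label.
    """

    counts: pd.DataFrame
    groups: pd.Series
    classes: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.groups = pd.Series(self.groups).reindex(self.counts.columns)
        self.classes = pd.Series(self.classes).reindex(self.counts.index)
        self._validate()

    def _validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("annotation ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if self.classes.isna().any():
            raise ValueError("every annotation needs a class label")
        level_counts = self.groups.value_counts()
        if len(level_counts) != 2:
            raise ValueError(
                f"groups must have exactly 2 levels, got {list(level_counts.index)}"
            )
        if (level_counts < 2).any():
            raise ValueError("each group level needs >= 2 samples")

    # ------------------------------------------------------------------
    @property
    def annotation_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_annotations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def levels(self) -> tuple[str, str]:
        """(reference, treatment) levels; CD/HFD if present, else sorted."""
        present = set(self.groups.unique())
        if present == {REFERENCE_LEVEL, TREATMENT_LEVEL}:
            return REFERENCE_LEVEL, TREATMENT_LEVEL
        ref, treat = sorted(present)
        return ref, treat

    def group_mask(self, level: str) -> np.ndarray:
        return (self.groups == level).to_numpy()

    def design_indicator(self) -> np.ndarray:
        """0/1 treatment indicator per sample (1 = treatment level)."""
        _, treat = self.levels
        return self.group_mask(treat).astype(float)

    # ------------------------------------------------------------------
    def subset_class(self, cls: str) -> "CountMatrix":
        keep = self.classes == cls
        if not keep.any():
            raise KeyError(f"no annotations of class {cls!r}")
        return CountMatrix(
            self.counts.loc[keep.to_numpy()], self.groups, self.classes[keep], dict(self.meta)
        )

    def subset_annotations(self, ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[ids], self.groups, self.classes.loc[ids], dict(self.meta)
        )

    def class_names(self) -> list[str]:
        return list(pd.unique(self.classes))

    # ------------------------------------------------------------------
    def to_tsv(self, outdir: str, prefix: str = "counts") -> None:
        """Write counts plus sample-map and annotation-map sidecars."""
        os.makedirs(outdir, exist_ok=True)
        tab = self.counts.copy()
        tab.index.name = "annotation_id"
        tab.to_csv(os.path.join(outdir, f"{prefix}.tsv"), sep="\t")
        smp = pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups.values})
        smp.to_csv(os.path.join(outdir, f"{prefix}.samples.tsv"), sep="\t", index=False)
        ann = pd.DataFrame(
            {"annotation_id": self.annotation_ids, "class": self.classes.values}
        )
        ann.to_csv(os.path.join(outdir, f"{prefix}.annotations.tsv"), sep="\t", index=False)


def read_count_matrix(
    counts_path: str, samples_path: str, annotations_path: str | None = None
) -> CountMatrix:
    """Load a CountMatrix from the TSV dialect written by :meth:`CountMatrix.to_tsv`.

    ``annotations_path`` may be omitted, in which case every annotation is
    assigned class ``"unknown"``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = counts.astype(np.int64)
    smp = pd.read_csv(samples_path, sep="\t")
    groups = pd.Series(smp["group"].values, index=smp["sample_id"].values)
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t")
        classes = pd.Series(ann["class"].values, index=ann["annotation_id"].values)
    else:
        classes = pd.Series("unknown", index=counts.index)
    return CountMatrix(counts, groups, classes)
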