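"""Two-group expression study container.

An :class:`ExpressionStudy` holds one feature-by-sample expression matrix for a
resistant-vs-control comparison, together with its group assignment, platform
label and a flag saying whether values are already on the log2 scale.  Missing
entries are represented as NaN in the matrix; ``missing_mask`` is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUP_RESISTANT = "resistant"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_RESISTANT, GROUP_CONTROL)


@dataclass
class ExpressionStudy:
    """One two-group expression matrix (features x samples).

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.  NaN marks
        a missing measurement.
    groups
        Series mapping sample id -> ``"resistant"`` or ``"control"``, covering
        every column of ``values``.
    platform
        Free-text platform label (e.g. an array identifier).
    log_scale
        True when values are log2-transformed intensities.
    study_id
        Identifier used in logs and meta-analysis bookkeeping.
    """

    values: pd.DataFrame
    groups: pd.Series
    platform: str = ""
    log_scale: bool = True
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group assignment: {missing}")
        bad = set(self.groups.unique()) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        for g in VALID_GROUPS:
            if counts.get(g, 0) < 2:
                raise ValueError(
                    f"group '{g}' has {counts.get(g, 0)} samples; need >= 2"
                )
        fully_missing = self.values.isna().all(axis=1)
        if fully_missing.any():
            raise ValueError(
                "features entirely missing: "
                f"{list(self.values.index[fully_missing])[:5]}"
            )

    # -- derived views ----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def samples_in_group(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group '{group}'")
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_matrix(self, group: str) -> np.ndarray:
        return self.values[self.samples_in_group(group)].to_numpy(dtype=float)

    def copy(self) -> "ExpressionStudy":
        return replace(self, values=self.values.copy(), groups=self.groups.copy())

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, matrix_path, groups_path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(matrix_path, sep="\t")
        g = self.groups.rename("group")
        g.index.name = "sample_id"
        g.to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        matrix_path,
        groups_path,
        platform: str = "",
        log_scale: bool = True,
        study_id: str = "",
    ) -> "ExpressionStudy":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str).rename(None)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        groups.index = groups.index.astype(str)
        return cls(
            values=values,
            groups=groups,
            platform=platform,
            log_scale=log_scale,
            study_id=study_id,
        )
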