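"""Model/Results interface for the thickness-association analysis.

:class:`SleepThicknessModel` holds the aligned per-subject data (sleep-EEG
indexes, regional thickness, optional age/sex covariates); ``fit()`` runs
every per-(region, hemisphere) FDR family and returns an
:class:`AssociationResults` with the full record table, the significant
subset formatted as a publication-style table, partial-correlation controls,
and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .association import (
    CorrelationRecord,
    format_significant_table,
    partial_pearson,
    records_to_frame,
    run_family,
)
from .errors import ReconciliationError, SpecError
from .spectral import CLUSTER_NAMES, INDEX_NAMES
from .thickness import ALL_REGIONS, HEMISPHERES, ThicknessTable, read_covariates, read_thickness


def read_indexes_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-subject sleep-index CSV (long form) into the wide layout.

    Long form columns: subject, index, cluster, value.  Returns a frame with
    one row per subject and a (index, cluster) column MultiIndex.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    required = {"subject", "index", "cluster", "value"}
    if not required <= set(df.columns):
        raise SpecError(f"{path}: expected columns {sorted(required)}")
    wide = df.pivot(index="subject", columns=["index", "cluster"], values="value")
    cols = pd.MultiIndex.from_product([INDEX_NAMES, CLUSTER_NAMES])
    return wide[cols].sort_index()


def write_indexes_csv(indexes: pd.DataFrame, path: str | Path) -> None:
    long = indexes.stack([0, 1], future_stack=True).rename("value").reset_index()
    long.columns = ["subject", "index", "cluster", "value"]
    long.to_csv(path, index=False)


class SleepThicknessModel:
    """Pearson/FDR association model between sleep-EEG indexes and thickness.

    Parameters
    ----------
    indexes
        One row per subject, (index_name, cluster) MultiIndex columns with
        the 18 sleep-EEG index values (percent).
    thickness
        A :class:`~sleepcortex.thickness.ThicknessTable` over the same
        subjects.
    covariates
        Optional DataFrame indexed by subject with ``age`` and ``sex_code``
        columns; enables the partial-correlation control analysis.
    alpha
        FDR significance level for the per-family BH adjustment.
    """

    def __init__(
        self,
        indexes: pd.DataFrame,
        thickness: ThicknessTable,
        covariates: Optional[pd.DataFrame] = None,
        alpha: float = 0.05,
    ) -> None:
        subjects = sorted(map(str, indexes.index))
        t_subjects = sorted(thickness.subjects)
        if subjects != t_subjects:
            raise ReconciliationError(
                f"index/thickness subject mismatch; only in indexes: "
                f"{sorted(set(subjects) - set(t_subjects))}, only in thickness: "
                f"{sorted(set(t_subjects) - set(subjects))}"
            )
        if covariates is not None:
            c_subjects = sorted(map(str, covariates.index))
            if c_subjects != subjects:
                raise ReconciliationError(
                    f"covariate subject mismatch; missing "
                    f"{sorted(set(subjects) - set(c_subjects))}, unexpected "
                    f"{sorted(set(c_subjects) - set(subjects))}"
                )
            covariates = covariates.loc[subjects]
        missing_cols = [
            (i, c)
            for i in INDEX_NAMES
            for c in CLUSTER_NAMES
            if (i, c) not in indexes.columns
        ]
        if missing_cols:
            raise SpecError(f"indexes missing cells {missing_cols[:4]}")
        self.indexes = indexes.loc[subjects]
        self.thickness = thickness
        self.covariates = covariates
        self.alpha = alpha
        self.subjects = subjects

    @classmethod
    def from_csv(
        cls,
        indexes_path: str | Path,
        thickness_path: str | Path,
        covariates_path: Optional[str | Path] = None,
        alpha: float = 0.05,
    ) -> "SleepThicknessModel":
        indexes = read_indexes_csv(indexes_path)
        thickness = read_thickness(thickness_path)
        covariates = (
            read_covariates(covariates_path, subjects=indexes.index)
            if covariates_path
            else None
        )
        return cls(indexes, thickness, covariates, alpha=alpha)

    def fit(self) -> "AssociationResults":
        """Run all (region, hemisphere) families and the partial controls."""
        records: list[CorrelationRecord] = []
        thick = self.thickness.data.loc[self.subjects]
        for hemi in HEMISPHERES:
            for region in ALL_REGIONS:
                vec = thick[(hemi, region)]
                records.extend(
                    run_family(region, hemi, vec, self.indexes, alpha=self.alpha)
                )
        if self.covariates is not None:
            cov = self.covariates[["age", "sex_code"]].to_numpy(dtype=float)
            for rec in records:
                if not rec.significant:
                    continue
                x = self.indexes[(rec.index_name, rec.cluster)].to_numpy(dtype=float)
                y = thick[(rec.hemisphere, rec.region)].to_numpy(dtype=float)
                rec.partial_r, rec.partial_p = partial_pearson(x, y, cov)
        return AssociationResults(self, records)


@dataclass
class AssociationResults:
    """Fitted association families and their summaries."""

    model: SleepThicknessModel
    records: list[CorrelationRecord]

    @property
    def frame(self) -> pd.DataFrame:
        """All records (one row per region x hemisphere x index x cluster)."""
        return records_to_frame(self.records)

    @property
    def significant(self) -> pd.DataFrame:
        df = self.frame
        return df[df["significant"]].reset_index(drop=True)

    def significant_table(self) -> pd.DataFrame:
        """Significant correlations in the publication-style layout."""
        return format_significant_table(self.records)

    def summary(self) -> str:
        df = self.frame
        sig = df[df["significant"]]
        lines = [
            "Sleep-EEG index vs cortical thickness associations",
            f"  subjects: {len(self.model.subjects)}",
            f"  families: {df[['region', 'hemisphere']].drop_duplicates().shape[0]}"
            f" (18 tests each), alpha = {self.model.alpha} (BH-FDR per family)",
            f"  significant records: {len(sig)}",
        ]
        if len(sig):
            lines.append("")
            lines.append(self.significant_table().to_string(index=False))
        if self.model.covariates is not None and len(sig):
            confirmed = sig[
                (np.sign(sig["partial_r"]) == np.sign(sig["r"]))
                & (sig["partial_p"] <= self.model.alpha)
            ]
            lines.append("")
            lines.append(
                f"  partial-correlation control (age, sex): "
                f"{len(confirmed)}/{len(sig)} significant records confirmed "
                f"(same sign, partial p <= {self.model.alpha})"
            )
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the full, significant-only, and partial-control CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "correlations": out / "correlations_full.csv",
            "significant": out / "correlations_significant.csv",
        }
        self.frame.to_csv(paths["correlations"], index=False)
        self.significant_table().to_csv(paths["significant"], index=False)
        if self.model.covariates is not None:
            paths["partial"] = out / "correlations_partial_control.csv"
            sig = self.significant
            sig.to_csv(paths["partial"], index=False)
        return paths
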