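"""Desikan-atlas cortical thickness tables and subject covariates.

Thickness values (mm) are consumed per subject for the 34 gyral regions of
the Desikan-Killiany parcellation in each hemisphere, plus the hemispheric
mean thickness.  Readers accept tidy long-form TSV/CSV and normalize common
FreeSurfer spellings (``bankssts``, ``ctx-lh-precuneus``, ...) to a canonical
vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, ReconciliationError

#: Canonical names of the 34 Desikan regions.
DESIKAN_REGIONS = (
    "bank of the superior temporal sulcus",
    "caudal anterior cingulate",
    "caudal middle frontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferior parietal",
    "inferior temporal",
    "isthmus cingulate",
    "lateral occipital",
    "lateral orbitofrontal",
    "lingual",
    "medial orbitofrontal",
    "middle temporal",
    "parahippocampal",
    "paracentral",
    "pars opercularis",
    "pars orbitalis",
    "pars triangularis",
    "pericalcarine",
    "postcentral",
    "posterior cingulate",
    "precentral",
    "precuneus",
    "rostral anterior cingulate",
    "rostral middle frontal",
    "superior frontal",
    "superior parietal",
    "superior temporal",
    "supramarginal",
    "frontal pole",
    "temporal pole",
    "transverse temporal",
    "insula",
)
#: Hemispheric mean thickness is carried as a pseudo-region.
MEAN_REGION = "mean"
ALL_REGIONS = DESIKAN_REGIONS + (MEAN_REGION,)
HEMISPHERES = ("L", "R")

#: FreeSurfer aparc spellings -> canonical names.
FREESURFER_ALIASES = {
    "bankssts": "bank of the superior temporal sulcus",
    "caudalanteriorcingulate": "caudal anterior cingulate",
    "caudalmiddlefrontal": "caudal middle frontal",
    "inferiorparietal": "inferior parietal",
    "inferiortemporal": "inferior temporal",
    "isthmuscingulate": "isthmus cingulate",
    "lateraloccipital": "lateral occipital",
    "lateralorbitofrontal": "lateral orbitofrontal",
    "medialorbitofrontal": "medial orbitofrontal",
    "middletemporal": "middle temporal",
    "parsopercularis": "pars opercularis",
    "parsorbitalis": "pars orbitalis",
    "parstriangularis": "pars triangularis",
    "posteriorcingulate": "posterior cingulate",
    "rostralanteriorcingulate": "rostral anterior cingulate",
    "rostralmiddlefrontal": "rostral middle frontal",
    "superiorfrontal": "superior frontal",
    "superiorparietal": "superior parietal",
    "superiortemporal": "superior temporal",
    "transversetemporal": "transverse temporal",
    "frontalpole": "frontal pole",
    "temporalpole": "temporal pole",
    "meanthickness": "mean",
}

_CANON = {r.lower(): r for r in ALL_REGIONS}
_CANON.update(FREESURFER_ALIASES)
_HEMI_TAGS = {"lh": "L", "rh": "R", "l": "L", "r": "R", "left": "L", "right": "R"}


def normalize_region(name: str) -> str:
    """Map a region spelling to the canonical vocabulary (idempotent).

    Accepts canonical names (case-insensitive), FreeSurfer aparc names, and
    a leading hemisphere tag (``lh_precuneus``, ``ctx-rh-bankssts``) whose
    tag is ignored here (the hemisphere column carries it).
    """
    s = name.strip().lower()
    if s.startswith("ctx-"):
        s = s[4:]
    for sep in ("-", "_", "."):
        head, _, tail = s.partition(sep)
        if head in _HEMI_TAGS and tail:
            s = tail
            break
    s = s.replace("_", " ").replace("-", " ").strip()
    if s in _CANON:
        return _CANON[s]
    if s.replace(" ", "") in _CANON:
        return _CANON[s.replace(" ", "")]
    raise FormatError(
        f"unknown region name {name!r}; accepted names are the 34 Desikan "
        f"regions plus 'mean' (FreeSurfer spellings allowed)"
    )


def normalize_hemisphere(h: str) -> str:
    s = str(h).strip().lower()
    if s in _HEMI_TAGS:
        return _HEMI_TAGS[s]
    raise FormatError(f"unknown hemisphere {h!r} (use L/R, lh/rh, left/right)")


@dataclass
class ThicknessTable:
    """Wide per-subject thickness table.

    ``data`` has one row per subject and a (hemisphere, region) column
    MultiIndex covering 2 x 35 entries (34 regions + ``mean``).
    ``approximated_means`` lists (subject, hemisphere) pairs whose mean
    thickness was not supplied and was filled with the unweighted average of
    the hemisphere's 34 regions.
    """

    data: pd.DataFrame
    approximated_means: frozenset = frozenset()

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    def region_vector(self, region: str, hemisphere: str) -> pd.Series:
        return self.data[(normalize_hemisphere(hemisphere), normalize_region(region))]

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack([0, 1], future_stack=True).rename("thickness_mm").reset_index()
        long.columns = ["subject", "hemisphere", "region", "thickness_mm"]
        return long

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


def _from_long(df: pd.DataFrame, source: str = "<table>") -> ThicknessTable:
    required = {"subject", "hemisphere", "region", "thickness_mm"}
    if not required <= set(df.columns):
        raise FormatError(f"{source}: expected columns {sorted(required)}")
    df = df.copy()
    df["hemisphere"] = df["hemisphere"].map(normalize_hemisphere)
    df["region"] = df["region"].map(normalize_region)
    df["thickness_mm"] = pd.to_numeric(df["thickness_mm"])
    dup = df.duplicated(subset=["subject", "hemisphere", "region"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{source}: duplicate entry for ({row['subject']}, "
            f"{row['hemisphere']}, {row['region']})"
        )
    if (df["thickness_mm"] <= 0).any():
        row = df[df["thickness_mm"] <= 0].iloc[0]
        raise FormatError(
            f"{source}: non-positive thickness {row['thickness_mm']} for "
            f"({row['subject']}, {row['hemisphere']}, {row['region']})"
        )
    out_of_range = df[(df["thickness_mm"] < 0.5) | (df["thickness_mm"] > 5.5)]
    if len(out_of_range):
        warnings.warn(
            f"{source}: {len(out_of_range)} thickness value(s) outside the "
            "plausible 0.5-5.5 mm range",
            stacklevel=3,
        )
    wide = df.pivot(index="subject", columns=["hemisphere", "region"], values="thickness_mm")

    approx = set()
    for hemi in HEMISPHERES:
        missing_regions = [
            r for r in DESIKAN_REGIONS if (hemi, r) not in wide.columns
        ]
        if missing_regions:
            raise FormatError(
                f"{source}: hemisphere {hemi} missing regions {missing_regions[:3]}..."
                if len(missing_regions) > 3
                else f"{source}: hemisphere {hemi} missing regions {missing_regions}"
            )
        region_block = wide[[(hemi, r) for r in DESIKAN_REGIONS]]
        if region_block.isna().any().any():
            subj = region_block[region_block.isna().any(axis=1)].index[0]
            raise FormatError(f"{source}: incomplete regions for subject {subj!r} ({hemi})")
        if (hemi, MEAN_REGION) not in wide.columns:
            wide[(hemi, MEAN_REGION)] = region_block.mean(axis=1)
            approx.update((s, hemi) for s in wide.index)
        else:
            na = wide[(hemi, MEAN_REGION)].isna()
            if na.any():
                wide.loc[na, (hemi, MEAN_REGION)] = region_block.loc[na].mean(axis=1)
                approx.update((s, hemi) for s in wide.index[na])
    cols = pd.MultiIndex.from_product([HEMISPHERES, list(ALL_REGIONS)])
    wide = wide[cols]
    wide.index = wide.index.astype(str)
    return ThicknessTable(data=wide.sort_index(), approximated_means=frozenset(approx))


def read_thickness(path: str | Path) -> ThicknessTable:
    """Read a tidy thickness file (TSV or CSV by extension).

    Columns: subject, hemisphere, region, thickness_mm.  Missing hemispheric
    mean rows are filled with the unweighted average of the 34 regions and
    flagged in ``approximated_means``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject": str})
    return _from_long(df, source=str(path))


def thickness_from_long(df: pd.DataFrame) -> ThicknessTable:
    """Build a :class:`ThicknessTable` from an in-memory long-form frame."""
    return _from_long(df)


def read_covariates(
    path: str | Path, subjects: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Read subject covariates (TSV columns: subject, age, sex).

    Returns a DataFrame indexed by subject with ``age`` (years), ``sex``
    (F/M) and ``sex_code`` (F=1, M=0, the binary coding used by the partial
    correlations).  When ``subjects`` is given, the two sets must match
    exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    required = {"subject", "age", "sex"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if df["subject"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject rows")
    df = df.set_index("subject")
    df["age"] = pd.to_numeric(df["age"])
    if (df["age"] <= 0).any():
        bad = df[df["age"] <= 0].index[0]
        raise FormatError(f"{path}: non-positive age for subject {bad!r}")
    df["sex"] = df["sex"].astype(str).str.upper().str.strip()
    unknown = ~df["sex"].isin(["F", "M"])
    if unknown.any():
        bad = df[unknown].index[0]
        raise FormatError(f"{path}: sex must be F or M (subject {bad!r})")
    df["sex_code"] = (df["sex"] == "F").astype(float)
    if subjects is not None:
        want = set(map(str, subjects))
        have = set(df.index)
        if want != have:
            raise ReconciliationError(
                f"{path}: subject mismatch; missing {sorted(want - have)}, "
                f"unexpected {sorted(have - want)}"
            )
    return df.sort_index()
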