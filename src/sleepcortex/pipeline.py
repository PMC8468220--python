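"""End-to-end study orchestration.

``run_study`` takes a :class:`RunConfig` naming per-subject PSG inputs
(EDF + hypnogram TSV + optional artifact-mask TSV) and the cohort tables
(thickness, covariates), runs macrostructure + spectral indexes per subject,
fits the association model, and writes the result bundle: per-subject
macrostructure CSV, cohort summary, index CSV, full/significant correlation
CSVs, partial-control CSV and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edf import read_edf
from .errors import InsufficientDataError, SleepCortexError, SpecError
from .hypnogram import (
    MACRO_COLUMNS,
    Hypnogram,
    macrostructure,
    macrostructure_frame,
    read_hypnogram,
)
from .model import SleepThicknessModel, write_indexes_csv
from .spectral import (
    CLUSTER_NAMES,
    MASTOIDS,
    SleepEegIndexSet,
    bandpass,
    read_artifact_mask,
    reference_to_linked_mastoids,
    sleep_indexes,
    state_band_cluster,
)
from .thickness import read_covariates, read_thickness

#: Analysis constants of the reference configuration.  A RunConfig deviating
#: from these is allowed but logged prominently in the manifest.
REFERENCE_DEFAULTS = {
    "filter_lo_hz": 0.33,
    "filter_hi_hz": 30.0,
    "alpha": 0.05,
    "taper": "rect",
}


@dataclass
class SubjectInputs:
    subject: str
    edf: str
    hypnogram: str
    mask: Optional[str] = None


@dataclass
class RunConfig:
    """Configuration of a full study run."""

    subjects: list[SubjectInputs]
    thickness: str
    covariates: Optional[str] = None
    out_dir: str = "results"
    alpha: float = 0.05
    taper: str = "rect"
    filter_lo_hz: float = 0.33
    filter_hi_hz: float = 30.0
    filter_method: str = "fft"
    rereference: bool = True
    seed: int = 0

    def deviations(self) -> list[str]:
        out = []
        for key, ref in REFERENCE_DEFAULTS.items():
            val = getattr(self, key)
            if val != ref:
                out.append(f"{key}={val!r} deviates from reference default {ref!r}")
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["subjects"] = [
            SubjectInputs(**s) if isinstance(s, dict) else s for s in d["subjects"]
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def subject_indexes(
    rec,
    hyp: Hypnogram,
    mask=None,
    taper: str = "rect",
    rereference: bool = True,
    filter_lo: float = 0.33,
    filter_hi: float = 30.0,
    filter_method: str = "fft",
    log: Optional[list[str]] = None,
) -> SleepEegIndexSet:
    """Spectral index set of one subject; missing states give NaN indexes.

    A subject without eligible REM (or NREM) windows keeps NaN for that
    state's indexes and is excluded pairwise from the affected correlation
    cells downstream.
    """
    if rereference and all(m in rec.labels for m in MASTOIDS):
        rec = reference_to_linked_mastoids(rec)
    rec = rec.scalp_order()
    rec = bandpass(rec, lo=filter_lo, hi=filter_hi, method=filter_method)
    tables = {}
    for state in ("NREM", "REM"):
        try:
            tables[state] = state_band_cluster(rec, hyp, state, mask, taper)
        except InsufficientDataError:
            tables[state] = None
            if log is not None:
                log.append(f"no eligible {state} windows; {state} indexes set to NaN")
    nan = pd.Series(np.nan, index=list(CLUSTER_NAMES))
    if tables["NREM"] is not None and tables["REM"] is not None:
        return sleep_indexes(tables["NREM"], tables["REM"])
    return SleepEegIndexSet(
        nrem_sigma=tables["NREM"].cluster_band["sigma"] if tables["NREM"] else nan.copy(),
        rem_delta=tables["REM"].cluster_band["delta"] if tables["REM"] else nan.copy(),
        rem_beta=tables["REM"].cluster_band["beta"] if tables["REM"] else nan.copy(),
    )


def summarize_cohort(macro: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation of each macrostructure variable."""
    if len(macro) < 2:
        raise SpecError("cohort summary needs at least 2 subjects")
    cols = [c for c in MACRO_COLUMNS if c in macro.columns]
    return pd.DataFrame(
        {"Mean": macro[cols].mean(), "s.d.": macro[cols].std(ddof=1)}
    ).loc[cols]


def run_study(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``.

    Returns a manifest dict (also written as JSON) naming every output file.
    Raises with the failing subject/stage identified; outputs produced so
    far are preserved next to a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs: list[str] = list(config.deviations())
    paths: dict[str, str] = {}
    try:
        macro_reports = {}
        index_rows = {}
        for sub in config.subjects:
            stage = f"subject {sub.subject}"
            try:
                hyp = read_hypnogram(sub.hypnogram)
                macro_reports[sub.subject] = macrostructure(hyp)
                rec = read_edf(sub.edf)
                mask = read_artifact_mask(sub.mask) if sub.mask else None
                sublog: list[str] = []
                idx = subject_indexes(
                    rec,
                    hyp,
                    mask,
                    taper=config.taper,
                    rereference=config.rereference,
                    filter_lo=config.filter_lo_hz,
                    filter_hi=config.filter_hi_hz,
                    filter_method=config.filter_method,
                    log=sublog,
                )
                logs.extend(f"{sub.subject}: {m}" for m in sublog)
                index_rows[sub.subject] = idx.to_frame().iloc[0]
            except SleepCortexError as exc:
                raise SleepCortexError(f"{stage}: {exc}") from exc

        macro_df = macrostructure_frame(macro_reports)
        paths["macrostructure"] = str(out / "macrostructure.csv")
        macro_df.to_csv(paths["macrostructure"])
        if len(macro_df) >= 2:
            paths["macrostructure_summary"] = str(out / "macrostructure_summary.csv")
            summarize_cohort(macro_df).to_csv(paths["macrostructure_summary"])

        indexes = pd.DataFrame(index_rows).T
        indexes.index.name = "subject"
        indexes.columns = pd.MultiIndex.from_tuples(indexes.columns)
        paths["indexes"] = str(out / "sleep_indexes.csv")
        write_indexes_csv(indexes, paths["indexes"])

        thickness = read_thickness(config.thickness)
        for s, h in sorted(thickness.approximated_means):
            logs.append(f"{s}: hemispheric mean thickness ({h}) approximated as region average")
        covariates = (
            read_covariates(config.covariates, subjects=indexes.index)
            if config.covariates
            else None
        )
        model = SleepThicknessModel(indexes, thickness, covariates, alpha=config.alpha)
        results = model.fit()
        for name, p in results.to_csv(out).items():
            paths[name] = str(p)
        paths["summary"] = str(out / "summary.txt")
        Path(paths["summary"]).write_text(results.summary() + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_subjects": len(config.subjects),
        "warnings": logs,
        "outputs": paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest
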