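"""Scored sleep (hypnogram) representation and macrostructure variables.

A hypnogram is an ordered sequence of AASM stages (W, N1, N2, N3, REM), one
per fixed-duration scoring epoch (20 s by default).  From it the classical
polysomnographic macrostructure variables are derived: sleep-onset latency,
REM latency, wake after sleep onset (WASO), total sleep/bed time, stage
percentages of total sleep time, sleep efficiency and the number of
intra-sleep awakenings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import FormatError

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")

#: Column names (and order) of the macrostructure report, matching the
#: conventional PSG summary-table layout.
MACRO_COLUMNS = (
    "SO latency (min)",
    "REM latency (min)",
    "WASO (min)",
    "N1 (%)",
    "N2 (%)",
    "N3 (%)",
    "REM (%)",
    "TBT (min)",
    "TST (min)",
    "SEI (%)",
    "ISA (#)",
)


@dataclass(frozen=True)
class Hypnogram:
    """An ordered sequence of scored sleep stages.

    Parameters
    ----------
    stages
        One AASM stage code per epoch, each in ``{"W","N1","N2","N3","REM"}``.
    epoch_duration
        Epoch length in seconds (20 s scoring is the default).
    lights_off
        First epoch of the in-bed interval (0-based, inclusive).
    lights_on
        End of the in-bed interval (0-based, exclusive).  Defaults to the
        number of epochs.
    so_marker
        Optional epoch index of sleep onset from event-level scoring (first
        K-complex or >0.5 s spindle); takes precedence over the stage-based
        fallback when present.
    """

    stages: tuple[str, ...]
    epoch_duration: float = 20.0
    lights_off: int = 0
    lights_on: Optional[int] = None
    so_marker: Optional[int] = None

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        n = len(stages)
        if n == 0:
            raise FormatError("hypnogram has no epochs")
        bad = [(i, s) for i, s in enumerate(stages) if s not in STAGES]
        if bad:
            i, s = bad[0]
            raise FormatError(f"unknown stage token {s!r} at epoch {i}")
        if self.epoch_duration <= 0:
            raise FormatError("epoch_duration must be positive")
        if self.lights_on is None:
            object.__setattr__(self, "lights_on", n)
        if not (0 <= self.lights_off < self.lights_on <= n):
            raise FormatError(
                f"lights bounds [{self.lights_off}, {self.lights_on}) invalid "
                f"for {n} epochs"
            )
        if self.so_marker is not None and not (
            self.lights_off <= self.so_marker < self.lights_on
        ):
            raise FormatError("so_marker outside the lights-off..lights-on interval")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def in_bed(self) -> tuple[str, ...]:
        """Stages of the in-bed (lights-off to lights-on) interval."""
        return self.stages[self.lights_off : self.lights_on]


@dataclass
class MacrostructureReport:
    """Macrostructural sleep variables for one recording.

    Latencies and WASO are ``None`` when the record contains no sleep (or,
    for ``rem_latency_min``, no REM).  Durations are minutes; stage
    percentages are relative to total sleep time.
    """

    so_latency_min: Optional[float]
    rem_latency_min: Optional[float]
    waso_min: Optional[float]
    n1_pct: float
    n2_pct: float
    n3_pct: float
    rem_pct: float
    tbt_min: float
    tst_min: float
    sei_pct: float
    isa_count: Optional[int]

    def to_dict(self) -> dict:
        vals = (
            self.so_latency_min,
            self.rem_latency_min,
            self.waso_min,
            self.n1_pct,
            self.n2_pct,
            self.n3_pct,
            self.rem_pct,
            self.tbt_min,
            self.tst_min,
            self.sei_pct,
            self.isa_count,
        )
        return dict(zip(MACRO_COLUMNS, vals))


def read_hypnogram(path: str | Path | io.TextIOBase, epoch_duration: float = 20.0) -> Hypnogram:
    """Read a hypnogram TSV.

    Format: optional ``#lights_off=<int>``, ``#lights_on=<int>``,
    ``#so_marker=<int>`` comment lines, then a header line ``epoch\tstage``
    followed by one row per epoch.  Epoch indexes must be contiguous from 0.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        lines = Path(path).read_text().splitlines()
        name = str(path)
    meta: dict[str, int] = {}
    rows: list[tuple[str, str]] = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            key = key.strip()
            if key in ("lights_off", "lights_on", "so_marker"):
                try:
                    meta[key] = int(val)
                except ValueError as exc:
                    raise FormatError(f"{name}:{lineno}: bad {key} value {val!r}") from exc
            continue
        parts = line.split("\t")
        if not header_seen:
            if [p.strip().lower() for p in parts[:2]] != ["epoch", "stage"]:
                raise FormatError(f"{name}:{lineno}: expected header 'epoch\\tstage'")
            header_seen = True
            continue
        if len(parts) < 2:
            raise FormatError(f"{name}:{lineno}: expected two tab-separated columns")
        rows.append((parts[0].strip(), parts[1].strip()))
    if not header_seen or not rows:
        raise FormatError(f"{name}: no hypnogram rows found")
    stages = []
    for i, (idx_s, stage) in enumerate(rows):
        try:
            idx = int(idx_s)
        except ValueError as exc:
            raise FormatError(f"{name}: row {i}: epoch index {idx_s!r} not an integer") from exc
        if idx != i:
            raise FormatError(
                f"{name}: non-contiguous epoch indexes (expected {i}, found {idx})"
            )
        if stage not in STAGES:
            raise FormatError(f"{name}: row {i}: unknown stage token {stage!r}")
        stages.append(stage)
    return Hypnogram(
        stages=tuple(stages),
        epoch_duration=epoch_duration,
        lights_off=meta.get("lights_off", 0),
        lights_on=meta.get("lights_on"),
        so_marker=meta.get("so_marker"),
    )


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram in the TSV format accepted by :func:`read_hypnogram`."""
    out = [f"#lights_off={h.lights_off}", f"#lights_on={h.lights_on}"]
    if h.so_marker is not None:
        out.append(f"#so_marker={h.so_marker}")
    out.append("epoch\tstage")
    out.extend(f"{i}\t{s}" for i, s in enumerate(h.stages))
    Path(path).write_text("\n".join(out) + "\n")


def sleep_onset_epoch(h: Hypnogram) -> Optional[int]:
    """Epoch index of sleep onset, or ``None`` for an all-wake record.

    Uses the event-scored ``so_marker`` when present; otherwise the first
    non-wake epoch within the in-bed interval.
    """
    if h.so_marker is not None:
        return h.so_marker
    for i in range(h.lights_off, h.lights_on):
        if h.stages[i] != "W":
            return i
    return None


def macrostructure(h: Hypnogram) -> MacrostructureReport:
    """Compute the macrostructure variables of a hypnogram.

    Conventions: total bed time spans lights-off to lights-on; REM latency is
    measured from sleep onset; WASO counts wake epochs strictly between sleep
    onset and the final sleep epoch (terminal wake excluded); ISA is the
    number of maximal wake runs counted in WASO; stage percentages are
    relative to total sleep time.
    """
    minutes = h.epoch_duration / 60.0
    tbt = (h.lights_on - h.lights_off) * minutes
    so = sleep_onset_epoch(h)
    if so is None:
        return MacrostructureReport(
            so_latency_min=None,
            rem_latency_min=None,
            waso_min=None,
            n1_pct=0.0,
            n2_pct=0.0,
            n3_pct=0.0,
            rem_pct=0.0,
            tbt_min=tbt,
            tst_min=0.0,
            sei_pct=0.0,
            isa_count=None,
        )
    bed = h.stages[h.lights_off : h.lights_on]
    counts = {s: 0 for s in STAGES}
    for s in bed:
        counts[s] += 1
    tst_epochs = sum(counts[s] for s in SLEEP_STAGES)
    tst = tst_epochs * minutes
    sol = (so - h.lights_off) * minutes

    rem_latency = None
    for i in range(so, h.lights_on):
        if h.stages[i] == "REM":
            rem_latency = (i - so) * minutes
            break

    last_sleep = max(
        i for i in range(h.lights_off, h.lights_on) if h.stages[i] != "W"
    )
    waso_epochs = 0
    isa = 0
    in_run = False
    for i in range(so + 1, last_sleep):
        if h.stages[i] == "W":
            waso_epochs += 1
            if not in_run:
                isa += 1
                in_run = True
        else:
            in_run = False

    def pct(stage: str) -> float:
        return 100.0 * counts[stage] / tst_epochs if tst_epochs else 0.0

    return MacrostructureReport(
        so_latency_min=sol,
        rem_latency_min=rem_latency,
        waso_min=waso_epochs * minutes,
        n1_pct=pct("N1"),
        n2_pct=pct("N2"),
        n3_pct=pct("N3"),
        rem_pct=pct("REM"),
        tbt_min=tbt,
        tst_min=tst,
        sei_pct=100.0 * tst / tbt if tbt else 0.0,
        isa_count=isa,
    )


def macrostructure_frame(reports: dict[str, MacrostructureReport]) -> pd.DataFrame:
    """Stack per-subject reports into a DataFrame with the standard columns."""
    df = pd.DataFrame({k: v.to_dict() for k, v in reports.items()}).T
    df.index.name = "subject"
    return df[list(MACRO_COLUMNS)].astype(float)
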