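"""Tidy-CSV time-course I/O and run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .timecourse import COLUMNS, TimeCourse, to_frame

log = logging.getLogger("ireskinetics")


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Read tidy time courses (columns ``time_s, signal, assay, replicate``,
    optional ``condition``) into one :class:`TimeCourse` per
    (assay, replicate, condition) group.

    Parse problems are reported with 1-based file line numbers (header is
    line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "condition" not in df.columns:
        df["condition"] = "ires"

    for col in ("time_s", "signal"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        if values.isna().any():
            lines = [int(i) + 2 for i in df.index[values.isna()][:5]]
            raise ValueError(f"{path}: missing {col!r} at line(s) {lines}")
        df[col] = values
    if (df["time_s"] < 0).any():
        lines = [int(i) + 2 for i in df.index[df["time_s"] < 0][:5]]
        raise ValueError(f"{path}: negative time_s at line(s) {lines}")

    out = []
    for (assay, replicate, condition), group in df.groupby(
        ["assay", "replicate", "condition"], sort=True
    ):
        times = group["time_s"].to_numpy()
        if np.any(np.diff(times) <= 0):
            i = int(np.nonzero(np.diff(times) <= 0)[0][0])
            line = int(group.index[i + 1]) + 2
            raise ValueError(
                f"{path}: unsorted or duplicated time_s for assay={assay!r} "
                f"replicate={replicate} at line {line}"
            )
        out.append(
            TimeCourse(
                times,
                group["signal"].to_numpy(),
                assay=str(assay),
                replicate=int(replicate),
                condition=str(condition),
            )
        )
    return out


def write_timecourses(tcs: list[TimeCourse], path: str | Path) -> None:
    """Write tidy CSV; float formatting round-trips to full precision."""
    to_frame(tcs).to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run configuration; the seed is embedded in every artifact."""

    output_dir: Path | None = Path("ireskinetics_out")
    scheme_path: Path | None = None
    data_paths: tuple[Path, ...] = ()
    seed: int = 0
    error_method: str = "quadrature"
    c_constant: float = 0.69
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir) if self.output_dir is not None else None
        if self.scheme_path is not None:
            self.scheme_path = Path(self.scheme_path)
            if not self.scheme_path.exists():
                raise FileNotFoundError(self.scheme_path)
        self.data_paths = tuple(Path(p) for p in self.data_paths)
        for p in self.data_paths:
            if not p.exists():
                raise FileNotFoundError(p)
        if self.error_method not in ("quadrature", "linear"):
            raise ValueError("error_method must be 'quadrature' or 'linear'")

    def config_hash(self) -> str:
        payload = {
            "scheme": str(self.scheme_path),
            "data": [str(p) for p in self.data_paths],
            "seed": self.seed,
            "error_method": self.error_method,
            "c": self.c_constant,
            **self.extra,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}
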