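"""Delimited-text and JSON I/O for cohorts, matrices and reports.

Layouts
-------
* Time courses: one TSV per subject, rows = regions, first column = region
  label, remaining columns = samples.  The sampling interval travels in the
  run configuration, not the file.
* Coupling matrices: r x r TSV with region labels as both index and header.
* Cohort stacks: one long-format TSV (subject, target, source, value) plus a
  small JSON sidecar holding measure, symmetry and seeds.
* Reports and configs: JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kuramoto import CouplingMatrix, MeasureStack
from .signals import NARROW_BAND, WIDE_BAND, TimeCourseSet

__all__ = [
    "RunConfig",
    "read_timecourses",
    "write_timecourses",
    "read_matrix",
    "write_matrix",
    "read_stack",
    "write_stack",
    "read_regressors",
    "write_json",
]


@dataclass
class RunConfig:
    """Parameters of one analysis run (bands, thresholds, seeds).

    Defaults are the empirical pipeline's stated values: narrow 0.05-0.075 Hz
    band for phase measures, wide 0.01-0.1 Hz band for FC/AR, order-7
    Butterworth, uncorrected threshold P_u = 0.05, 500 permutations.
    """

    dt: float = 2.0
    band_K: tuple[float, float] = NARROW_BAND
    band_FC_AR: tuple[float, float] = WIDE_BAND
    filter_order: int = 7
    omega_mode: str = "band_mean"
    threshold_pu: float = 0.05
    n_perm: int = 500
    bonferroni_factor: int = 3
    seed: int = 0
    measures: tuple[str, ...] = ("K",)
    outlier_sd: float = 2.0

    def __post_init__(self) -> None:
        self.band_K = tuple(self.band_K)
        self.band_FC_AR = tuple(self.band_FC_AR)
        self.measures = tuple(self.measures)
        nyq = 0.5 / self.dt
        for band in (self.band_K, self.band_FC_AR):
            if not 0 < band[0] < band[1] < nyq:
                raise ValidationError(f"band {band} invalid for dt={self.dt}")
        for m in self.measures:
            if m not in ("K", "FC", "PS", "AR"):
                raise ValidationError(f"unknown measure {m!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_timecourses(path: str | Path, dt: float) -> TimeCourseSet:
    """Read one subject's region x time TSV (region labels in column 0)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, header=None)
    # tolerate an optional header row of sample indices
    try:
        data = df.to_numpy(dtype=float)
    except ValueError:
        df = pd.read_csv(path, sep="\t", index_col=0)
        data = df.to_numpy(dtype=float)
    return TimeCourseSet(
        data=data,
        dt=dt,
        region_labels=[str(x) for x in df.index],
        subject_id=path.stem,
    )


def write_timecourses(tc: TimeCourseSet, path: str | Path) -> None:
    df = pd.DataFrame(tc.data, index=tc.region_labels)
    df.to_csv(path, sep="\t", header=False, float_format="%.10g")


def write_matrix(cm: CouplingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.values, index=cm.region_labels, columns=cm.region_labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path, measure: str, directed: bool) -> CouplingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CouplingMatrix(
        values=df.to_numpy(dtype=float),
        measure=measure,
        directed=directed,
        region_labels=[str(x) for x in df.index],
        subject_id=Path(path).stem,
        diagonal_convention=None if measure == "AR" else 1.0,
    )


def write_stack(stack: MeasureStack, path: str | Path, metadata: dict | None = None) -> None:
    """Long-format stack table plus a JSON sidecar with stack metadata."""
    path = Path(path)
    s, r, _ = stack.tensor.shape
    subj = np.repeat(stack.subject_ids, r * r)
    tgt, src = np.meshgrid(np.arange(r), np.arange(r), indexing="ij")
    df = pd.DataFrame(
        {
            "subject": subj,
            "target": np.tile(tgt.ravel(), s),
            "source": np.tile(src.ravel(), s),
            "value": stack.tensor.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "measure": stack.measure,
        "symmetric": stack.symmetric,
        "n_subjects": s,
        "n_regions": r,
        "subject_ids": list(stack.subject_ids),
    }
    if metadata:
        sidecar.update(metadata)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_stack(path: str | Path) -> MeasureStack:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, sep="\t")
    s, r = meta["n_subjects"], meta["n_regions"]
    tensor = np.empty((s, r, r))
    order = {sid: k for k, sid in enumerate(meta["subject_ids"])}
    for sid, grp in df.groupby("subject", sort=False):
        k = order[str(sid)]
        tensor[k] = np.asarray(grp["value"]).reshape(r, r)
    return MeasureStack(
        tensor=tensor,
        measure=meta["measure"],
        subject_ids=[str(x) for x in meta["subject_ids"]],
        symmetric=bool(meta["symmetric"]),
    )


def read_regressors(path: str | Path) -> pd.DataFrame:
    """Per-subject regressor table: a 'subject' column plus scalar columns."""
    df = pd.read_csv(path, sep="\t")
    if "subject" not in df.columns:
        raise ValidationError("regressor table needs a 'subject' column")
    return df.set_index(df["subject"].astype(str)).drop(columns="subject")


def write_json(obj: dict, path: str | Path) -> None:
    def _default(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        raise TypeError(f"not JSON serialisable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
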