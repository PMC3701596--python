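"""In-memory containers for expression studies and activity traces, with
plain-text readers and writers.

An :class:`ExpressionStudy` holds a probes-by-samples matrix of log2
expression intensities together with the per-sample design metadata
(tissue, experimental arm, hours of sleep opportunity, animal id).  Every
analysis stage in this package consumes this object.  An
:class:`ActivityTrace` holds an epoch-by-epoch beam-break count series used
for behavioural sleep scoring.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

ARMS = ("baseline", "sleep", "deprived")

SAMPLE_COLUMNS = ["sample_id", "tissue", "arm", "time_h", "animal_id"]


class DesignError(ValueError):
    """Raised when sample metadata violates the study design contract."""


@dataclasses.dataclass
class ExpressionStudy:
    """A log2 expression matrix plus its per-sample design metadata.

    Parameters
    ----------
    probe_ids : array-like of str
        Probe identifiers, one per matrix row.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``tissue``, ``arm``
        (``baseline``/``sleep``/``deprived``), ``time_h`` and ``animal_id``.
    values : numpy.ndarray
        Float matrix of shape ``(n_probes, n_samples)``; log2 intensities.
    """

    probe_ids: np.ndarray
    samples: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- contract checks -------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DesignError(f"sample sheet missing columns: {missing}")
        if self.values.shape != (len(self.probe_ids), len(self.samples)):
            raise DesignError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DesignError("expression values must all be finite")
        bad_arm = set(self.samples["arm"]) - set(ARMS)
        if bad_arm:
            raise DesignError(f"unknown arm labels: {sorted(bad_arm)}")
        t = self.samples["time_h"].to_numpy(dtype=float)
        is_base = (self.samples["arm"] == "baseline").to_numpy()
        if np.any(is_base & (t != 0)) or np.any(~is_base & (t == 0)):
            raise DesignError("arm == 'baseline' must hold exactly when time_h == 0")
        dup = self.samples.duplicated(subset=["tissue", "animal_id"])
        if dup.any():
            raise DesignError("(tissue, animal_id) pairs must be unique")
        cells = self.samples[~is_base].groupby(["tissue", "arm", "time_h"]).size()
        if (cells < 2).any():
            small = cells[cells < 2].index.tolist()
            raise DesignError(f"design cells with < 2 samples: {small}")

    # -- convenience -----------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def subset(self, tissue: str | None = None, arms=None) -> "ExpressionStudy":
        """Return the sub-study restricted to a tissue and/or set of arms."""
        mask = np.ones(self.n_samples, dtype=bool)
        if tissue is not None:
            mask &= (self.samples["tissue"] == tissue).to_numpy()
        if arms is not None:
            mask &= self.samples["arm"].isin(arms).to_numpy()
        if not mask.any():
            raise DesignError(f"no samples match tissue={tissue!r}, arms={arms!r}")
        return ExpressionStudy(
            probe_ids=self.probe_ids,
            samples=self.samples.loc[mask].reset_index(drop=True),
            values=self.values[:, mask],
        )

    def resolve_tissue(self, tissue: str | None) -> "ExpressionStudy":
        """Return the single-tissue view, requiring ``tissue`` if ambiguous."""
        present = self.tissues()
        if tissue is None:
            if len(present) > 1:
                raise DesignError(
                    f"study contains tissues {present}; specify which to analyse"
                )
            return self
        if tissue not in present:
            raise DesignError(f"tissue {tissue!r} not present (have {present})")
        return self.subset(tissue=tissue)


@dataclasses.dataclass
class ActivityTrace:
    """Beam-break counts per fixed-length epoch.

    ``t0_h`` is the clock time of the first epoch in Zeitgeber hours
    (ZT0 = lights on).
    """

    epoch_s: int
    counts: np.ndarray
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.epoch_s <= 0 or 60 % self.epoch_s != 0:
            raise ValueError("epoch_s must be a positive divisor of 60")
        if np.any(self.counts < 0):
            raise ValueError("beam-break counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def duration_s(self) -> int:
        return self.n_epochs * self.epoch_s


# ---------------------------------------------------------------------------
# Plain-text readers / writers (TSV for matrices, CSV for activity traces)
# ---------------------------------------------------------------------------

def write_study(study: ExpressionStudy, matrix_path, samples_path) -> None:
    mat = pd.DataFrame(
        study.values,
        index=pd.Index(study.probe_ids, name="probe_id"),
        columns=study.samples["sample_id"],
    )
    mat.to_csv(matrix_path, sep="\t", float_format="%.10g")
    study.samples[SAMPLE_COLUMNS].to_csv(samples_path, sep="\t", index=False)


def read_study(matrix_path, samples_path) -> ExpressionStudy:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "animal_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DesignError(f"{samples_path}: missing columns {missing}")
    sample_ids = samples["sample_id"].tolist()
    if list(mat.columns) != sample_ids:
        try:
            mat = mat[sample_ids]
        except KeyError as exc:
            raise DesignError(
                f"{matrix_path}: columns do not match sample sheet ids"
            ) from exc
    return ExpressionStudy(
        probe_ids=mat.index.to_numpy(dtype=object),
        samples=samples,
        values=mat.to_numpy(dtype=float),
    )


def write_activity(trace: ActivityTrace, path) -> None:
    start = trace.t0_h * 3600.0 + np.arange(trace.n_epochs) * trace.epoch_s
    pd.DataFrame({"epoch_start_s": start, "counts": trace.counts}).to_csv(
        path, index=False
    )


def read_activity(path) -> ActivityTrace:
    df = pd.read_csv(path)
    if not {"epoch_start_s", "counts"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns epoch_start_s, counts")
    start = df["epoch_start_s"].to_numpy(dtype=float)
    if len(start) < 2:
        raise ValueError(f"{path}: need at least 2 epochs to infer epoch length")
    steps = np.diff(start)
    if not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: epochs are not evenly spaced")
    return ActivityTrace(
        epoch_s=int(round(steps[0])),
        counts=df["counts"].to_numpy(dtype=int),
        t0_h=float(start[0]) / 3600.0,
    )


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table as TSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
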