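"""Angular error metrics and the calibration-error sweep study.

The error of an estimated segment orientation is the relative rotation
angle to the ground-truth orientation, ``E = 2 acos |(q_ref ⊙ q_est*)_w|``
in degrees.  Statistics aggregate over ``K`` segments and ``N`` time
steps: the mean of per-segment time means, the mean of per-segment time
standard deviations (N-1 denominator), and the overall maximum.  The
normalized range error sums a tracker's mean errors over a calibration
error grid and divides by the reference tracker's worst-case sum, so 1.0
means "as sensitive as the reference".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .body import BodyModel, build_arm_model
from .ekf import Chaintracker, EKFConfig, QuattrackerIMU, QuattrackerSegment
from .opti import Optitracker, OptiConfig
from .quat import rotation_angle
from .simulate import (
    AngleSequenceParams,
    CalibrationErrorSpec,
    NoiseConfig,
    simulate_arm_sequence,
    sweep_grid,
)

__all__ = [
    "ErrorStats",
    "SweepResult",
    "TRACKERS",
    "make_tracker",
    "angular_error_series",
    "error_stats",
    "normalized_range_error",
    "run_sweep",
    "render_report",
]

TRACKERS = {
    "chain": Chaintracker,
    "quat-seg": QuattrackerSegment,
    "quat-imu": QuattrackerIMU,
    "opti": Optitracker,
}


def make_tracker(method: str, data, model: BodyModel, config=None):
    """Instantiate a tracker by its short name (see :data:`TRACKERS`)."""
    try:
        cls = TRACKERS[method]
    except KeyError:
        raise ValueError(f"unknown tracker {method!r}; choose from {sorted(TRACKERS)}") from None
    if config is None:
        config = OptiConfig() if cls is Optitracker else EKFConfig()
    return cls(data, model, config)


def angular_error_series(est_quat: np.ndarray, ref_quat: np.ndarray) -> np.ndarray:
    """Per-segment, per-step angular error in degrees.

    Inputs are ``(n_segments, n_t, 4)`` quaternion arrays; double-cover sign
    flips do not affect the result.
    """
    est_quat = np.asarray(est_quat, dtype=float)
    ref_quat = np.asarray(ref_quat, dtype=float)
    if est_quat.shape != ref_quat.shape:
        raise ValueError("estimate and reference series have different shapes")
    return rotation_angle(ref_quat, est_quat)


@dataclass(frozen=True)
class ErrorStats:
    """Aggregated angular error statistics, degrees."""

    e_mean: float
    e_sd: float
    e_max: float
    n_segments: int
    n_steps: int

    def __str__(self) -> str:
        return f"{self.e_mean:.2f} deg ({self.e_sd:.2f}; {self.e_max:.2f})"


def error_stats(errors: np.ndarray, segments: Iterable[int] | None = None) -> ErrorStats:
    """Statistics over a ``(n_segments, n_t)`` error series (degrees).

    ``segments`` restricts the aggregation (``K=1`` gives per-segment
    statistics).  The standard deviation is the mean over segments of the
    per-segment temporal standard deviation about the per-segment mean
    (N-1 denominator).
    """
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    if segments is not None:
        errors = errors[np.asarray(list(segments), dtype=int)]
    if errors.size == 0:
        raise ValueError("empty error series")
    k, n = errors.shape
    per_mean = errors.mean(axis=1)
    if n > 1:
        per_sd = np.sqrt(np.sum((errors - per_mean[:, None]) ** 2, axis=1) / (n - 1))
    else:
        per_sd = np.zeros(k)
    return ErrorStats(float(per_mean.mean()), float(per_sd.mean()), float(errors.max()), k, n)


def normalized_range_error(
    tracker_sums: float, reference_sums_by_test: Iterable[float]
) -> float:
    """Sum of a tracker's grid mean errors over the reference's worst test.

    ``tracker_sums`` is the tracker's sum of mean errors over one error
    type's grid; ``reference_sums_by_test`` are the reference tracker's
    corresponding sums for every test (sequence x condition); the maximum
    of those is the denominator.
    """
    denom = max(reference_sums_by_test)
    if denom <= 0:
        raise ZeroDivisionError("reference tracker sums are all zero")
    return float(tracker_sums) / float(denom)


@dataclass
class SweepResult:
    """Tidy per-run records of a calibration-error sweep.

    ``table`` columns: tracker, condition (mag / nomag), error_type,
    magnitude, segment (0..K-1 or 'all'), e_mean, e_sd, e_max.
    """

    table: pd.DataFrame
    reference: str = "chain"

    def normalized_range_errors(self) -> pd.DataFrame:
        """Eq.-(23)-style table: one row per (tracker, condition, error_type)."""
        df = self.table[self.table.segment == "all"]
        sums = (
            df.groupby(["tracker", "condition", "error_type"])["e_mean"].sum().rename("sum_mean")
        ).reset_index()
        ref = sums[sums.tracker == self.reference]
        denom = {
            et: ref[ref.error_type == et]["sum_mean"].max() for et in sums.error_type.unique()
        }
        sums["normalized_range_error"] = [
            s / denom[et] if denom[et] > 0 else np.nan
            for s, et in zip(sums.sum_mean, sums.error_type)
        ]
        return sums


def run_sweep(
    trackers: Iterable[str] = ("chain", "quat-seg", "quat-imu", "opti"),
    conditions: Iterable[str] = ("mag", "nomag"),
    grid: Iterable[CalibrationErrorSpec] | None = None,
    model: BodyModel | None = None,
    params: AngleSequenceParams | None = None,
    noise: NoiseConfig | None = None,
    configs: Mapping[str, object] | None = None,
    include_baseline: bool = True,
    progress: bool = False,
) -> SweepResult:
    """Run the calibration-error study.

    For every grid point, IMU data is simulated from the model with that
    error injected; every tracker then runs with the *nominal* model and is
    scored against the unperturbed ground-truth segment orientations.  The
    default grid is the full 120-point study grid; pass a smaller ``grid``
    for quick looks.  ``conditions`` selects magnetometer usage; data is
    noise-free unless a ``noise`` config is given.
    """
    model = model or build_arm_model()
    grid = list(sweep_grid() if grid is None else grid)
    specs: list[CalibrationErrorSpec | None] = ([None] if include_baseline else []) + grid
    configs = configs or {}
    rows = []
    for spec in specs:
        truth, data = simulate_arm_sequence(
            model=model, params=params, calibration_error=spec, noise=noise, magnetometer=True
        )
        for condition in conditions:
            # the magnetometer channel stays in the dataset (the first sample
            # seeds the initial heading in both conditions); the tracking-time
            # measurement model is switched off via the tracker config
            for name in trackers:
                if progress:  # pragma: no cover - cosmetic
                    mag = "w/mag" if condition == "mag" else "w/o mag"
                    print(f"[sweep] {name} {mag} {spec.type if spec else 'baseline'} "
                          f"{spec.magnitude if spec else 0}")
                base_cfg = configs.get(name)
                if base_cfg is None:
                    base_cfg = OptiConfig() if name == "opti" else EKFConfig()
                cfg = dataclasses.replace(base_cfg, use_magnetometer=(condition == "mag"))
                res = make_tracker(name, data, model, cfg).fit()
                err = angular_error_series(res.seg_quat, truth.seg_quat)
                base = {
                    "tracker": name,
                    "condition": condition,
                    "error_type": spec.type if spec else "none",
                    "magnitude": spec.magnitude if spec else 0.0,
                }
                for i in range(err.shape[0]):
                    st = error_stats(err, segments=[i])
                    rows.append(base | {"segment": str(i), "e_mean": st.e_mean, "e_sd": st.e_sd, "e_max": st.e_max})
                st = error_stats(err)
                rows.append(base | {"segment": "all", "e_mean": st.e_mean, "e_sd": st.e_sd, "e_max": st.e_max})
    return SweepResult(pd.DataFrame(rows))


def render_report(result: SweepResult, out_dir, figures: bool = False) -> list:
    """Write sweep tables (CSV + markdown) and optional error-vs-magnitude
    curves; returns the list of files written."""
    from pathlib import Path

    if result.table.empty:
        raise ValueError("empty sweep result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    p = out / "sweep_stats.csv"
    result.table.to_csv(p, index=False)
    written.append(p)
    nre = result.normalized_range_errors()
    p = out / "normalized_range_errors.csv"
    nre.to_csv(p, index=False)
    written.append(p)
    p = out / "normalized_range_errors.md"
    with open(p, "w") as fh:
        piv = nre.pivot_table(
            index="error_type", columns=["tracker", "condition"], values="normalized_range_error"
        )
        fh.write(piv.round(3).to_markdown())
        fh.write("\n")
    written.append(p)
    if figures:  # pragma: no cover - optional matplotlib path
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = result.table[(result.table.segment != "all") & (result.table.error_type != "none")]
        for (etype, cond), sub in df.groupby(["error_type", "condition"]):
            fig, ax = plt.subplots()
            for (trk, seg), ss in sub.groupby(["tracker", "segment"]):
                ss = ss.sort_values("magnitude")
                ax.plot(ss.magnitude, ss.e_mean, label=f"{trk} S{seg}")
            ax.set_xlabel("error magnitude")
            ax.set_ylabel("mean angular error [deg]")
            ax.set_title(f"{etype} ({cond})")
            ax.legend(fontsize=6)
            p = out / f"curve_{etype}_{cond}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written
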