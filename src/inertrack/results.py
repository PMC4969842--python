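"""Tracking results: estimated kinematics, diagnostics and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["TrackingResult"]


@dataclass
class TrackingResult:
    """Estimated per-segment kinematics from one tracker run.

    ``seg_quat``: ``(n_segments, n_t, 4)`` global segment orientations
    ``q_GS``; ``seg_pos``: ``(n_segments, n_t, 3)`` global segment origins.
    ``diagnostics`` carries per-step innovation norms, solver iteration
    counts and similar method-specific records.
    """

    method: str
    t: np.ndarray
    seg_quat: np.ndarray
    seg_pos: np.ndarray
    imu_quat: np.ndarray | None = None
    imu_pos: np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)
    config: Any = None

    @property
    def n_segments(self) -> int:
        return self.seg_quat.shape[0]

    @property
    def n_samples(self) -> int:
        return self.seg_quat.shape[1]

    def angular_errors(self, ref_quat: np.ndarray) -> np.ndarray:
        """Per-segment angular error series (degrees) against a reference."""
        from .evaluate import angular_error_series

        return angular_error_series(self.seg_quat, ref_quat)

    def error_stats(self, ref_quat: np.ndarray):
        from .evaluate import error_stats

        return error_stats(self.angular_errors(ref_quat))

    def summary(self, ref_quat: np.ndarray | None = None) -> str:
        """Human-readable run summary; adds error statistics if a reference
        orientation series is supplied."""
        lines = [
            f"Tracker: {self.method}",
            f"  segments: {self.n_segments}   samples: {self.n_samples}"
            f"   duration: {self.t[-1] - self.t[0]:.2f} s",
        ]
        for key in ("mean_innovation_norm", "max_innovation_norm", "mean_iterations"):
            if key in self.diagnostics:
                lines.append(f"  {key.replace('_', ' ')}: {self.diagnostics[key]:.4g}")
        if ref_quat is not None:
            stats = self.error_stats(ref_quat)
            lines.append(
                "  angular error vs reference:"
                f" mean {stats.e_mean:.3f} deg, sd {stats.e_sd:.3f} deg, max {stats.e_max:.3f} deg"
            )
            per_seg = self.angular_errors(ref_quat).mean(axis=1)
            lines.append(
                "  per-segment mean: "
                + ", ".join(f"S{i} {v:.3f} deg" for i, v in enumerate(per_seg))
            )
        return "\n".join(lines)
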