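"""Scoring autofocus policies on focal-time scans.

A policy is stepped through a scan frame by frame; each frame after the
first, the post-action focal error ``|f* - f|`` is recorded.  Summaries are
the mean absolute focal error (MAE, on the normalised 0-1 focal scale), its
per-frame standard deviation, and the percentage of in-focus frames (error
below 0.1 by default).

:func:`compare_policies` aggregates over a scan set and attaches a paired
Wilcoxon signed-rank test over per-scan MAEs between every policy pair.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import extract_patch, locate_patch
from .policies import Policy
from .simulate import FocalTimeScan

__all__ = [
    "EvalResult",
    "IN_FOCUS_THRESHOLD",
    "evaluate",
    "smooth_trajectory",
    "compare_policies",
]

#: focal-power error below which a frame counts as in focus
IN_FOCUS_THRESHOLD = 0.1


@dataclasses.dataclass
class EvalResult:
    """Per-frame trajectory and summary statistics for one (policy, scan)."""

    f: np.ndarray
    fstar: np.ndarray
    error: np.ndarray
    threshold: float = IN_FOCUS_THRESHOLD

    @property
    def frames(self) -> int:
        return len(self.error)

    @property
    def mae(self) -> float:
        return float(self.error.mean())

    @property
    def mae_std(self) -> float:
        return float(self.error.std())

    def in_focus_pct(self, threshold: float | None = None) -> float:
        thr = self.threshold if threshold is None else threshold
        return float((self.error < thr).mean() * 100.0)

    def to_frame(self) -> pd.DataFrame:
        """Per-frame trajectory table (t, f, f_star, error)."""
        t = np.arange(1, self.frames + 1)
        return pd.DataFrame(
            {"t": t, "f": self.f[1:], "f_star": self.fstar[1:], "error": self.error}
        )


def evaluate(
    policy: Policy,
    scan: FocalTimeScan,
    seed: int | None = None,
    f0: float | None = None,
    patch_origin: tuple[int, int] | None = None,
    threshold: float = IN_FOCUS_THRESHOLD,
) -> EvalResult:
    """Step ``policy`` through ``scan`` and score its focal trajectory.

    The initial focal power is drawn uniformly (seeded) unless ``f0`` is
    given; frame 0 carries no policy action and is not scored.  The policy
    sees the 32x32 observation patch rendered at its current focal power,
    then emits the focal power used for the next frame; the error recorded
    at frame t >= 1 is the post-action ``|f*_t - f_t|``.
    """
    if scan.length < 2:
        raise ValueError("scan must have at least 2 frames")
    rng = np.random.default_rng(seed)
    f = float(rng.uniform()) if f0 is None else float(f0)
    if not 0.0 <= f <= 1.0:
        raise ValueError("f0 must lie in [0, 1]")
    policy.reset(seed)
    fs = np.empty(scan.length)
    fstars = np.empty(scan.length)
    errors = np.empty(scan.length - 1)
    fs[0], fstars[0] = f, scan.fstar(0)
    for t in range(1, scan.length):
        frame = scan.render(t - 1, f)
        origin = patch_origin if patch_origin is not None else locate_patch(frame)
        patch = extract_patch(frame, origin)
        f = float(policy.observe(patch, f))
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"policy emitted focal power {f} outside [0, 1]")
        fs[t], fstars[t] = f, scan.fstar(t)
        errors[t - 1] = abs(fstars[t] - f)
    return EvalResult(fs, fstars, errors, threshold)


def smooth_trajectory(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average with a symmetrically shrinking window at the
    ends; length-preserving.  ``window`` must be odd (1 = identity)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    n = len(series)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = series[i - k : i + k + 1].mean()
    return out


def compare_policies(
    policies: dict[str, Policy],
    scans: list[FocalTimeScan],
    seeds: list[int] | None = None,
    threshold: float = IN_FOCUS_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score several policies on a common scan set.

    Each policy is reset per scan; the same per-scan evaluation seed (hence
    the same initial focal power) is shared across policies, making the
    comparison paired.

    Returns
    -------
    table
        One row per policy: pooled per-frame MAE and std, per-scan MAE mean
        and std, in-focus percentage, frame count.
    pvalues
        Symmetric matrix of paired two-sided Wilcoxon signed-rank p-values
        over per-scan MAEs (NaN on the diagonal and for identical scores).
    """
    if not policies or not scans:
        raise ValueError("need at least one policy and one scan")
    if seeds is None:
        seeds = list(range(len(scans)))
    if len(seeds) != len(scans):
        raise ValueError("one seed per scan required")
    per_scan: dict[str, list[EvalResult]] = {}
    for name, policy in policies.items():
        per_scan[name] = [
            evaluate(policy, scan, seed=seed, threshold=threshold)
            for scan, seed in zip(scans, seeds)
        ]
    rows = []
    for name, results in per_scan.items():
        errors = np.concatenate([r.error for r in results])
        scan_maes = np.array([r.mae for r in results])
        rows.append(
            {
                "policy": name,
                "mae": float(errors.mean()),
                "mae_std": float(errors.std()),
                "mae_scan_mean": float(scan_maes.mean()),
                "mae_scan_std": float(scan_maes.std()),
                "in_focus_pct": float((errors < threshold).mean() * 100.0),
                "frames": int(len(errors)),
            }
        )
    table = pd.DataFrame(rows).set_index("policy")

    names = list(policies)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.array([r.mae for r in per_scan[a]])
            xb = np.array([r.mae for r in per_scan[b]])
            diff = xa - xb
            if np.allclose(diff, 0.0):
                continue
            p = float(stats.wilcoxon(xa, xb).pvalue)
            pvals.loc[a, b] = pvals.loc[b, a] = p
    return table, pvals


def format_table(table: pd.DataFrame) -> str:
    """Plain-text summary in the mean ± std / percent layout."""
    lines = [f"{'policy':<18}{'MAE':>16}{'in focus':>12}"]
    for name, row in table.iterrows():
        lines.append(
            f"{name:<18}{row['mae']:>8.3f} ±{row['mae_std']:.3f}"
            f"{row['in_focus_pct']:>11.1f}%"
        )
    return "\n".join(lines)
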