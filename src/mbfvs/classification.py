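"""Normal/abnormal flow classification and Dice-based agreement statistics.

A flow value is abnormal iff it falls strictly below the lower bound of the
low-risk range at its position; values at or above the lower bound (including
above the upper bound) are normal.  Two Dice variants are provided:

* ``matched-fraction`` (default): DC = 2m / (n_a + n_b) with m the number of
  positions whose labels agree (equal-length vectors, so DC = m/n).
* ``abnormal-set``: set Dice over the abnormal index sets,
  DC = 2|A&B| / (|A| + |B|), defined as 1 when both sets are empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import FlowProfile, interpolate_profile

__all__ = [
    "NormalRange",
    "ClassificationVector",
    "AgreementResult",
    "TTestResult",
    "DC_MODES",
    "build_normal_range",
    "classify",
    "dice_agreement",
    "pool_agreement",
    "compare_dc_groups",
]

DC_MODES = ("matched-fraction", "abnormal-set")


class ClassificationError(ValueError):
    pass


@dataclass
class NormalRange:
    """Per-position low-risk flow band for one vessel and state."""

    vessel: str
    state: str
    positions: np.ndarray  # mm from base, strictly increasing
    lower: np.ndarray  # mL/min/g
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = self.positions.size
        if n == 0 or self.lower.size != n or self.upper.size != n:
            raise ClassificationError("range arrays must be non-empty and consistent")
        if np.any(np.diff(self.positions) <= 0):
            raise ClassificationError("range positions must be strictly increasing")
        if np.any(self.lower > self.upper):
            raise ClassificationError("lower bound exceeds upper bound")
        if np.any(self.lower < 0):
            raise ClassificationError("bounds must be non-negative")

    def bounds_at(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of the band; no extrapolation."""
        positions = np.asarray(positions, dtype=float)
        if positions.min() < self.positions[0] - 1e-9 or positions.max() > self.positions[-1] + 1e-9:
            raise ClassificationError(
                f"positions [{positions.min():.1f}, {positions.max():.1f}] mm outside the "
                f"range span [{self.positions[0]:.1f}, {self.positions[-1]:.1f}] mm"
            )
        lo = np.interp(positions, self.positions, self.lower)
        hi = np.interp(positions, self.positions, self.upper)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vessel": self.vessel,
                "state": self.state,
                "position_mm": self.positions,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormalRange":
        return cls(
            vessel=str(df["vessel"].iloc[0]),
            state=str(df["state"].iloc[0]),
            positions=df["position_mm"].to_numpy(),
            lower=df["lower"].to_numpy(),
            upper=df["upper"].to_numpy(),
        )


@dataclass
class ClassificationVector:
    labels: np.ndarray  # bool: True = abnormal
    positions: np.ndarray
    vessel: str
    state: str
    provenance: str = "M"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.labels.size == 0 or self.labels.size != self.positions.size:
            raise ClassificationError("labels and positions must be non-empty and matched")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_abnormal(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class AgreementResult:
    dc: float
    n: int
    matched: int
    mismatched: int
    n_abnormal_a: int
    n_abnormal_b: int
    mode: str
    group: str = "global"

    def __post_init__(self) -> None:
        if not (0.0 <= self.dc <= 1.0):
            raise ClassificationError(f"DC must lie in [0, 1], got {self.dc}")
        if self.matched + self.mismatched != self.n:
            raise ClassificationError("matched + mismatched must equal n")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    paired: bool
    n_a: int
    n_b: int
    degenerate: bool = False


def build_normal_range(
    profiles: Sequence[FlowProfile],
    k_sd: float = 2.0,
    step_mm: float | None = None,
) -> NormalRange:
    """Per-position mean +/- k_sd * sample SD band from low-risk profiles.

    Profiles are resampled onto a common grid spanning their shared extent
    before the band is formed; the lower bound is clipped at 0.
    """
    if len(profiles) < 2:
        raise ClassificationError("need >= 2 low-risk profiles to build a range")
    vessel, state = profiles[0].vessel, profiles[0].state
    if any(p.vessel != vessel or p.state != state for p in profiles):
        raise ClassificationError("all profiles must share vessel and state labels")

    lo_pos = max(p.positions[0] for p in profiles)
    hi_pos = min(p.positions[-1] for p in profiles)
    if hi_pos <= lo_pos:
        raise ClassificationError("profiles share no common position span")
    if step_mm is None:
        step_mm = float(np.median(np.diff(profiles[0].positions)))
    common = np.arange(lo_pos, hi_pos + step_mm / 2.0, step_mm)
    common = np.clip(common, lo_pos, hi_pos)

    values = []
    for p in profiles:
        if len(p) >= 2:
            s, v = interpolate_profile(p, step_mm=step_mm / 4.0)
            values.append(np.interp(common, s, v))
        else:
            values.append(np.full_like(common, p.mbf[0]))
    arr = np.vstack(values)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    lower = np.maximum(mean - k_sd * sd, 0.0)
    upper = mean + k_sd * sd
    return NormalRange(vessel=vessel, state=state, positions=common, lower=lower, upper=upper)


def classify(profile: FlowProfile, normal_range: NormalRange) -> ClassificationVector:
    """Label each ROI normal/abnormal against the range; abnormal means strictly
    below the interpolated lower bound ("within the range" is inclusive)."""
    lo, _ = normal_range.bounds_at(profile.positions)
    labels = profile.mbf < lo
    return ClassificationVector(
        labels=labels,
        positions=profile.positions,
        vessel=profile.vessel,
        state=profile.state,
        provenance=profile.provenance,
    )


def _check_comparable(a: ClassificationVector, b: ClassificationVector) -> None:
    if len(a) != len(b):
        raise ClassificationError(f"vector lengths differ ({len(a)} vs {len(b)})")
    if not np.allclose(a.positions, b.positions, atol=1e-6):
        raise ClassificationError("vector positions do not match")
    if a.vessel != b.vessel or a.state != b.state:
        raise ClassificationError("vessel/state labels do not match")


def _dice_from_labels(la: np.ndarray, lb: np.ndarray, mode: str) -> float:
    n = la.size
    if mode == "matched-fraction":
        m = int(np.sum(la == lb))
        dc = 2.0 * m / (2.0 * n)
    elif mode == "abnormal-set":
        inter = int(np.sum(la & lb))
        tot = int(la.sum() + lb.sum())
        dc = 1.0 if tot == 0 else 2.0 * inter / tot
    else:
        raise ClassificationError(f"unknown DC mode {mode!r}; choose from {DC_MODES}")
    return float(np.clip(dc, 0.0, 1.0))


def dice_agreement(
    a: ClassificationVector, b: ClassificationVector, mode: str = "matched-fraction",
    group: str = "global",
) -> AgreementResult:
    _check_comparable(a, b)
    matched = int(np.sum(a.labels == b.labels))
    return AgreementResult(
        dc=_dice_from_labels(a.labels, b.labels, mode),
        n=len(a),
        matched=matched,
        mismatched=len(a) - matched,
        n_abnormal_a=a.n_abnormal,
        n_abnormal_b=b.n_abnormal,
        mode=mode,
        group=group,
    )


def pool_agreement(
    pairs: Sequence[tuple[ClassificationVector, ClassificationVector]],
    mode: str = "matched-fraction",
    by_territory: bool = True,
) -> pd.DataFrame:
    """Recompute DC over concatenated samples (never a mean of per-vessel DCs).

    Returns one row per group: ``global`` plus, optionally, each vessel label
    present.  Rest and stress should be pooled separately by the caller.
    """
    if not pairs:
        raise ClassificationError("no classification pairs to pool")
    for a, b in pairs:
        _check_comparable(a, b)

    def pooled(sel_pairs, group_name):
        la = np.concatenate([a.labels for a, _ in sel_pairs])
        lb = np.concatenate([b.labels for _, b in sel_pairs])
        matched = int(np.sum(la == lb))
        return AgreementResult(
            dc=_dice_from_labels(la, lb, mode),
            n=la.size,
            matched=matched,
            mismatched=la.size - matched,
            n_abnormal_a=int(la.sum()),
            n_abnormal_b=int(lb.sum()),
            mode=mode,
            group=group_name,
        )

    results = [pooled(pairs, "global")]
    if by_territory:
        vessels = sorted({a.vessel for a, _ in pairs})
        for vessel in vessels:
            sel = [(a, b) for a, b in pairs if a.vessel == vessel]
            if sel:
                results.append(pooled(sel, vessel))
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "dc": [r.dc for r in results],
            "n_samples": [r.n for r in results],
            "matched": [r.matched for r in results],
            "mismatched": [r.mismatched for r in results],
            "n_abnormal_a": [r.n_abnormal_a for r in results],
            "n_abnormal_b": [r.n_abnormal_b for r in results],
            "mode": mode,
        }
    )


def compare_dc_groups(
    dc_a: Sequence[float], dc_b: Sequence[float], paired: bool = False
) -> TTestResult:
    """Two-sided Student's t test between two groups of per-vessel DC values.

    Paired when the same vessels underlie both groups; pooled-variance
    unpaired otherwise.  Zero-variance degeneracies are reported explicitly
    rather than as NaN: equal means give (t=0, p=1), unequal means are flagged.
    """
    a = np.asarray(dc_a, dtype=float)
    b = np.asarray(dc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ClassificationError("need at least 2 values per group")
    if paired and a.size != b.size:
        raise ClassificationError("paired comparison needs equal-length groups")

    if paired:
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                return TTestResult(t=0.0, p=1.0, paired=True, n_a=a.size, n_b=b.size)
            return TTestResult(
                t=np.inf if diff.mean() > 0 else -np.inf,
                p=0.0, paired=True, n_a=a.size, n_b=b.size, degenerate=True,
            )
        t, p = stats.ttest_rel(a, b)
        return TTestResult(t=float(t), p=float(p), paired=True, n_a=a.size, n_b=b.size)

    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.allclose(a.mean(), b.mean()):
            return TTestResult(t=0.0, p=1.0, paired=False, n_a=a.size, n_b=b.size)
        return TTestResult(
            t=np.inf if a.mean() > b.mean() else -np.inf,
            p=0.0, paired=False, n_a=a.size, n_b=b.size, degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), p=float(p), paired=False, n_a=a.size, n_b=b.size)
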