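"""Dissolution profiles and profile-comparison metrics.

A dissolution profile is the cumulative percentage of the drug dose released
into the medium as a function of time.  The sampling schedule used throughout
the package is the 37-point grid 2, 5, 10, 15, 30, 45, 60 min and then every
30 min up to 960 min (16 h).

Profiles are compared with the regulatory f2 similarity factor

    f2 = 50 * log10( 100 * [1 + (1/n) * sum_t w_t (R_t - T_t)^2]^(-1/2) )

where R is the reference (measured) and T the test (predicted) profile; f2 is
100 for identical profiles and >= 50 is the conventional "similar" threshold.
Before computing f2, points after the reference exceeds 85% release are
discarded except the first such point, so that the flat tail of the curve
does not inflate similarity.  RMSE and the coefficient of determination R²
are computed on the full, untruncated grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "dissolution_time_grid",
    "DissolutionProfile",
    "ProfilePair",
    "TooShortProfileError",
    "truncate_at_85",
    "f2",
    "rmse",
    "r_squared",
    "profile_metrics",
]


class TooShortProfileError(ValueError):
    """Raised when 85%-truncation leaves fewer than 3 points."""


def dissolution_time_grid() -> np.ndarray:
    """The fixed 37-point sampling schedule, in minutes."""
    early = np.array([2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0])
    late = np.arange(90.0, 961.0, 30.0)
    return np.concatenate([early, late])


N_TIME_POINTS = 37


@dataclass(frozen=True)
class DissolutionProfile:
    """(time, % released) pairs; times strictly increasing."""

    times: np.ndarray
    released: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.released, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("times and released must be equal-length 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "released", r)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "released_pct": self.released})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DissolutionProfile":
        frame = pd.read_csv(path)
        missing = {"time_min", "released_pct"} - set(frame.columns)
        if missing:
            raise ValueError(f"profile CSV missing columns {sorted(missing)}")
        return cls(frame["time_min"].to_numpy(), frame["released_pct"].to_numpy())


@dataclass(frozen=True)
class ProfilePair:
    """A reference (measured) and test (predicted) profile on one time grid."""

    reference: DissolutionProfile
    test: DissolutionProfile
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.reference.times.shape != self.test.times.shape or not np.allclose(
            self.reference.times, self.test.times
        ):
            raise ValueError("reference and test profiles must share one time grid")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != self.reference.times.shape:
                raise ValueError("weights must match the time grid")
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.reference)

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.n)
        return self.weights


def truncate_at_85(pair: ProfilePair, threshold: float = 85.0) -> ProfilePair:
    """Drop points after the reference exceeds ``threshold`` % release.

    All points where the reference is <= threshold are kept, plus the first
    point exceeding it; the rest are discarded.  Truncation is keyed to the
    reference (measured) profile, following regulatory practice.
    """
    ref = pair.reference.released
    over = np.nonzero(ref > threshold)[0]
    if over.size == 0:
        kept = np.arange(pair.n)
    else:
        kept = np.arange(over[0] + 1)
    if kept.size < 3:
        raise TooShortProfileError(
            f"only {kept.size} point(s) survive the {threshold}% truncation rule"
        )
    sub = lambda p: DissolutionProfile(p.times[kept], p.released[kept])  # noqa: E731
    w = None if pair.weights is None else pair.weights[kept]
    return ProfilePair(sub(pair.reference), sub(pair.test), w)


def f2(pair: ProfilePair) -> float:
    """The f2 similarity factor of an (already truncated) profile pair."""
    if pair.n < 3:
        raise TooShortProfileError("f2 requires at least 3 points")
    w = pair.effective_weights()
    diff = pair.reference.released - pair.test.released
    msd = float(np.mean(w * diff**2))
    return float(50.0 * np.log10(100.0 * (1.0 + msd) ** -0.5))


def f2_truncated(pair: ProfilePair) -> float:
    """Convenience: apply the 85% truncation rule, then compute f2."""
    return f2(truncate_at_85(pair))


def rmse(pair: ProfilePair) -> float:
    """Root mean squared error over the full (untruncated) grid, in %."""
    diff = pair.reference.released - pair.test.released
    return float(np.sqrt(np.mean(diff**2)))


def r_squared(pair: ProfilePair) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    SS_tot uses the variance of the reference (measured) profile about its
    mean; a reference with zero variance is degenerate.
    """
    ref = pair.reference.released
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference profile has zero variance; R² undefined")
    ss_res = float(np.sum((pair.test.released - ref) ** 2))
    return 1.0 - ss_res / ss_tot


def profile_metrics(pair: ProfilePair) -> dict[str, float]:
    """f2 (with truncation), RMSE and R² of one predicted-vs-measured pair."""
    return {
        "f2": f2_truncated(pair),
        "rmse": rmse(pair),
        "r_squared": r_squared(pair),
    }
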