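"""Closed-form read-density model for uniformly fragmented transcripts.

A transcript of length ``L`` is fragmented uniformly and a read of length
``J <= L`` is placed at one of the ``L - J + 1`` possible start positions,
each equally likely.  The probability that such a read overlaps position
``I`` (1-based) is

    p(I, J, L) = min(I, J, L - I + 1, L - J + 1) / (L - J + 1)

which is piecewise linear in ``I``: it climbs from the transcript ends,
plateaus in the middle, and is symmetric about the center.  Averaging these
curves over an observed read-length distribution gives the expected per-base
read density; comparing it with observed coverage via a coefficient of
determination quantifies how well unbiased fragmentation explains the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LengthDistribution",
    "DensityProfile",
    "overlap_probability",
    "overlap_probability_curve",
    "expected_density",
    "fit_r2",
    "coverage_report",
]


@dataclass
class LengthDistribution:
    """Observed read lengths with frequency weights."""

    lengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.lengths.shape != self.weights.shape:
            raise ValueError("lengths and weights must have equal shape")
        if self.lengths.size == 0:
            raise ValueError("empty length distribution")
        if np.any(self.weights < 0) or not np.sum(self.weights) > 0:
            raise ValueError("weights must be >= 0 with positive sum")
        if np.any(self.lengths < 1):
            raise ValueError("read lengths must be >= 1")

    @classmethod
    def from_lengths(cls, observed: "np.ndarray | list[int]") -> "LengthDistribution":
        """Tabulate a raw list of observed read lengths into (length, weight)."""
        lengths, counts = np.unique(np.asarray(observed, dtype=np.int64), return_counts=True)
        return cls(lengths, counts.astype(np.float64))

    @property
    def mean(self) -> float:
        return float(np.average(self.lengths, weights=self.weights))


@dataclass
class DensityProfile:
    """Observed coverage and model-expected density for one transcript unit."""

    name: str
    length: int
    observed: np.ndarray
    expected: np.ndarray | None = None
    r2: float | None = None
    r2_missing_reason: str | None = None
    exons: list[tuple[int, int]] | None = field(default=None)


def overlap_probability(I: int, J: int, L: int) -> float:  # noqa: E741
    """Probability that a read of length ``J`` overlaps position ``I`` of an
    ``L``-base transcript under uniform placement.

    ``I`` is 1-based.  Reads longer than the transcript are a domain error
    here (cap them before calling, see :func:`expected_density`).
    """
    if not 1 <= I <= L:
        raise ValueError(f"position I={I} outside transcript 1..{L}")
    if not 1 <= J <= L:
        raise ValueError(f"read length J={J} outside 1..{L}")
    return min(I, J, L - I + 1, L - J + 1) / (L - J + 1)


def overlap_probability_curve(J: int, L: int) -> np.ndarray:  # noqa: N803
    """Vectorized p(I, J, L) for I = 1..L."""
    if not 1 <= J <= L:
        raise ValueError(f"read length J={J} outside 1..{L}")
    I = np.arange(1, L + 1)  # noqa: E741
    return np.minimum.reduce([I, np.full(L, J), L - I + 1, np.full(L, L - J + 1)]) / (L - J + 1)


def expected_density(L: int, lengths: LengthDistribution) -> np.ndarray:  # noqa: N803
    """Per-base expected read density: the weighted average of the
    single-length overlap curves over the read-length distribution.

    Lengths exceeding ``L`` are capped at ``L`` (a read longer than the
    transcript covers all of it).
    """
    if L < 1:
        raise ValueError("transcript length must be >= 1")
    capped = np.minimum(lengths.lengths, L)
    w = lengths.weights / lengths.weights.sum()
    # collapse duplicate capped lengths before summing curves
    uniq, inv = np.unique(capped, return_inverse=True)
    agg = np.zeros(uniq.size)
    np.add.at(agg, inv, w)
    out = np.zeros(L)
    for j, wj in zip(uniq, agg):
        out += wj * overlap_probability_curve(int(j), L)
    return out


def fit_r2(observed: np.ndarray, expected: np.ndarray) -> tuple[float | None, str | None]:
    """Coefficient of determination between observed coverage counts and the
    model-expected density.

    The unitless expected density is put on the observed scale by matching
    totals (expected counts = density * sum(observed) / sum(density)), then
    R^2 = 1 - SS_res / SS_tot over positions.  R^2 may be negative when the
    model underperforms the positional mean; it is reported as computed.

    Returns ``(r2, None)`` or ``(None, reason)`` when undefined.
    """
    obs = np.asarray(observed, dtype=np.float64)
    exp = np.asarray(expected, dtype=np.float64)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    total = obs.sum()
    if not total > 0:
        raise ValueError("observed coverage total must be > 0")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        return None, "zero observed variance"
    scaled = exp * (total / exp.sum())
    ss_res = np.sum((obs - scaled) ** 2)
    return float(1.0 - ss_res / ss_tot), None


def _coverage_from_placements(length: int, placements: "list[tuple[int, int]]") -> np.ndarray:
    """Per-base coverage from 1-based inclusive (start, end) read placements,
    via a difference array."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for start, end in placements:
        if start < 1 or end > length or end < start:
            raise ValueError(f"placement ({start},{end}) outside 1..{length}")
        diff[start - 1] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1])


def coverage_report(
    name: str,
    length: int,
    placements: "list[tuple[int, int]]",
    lengths: LengthDistribution | None = None,
    exons: "list[tuple[int, int]] | None" = None,
) -> DensityProfile:
    """Build a :class:`DensityProfile` from read placements on one transcript
    unit (or genomic interval).

    ``placements`` are 1-based inclusive (start, end) coordinates.  When a
    read-length distribution is supplied the model-expected density and R^2
    are attached; when ``exons`` is given the profile is interpreted as a
    genomic-coordinate view with exon intervals annotated.
    """
    observed = _coverage_from_placements(length, placements)
    profile = DensityProfile(name=name, length=length, observed=observed, exons=exons)
    if lengths is not None:
        profile.expected = expected_density(length, lengths)
        if observed.sum() > 0:
            profile.r2, profile.r2_missing_reason = fit_r2(observed, profile.expected)
        else:
            profile.r2, profile.r2_missing_reason = None, "no observed coverage"
    return profile


def profile_table(profile: DensityProfile):
    """Profile as a pandas DataFrame (position, observed, expected)."""
    import pandas as pd

    data = {"position": np.arange(1, profile.length + 1), "observed": profile.observed}
    if profile.expected is not None:
        data["expected"] = profile.expected
    return pd.DataFrame(data)


def plot_profile(profile: DensityProfile, ax=None):
    """Plot observed coverage against the model-expected curve.

    Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(1, profile.length + 1)
    total = profile.observed.sum()
    ax.plot(x, profile.observed, color="black", lw=0.8, label="observed")
    if profile.expected is not None and total > 0:
        scale = total / profile.expected.sum()
        ax.plot(x, profile.expected * scale, color="tab:blue", lw=1.2, label="model")
    ax.set_xlabel("position (bases)")
    ax.set_ylabel("read coverage")
    title = profile.name
    if profile.r2 is not None:
        title += f"  (R²={profile.r2:.2f})"
    ax.set_title(title)
    ax.legend(frameon=False)
    return ax
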