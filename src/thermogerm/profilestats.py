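"""Optimal-regime classification and germination profile statistics.

A regime is *optimal* when its mean germination is not lower than the
profile maximum minus one half confidence-interval width (P = 0.05).  The
profile statistics summarise a 36-regime matrix: overall mean, share of
regimes with any germination, the maximum, the mean over non-zero regimes,
the mean over optimal regimes, and the share of optimal regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .germdata import GerminationMatrix, TemperatureRegime, round_half_up

__all__ = ["ProfileSummary", "classify_optimal", "summarize", "intersect_optimal"]

_DESIGN_SIZE = 36  # denominator for regime-share statistics
_EPS = 1e-9


@dataclass(frozen=True)
class ProfileSummary:
    """The six profile statistics of a germination matrix, reported to one
    decimal, plus the optimal-regime set used."""

    profile_mean: float
    regimes_with_some_germination: float
    maximum_germination: float
    mean_of_some_germination: float
    mean_of_optima: float
    regimes_with_optimum: float
    optimal_set: frozenset[TemperatureRegime]

    def summary(self) -> str:
        rows = [
            ("Profile mean", self.profile_mean),
            ("Regimes with some germination", self.regimes_with_some_germination),
            ("Maximum germination", self.maximum_germination),
            ("Mean of some germination", self.mean_of_some_germination),
            ("Mean of optima", self.mean_of_optima),
            ("Regimes with optimum germination", self.regimes_with_optimum),
        ]
        width = max(len(n) for n, _ in rows)
        return "\n".join(f"{n:<{width}}  {v:>6.1f}" for n, v in rows)


def classify_optimal(matrix: GerminationMatrix, rule: str = "own_ci"):
    """Regimes classified optimal under the half-CI rule.

    ``own_ci`` (default): regime r is optimal iff mean(r) >= max - half_ci(r),
    using each cell's own half-CI.  ``max_ci`` uses the maximum cell's half-CI
    for every comparison.  The maximum regime(s) always qualify.
    """
    if rule not in ("own_ci", "max_ci"):
        raise ValueError(f"unknown classification rule {rule!r}")
    max_mean = matrix.max_mean
    if rule == "max_ci":
        max_hci = min(matrix.half_ci(r) for r in matrix.max_regimes)
    out = set()
    for r in matrix.regimes:
        hci = matrix.half_ci(r) if rule == "own_ci" else max_hci
        if matrix.mean_percent(r) >= max_mean - hci - _EPS:
            out.add(r)
    out.update(matrix.max_regimes)
    return frozenset(out)


def summarize(matrix: GerminationMatrix, optimal_set=None) -> ProfileSummary:
    """Profile statistics for a matrix.

    ``optimal_set`` defaults to the matrix's transcribed flags when present,
    otherwise the ``own_ci`` rule.  Percent-of-regimes statistics use the
    design size (36) as denominator; means are computed on the unrounded
    cell values and reported rounded half-up to one decimal.
    """
    if not matrix.cells:
        raise ValueError("empty matrix")
    if optimal_set is None:
        optimal_set = matrix.flags if matrix.flags else classify_optimal(matrix)
    optimal_set = frozenset(optimal_set)
    unknown = optimal_set - set(matrix.cells)
    if unknown:
        raise ValueError(f"optimal_set contains regimes not in matrix: {sorted(unknown)}")

    means = [matrix.mean_percent(r) for r in matrix.regimes]
    nonzero = [m for m in means if m > 0.0]
    optima = [matrix.mean_percent(r) for r in sorted(optimal_set)]
    return ProfileSummary(
        profile_mean=round_half_up(sum(means) / len(means)),
        regimes_with_some_germination=round_half_up(100.0 * len(nonzero) / _DESIGN_SIZE),
        maximum_germination=round_half_up(max(means)),
        mean_of_some_germination=round_half_up(
            sum(nonzero) / len(nonzero) if nonzero else 0.0
        ),
        mean_of_optima=round_half_up(sum(optima) / len(optima) if optima else 0.0),
        regimes_with_optimum=round_half_up(100.0 * len(optimal_set) / _DESIGN_SIZE),
        optimal_set=optimal_set,
    )


def intersect_optimal(flag_sets) -> frozenset[TemperatureRegime]:
    """Regimes optimal for every cultivar (set intersection)."""
    flag_sets = list(flag_sets)
    if not flag_sets:
        raise ValueError("need at least one flag set")
    out = frozenset(flag_sets[0])
    for s in flag_sets[1:]:
        out &= frozenset(s)
    return out
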