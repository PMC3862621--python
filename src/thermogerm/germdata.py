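"""Data model for diurnal temperature-regime germination experiments.

A *diurnal temperature regime* alternates 16 h at a cool temperature with
8 h at a warm temperature.  The experimental design crosses 8 temperature
levels (5–40 °C in 5 °C steps) over the triangle cool ≤ warm, giving 36
regimes.  Each regime is observed as replicate counts of germinated seeds
(by default 3 replicates of 50 seeds), summarised as a mean germination
percentage with a half confidence-interval width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DESIGN_LEVELS",
    "TemperatureRegime",
    "ReplicateRecord",
    "GerminationMatrix",
    "design_regimes",
    "read_replicates",
    "percent_mean",
    "half_ci",
    "build_matrix",
    "write_matrix",
    "read_matrix",
    "round_half_up",
]

#: temperature levels of the factorial design, °C
DESIGN_LEVELS: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table-parity rounding, e.g. 87.35 -> 87.4)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True, order=True)
class TemperatureRegime:
    """A cool(16 h)/warm(8 h) alternating temperature schedule, °C."""

    cool_temp: float
    warm_temp: float

    def __post_init__(self) -> None:
        if self.cool_temp > self.warm_temp:
            raise ValueError(
                f"regime requires cool_temp <= warm_temp, got "
                f"({self.cool_temp}, {self.warm_temp})"
            )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.cool_temp:g}/{self.warm_temp:g}°C"


def design_regimes() -> list[TemperatureRegime]:
    """The 36 design regimes, row-major in (cool, warm)."""
    return [
        TemperatureRegime(c, w)
        for c in DESIGN_LEVELS
        for w in DESIGN_LEVELS
        if c <= w
    ]


@dataclass(frozen=True)
class ReplicateRecord:
    """Germinated-seed counts for one regime across replicates."""

    regime: TemperatureRegime
    germinated: tuple[int, ...]
    seeds_per_replicate: int = 50
    cultivar: str | None = None

    def __post_init__(self) -> None:
        if self.seeds_per_replicate <= 0:
            raise ValueError("seeds_per_replicate must be positive")
        for g in self.germinated:
            if not 0 <= g <= self.seeds_per_replicate:
                raise ValueError(
                    f"germinated count {g} outside [0, {self.seeds_per_replicate}] "
                    f"for regime {self.regime}"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.germinated)

    @property
    def replicate_percentages(self) -> np.ndarray:
        return 100.0 * np.asarray(self.germinated, dtype=float) / self.seeds_per_replicate


def percent_mean(record: ReplicateRecord) -> float:
    """Pooled mean germination percentage, 100 * Σgerminated / (n * seeds)."""
    total_seeds = record.n_replicates * record.seeds_per_replicate
    if total_seeds == 0:
        raise ValueError("record has no seeds")
    return 100.0 * sum(record.germinated) / total_seeds


def half_ci(record: ReplicateRecord, alpha: float = 0.05) -> float:
    """Half-width of the t confidence interval on the replicate percentages.

    t_{1-alpha/2, n-1} * SD / sqrt(n) with the sample (ddof=1) standard
    deviation of the per-replicate percentages.
    """
    n = record.n_replicates
    if n < 2:
        raise ValueError("need at least 2 replicates for a variance estimate")
    sd = float(np.std(record.replicate_percentages, ddof=1))
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    return tq * sd / math.sqrt(n)


@dataclass(frozen=True)
class _Cell:
    mean_percent: float
    half_ci: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_percent <= 100.0:
            raise ValueError(f"mean_percent {self.mean_percent} outside [0, 100]")
        if self.half_ci < 0.0:
            raise ValueError(f"half_ci {self.half_ci} is negative")


@dataclass
class GerminationMatrix:
    """Per-cultivar table of mean germination % and half-CI over the 36 regimes.

    ``flags`` is the set of regimes marked optimal (from transcription or from
    a classification rule); ``max_regime`` is the canonical regime attaining
    the maximum mean (smallest (cool, warm) row-major on ties).
    """

    cultivar: str
    cells: dict[TemperatureRegime, _Cell]
    flags: frozenset[TemperatureRegime] = frozenset()
    max_regime: TemperatureRegime | None = None

    Cell = _Cell

    def __post_init__(self) -> None:
        if self.max_regime is None and self.cells:
            self.max_regime = self._argmax()

    def _argmax(self) -> TemperatureRegime:
        best = max(self.cells.values(), key=lambda c: c.mean_percent).mean_percent
        return min(r for r, c in self.cells.items() if c.mean_percent == best)

    @property
    def regimes(self) -> list[TemperatureRegime]:
        return sorted(self.cells)

    def mean_percent(self, regime: TemperatureRegime) -> float:
        return self.cells[regime].mean_percent

    def half_ci(self, regime: TemperatureRegime) -> float:
        return self.cells[regime].half_ci

    @property
    def max_mean(self) -> float:
        return max(c.mean_percent for c in self.cells.values())

    @property
    def max_regimes(self) -> list[TemperatureRegime]:
        """All regimes attaining the maximum mean (ties retained)."""
        m = self.max_mean
        return sorted(r for r, c in self.cells.items() if c.mean_percent == m)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cool, warm, mean_fraction) arrays in sorted regime order."""
        rs = self.regimes
        cool = np.array([r.cool_temp for r in rs])
        warm = np.array([r.warm_temp for r in rs])
        frac = np.array([self.cells[r].mean_percent for r in rs]) / 100.0
        return cool, warm, frac

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.regimes:
            c = self.cells[r]
            rows.append(
                {
                    "cultivar": self.cultivar,
                    "cool_temp": r.cool_temp,
                    "warm_temp": r.warm_temp,
                    "mean_percent": c.mean_percent,
                    "half_ci": c.half_ci,
                    "optimal_flag": int(r in self.flags),
                    "is_max": int(c.mean_percent == self.max_mean),
                }
            )
        return pd.DataFrame(rows)

    def with_flags(self, flags) -> "GerminationMatrix":
        return replace(self, flags=frozenset(flags))


_REPLICATE_COLUMNS = ["cultivar", "cool_temp", "warm_temp", "replicate", "germinated", "seeds"]


def read_replicates(path, cultivar: str | None = None) -> list[ReplicateRecord]:
    """Read a replicate-level CSV into one :class:`ReplicateRecord` per regime.

    Expects columns ``cultivar,cool_temp,warm_temp,replicate,germinated,seeds``;
    rejects duplicate (regime, replicate) keys and germinated > seeds.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REPLICATE_COLUMNS if c not in df.columns]
    if len(df) == 0 and missing:
        return []
    if missing:
        raise ValueError(f"replicate file {path} missing columns {missing}")
    if cultivar is not None:
        df = df[df["cultivar"] == cultivar]
    if df.empty:
        return []
    cultivars = df["cultivar"].unique()
    if len(cultivars) > 1:
        raise ValueError(
            f"multiple cultivars in {path} ({list(cultivars)}); pass cultivar="
        )
    for col in ("cool_temp", "warm_temp", "germinated", "seeds", "replicate"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            # +2: header line and 1-based numbering
            line = int(bad.index[0]) + 2
            raise ValueError(f"malformed value in column {col!r} at line {line}")
    dup = df.duplicated(subset=["cool_temp", "warm_temp", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate replicate {int(row['replicate'])} for regime "
            f"({row['cool_temp']}, {row['warm_temp']})"
        )
    over = df[df["germinated"] > df["seeds"]]
    if not over.empty:
        line = int(over.index[0]) + 2
        raise ValueError(f"germinated exceeds seeds at line {line}")

    records = []
    for (cool, warm), grp in df.groupby(["cool_temp", "warm_temp"], sort=True):
        grp = grp.sort_values("replicate")
        seeds = grp["seeds"].unique()
        if len(seeds) > 1:
            raise ValueError(
                f"inconsistent seeds-per-replicate for regime ({cool}, {warm})"
            )
        records.append(
            ReplicateRecord(
                regime=TemperatureRegime(float(cool), float(warm)),
                germinated=tuple(int(g) for g in grp["germinated"]),
                seeds_per_replicate=int(seeds[0]),
                cultivar=str(cultivars[0]),
            )
        )
    return records


def _regression_se_half_ci(records, alpha: float) -> dict[TemperatureRegime, float]:
    """Half-CIs from the prediction standard error of a quadratic surface fit
    to replicate-level percentages (alternative to the replicate t-interval)."""
    import statsmodels.api as sm

    from .surface import build_basis

    rows, y = [], []
    for rec in records:
        for p in rec.replicate_percentages:
            rows.append(build_basis(rec.regime.cool_temp, rec.regime.warm_temp, degree=2))
            y.append(p)
    res = sm.OLS(np.asarray(y), np.vstack(rows)).fit()
    out = {}
    for rec in records:
        x = build_basis(rec.regime.cool_temp, rec.regime.warm_temp, degree=2)
        pred = res.get_prediction(x.reshape(1, -1))
        se = float(pred.se_mean[0])
        tq = float(stats.t.ppf(1.0 - alpha / 2.0, df=res.df_resid))
        out[rec.regime] = tq * se
    return out


def build_matrix(
    records: list[ReplicateRecord],
    cultivar: str,
    alpha: float = 0.05,
    ci_method: str = "t_replicate",
) -> GerminationMatrix:
    """Aggregate replicate records into a :class:`GerminationMatrix`.

    Requires exactly one record per design regime (the full cool ≤ warm
    triangle).  ``ci_method`` is ``t_replicate`` (default, per-regime t
    interval) or ``regression_se`` (prediction SE of a quadratic surface).
    """
    if ci_method not in ("t_replicate", "regression_se"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    seen: dict[TemperatureRegime, ReplicateRecord] = {}
    dups = []
    for rec in records:
        if rec.regime in seen:
            dups.append(rec.regime)
        seen[rec.regime] = rec
    if dups:
        raise ValueError(f"duplicate regimes: {sorted(set(dups))}")
    expected = set(design_regimes())
    missing = expected - set(seen)
    extra = set(seen) - expected
    if missing or extra:
        msg = []
        if missing:
            msg.append(f"missing regimes: {sorted(missing)}")
        if extra:
            msg.append(f"unexpected regimes: {sorted(extra)}")
        raise ValueError("; ".join(msg))

    if ci_method == "regression_se":
        hcis = _regression_se_half_ci(records, alpha)
    else:
        hcis = {rec.regime: half_ci(rec, alpha) for rec in records}
    cells = {
        rec.regime: _Cell(percent_mean(rec), hcis[rec.regime]) for rec in records
    }
    return GerminationMatrix(cultivar=cultivar, cells=cells)


def write_matrix(matrix: GerminationMatrix, path) -> None:
    """Write a matrix CSV; floats use repr so a round-trip is bit-exact."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cultivar,cool_temp,warm_temp,mean_percent,half_ci,optimal_flag,is_max\n")
        max_mean = matrix.max_mean
        for r in matrix.regimes:
            c = matrix.cells[r]
            fh.write(
                f"{matrix.cultivar},{r.cool_temp!r},{r.warm_temp!r},"
                f"{c.mean_percent!r},{c.half_ci!r},"
                f"{int(r in matrix.flags)},{int(c.mean_percent == max_mean)}\n"
            )


def read_matrix(path) -> GerminationMatrix:
    """Read a matrix CSV written by :func:`write_matrix` (or transcribed)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cultivar", "cool_temp", "warm_temp", "mean_percent", "half_ci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"matrix file {path} missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"matrix file {path} is empty")
    cultivars = df["cultivar"].unique()
    if len(cultivars) != 1:
        raise ValueError(f"matrix file must hold one cultivar, got {list(cultivars)}")
    cells, flags = {}, set()
    for _, row in df.iterrows():
        regime = TemperatureRegime(float(row["cool_temp"]), float(row["warm_temp"]))
        if regime in cells:
            raise ValueError(f"duplicate regime {regime} in {path}")
        cells[regime] = _Cell(float(row["mean_percent"]), float(row["half_ci"]))
        if "optimal_flag" in df.columns and int(row["optimal_flag"]):
            flags.add(regime)
    return GerminationMatrix(
        cultivar=str(cultivars[0]), cells=cells, flags=frozenset(flags)
    )
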