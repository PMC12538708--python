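"""Taguchi L18 analysis: S/N ratios, response tables, ANOVA, optimal levels.

The spreading device is screened with an L18 orthogonal array over six
factors (one 2-level, five 3-level): seed-socket arrangement, spreading
roller speed, conveyor motor speed, seed-box inclination, drop-chute
inclination and conveyor belt type. The per-run response is Moran's I of
the resulting seed layouts; uniformity means I close to zero, so the
smaller-the-better signal-to-noise ratio

    S/N = -10 * log10( (1/m) * sum_i Y_i^2 )   [dB]

is used: larger S/N means responses nearer zero and more stable.

The analysis follows standard response-table / ANOVA practice for
orthogonal arrays: per-factor level means (of run means) and level S/N
(of per-run S/N), delta = max - min with dense ranks, per-factor sums of
squares SS_f = sum_v n_v (ybar_v - Ybar)^2 with n_v runs per level
(9 for the 2-level factor, 6 for 3-level factors in L18), residual error
by subtraction with DOF_err = 17 - 11 = 6, and F/P against the residual
mean square.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaguchiDesign",
    "TaguchiRunSet",
    "ResponseTable",
    "FactorSS",
    "AnovaTable",
    "l18_design",
    "sn_smaller_better",
    "response_table",
    "anova_from_levels",
    "anova",
    "optimal_levels",
]


@dataclass(frozen=True)
class TaguchiDesign:
    """An orthogonal-array design: ordered factors with level labels and
    the runs-by-factors matrix of 0-based level indices.

    Balance (each level of each factor occurring equally often) is
    enforced at construction; it is what makes level means independent
    contrasts.
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    runs: np.ndarray = field(repr=False)

    def __post_init__(self):
        runs = np.asarray(self.runs, dtype=int)
        object.__setattr__(self, "runs", runs)
        if runs.ndim != 2 or runs.shape[1] != len(self.factors):
            raise ValueError("runs matrix shape does not match factor list")
        for j, (name, levels) in enumerate(self.factors):
            col = runs[:, j]
            if col.min() < 0 or col.max() >= len(levels):
                raise ValueError(f"factor {name!r}: level index out of range")
            counts = np.bincount(col, minlength=len(levels))
            if len(set(counts.tolist())) != 1:
                raise ValueError(f"factor {name!r}: design is not balanced ({counts})")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def levels(self, factor: str) -> tuple[str, ...]:
        for name, levels in self.factors:
            if name == factor:
                return levels
        raise KeyError(factor)

    def occurrences(self, factor: str) -> int:
        """Runs per level of this factor (9 or 6 in L18)."""
        return self.n_runs // len(self.levels(factor))

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i in range(self.n_runs):
            row = {"run": i + 1}
            for j, (name, levels) in enumerate(self.factors):
                row[name] = levels[self.runs[i, j]]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaguchiDesign":
        """Read a design matrix CSV (a ``run`` column plus one labelled
        column per factor); level order follows first appearance."""
        df = pd.read_csv(path, dtype=str)
        names = [c for c in df.columns if c != "run"]
        factors = []
        runs = np.empty((len(df), len(names)), dtype=int)
        for j, name in enumerate(names):
            col = df[name].tolist()
            levels = tuple(dict.fromkeys(col))
            index = {lab: k for k, lab in enumerate(levels)}
            runs[:, j] = [index[v] for v in col]
            factors.append((name, levels))
        return cls(factors=tuple(factors), runs=runs)


_L18_FACTORS = (
    ("socket_arrangement", ("deflection", "non_deflection")),
    ("roller_speed", ("50", "150", "250")),
    ("motor_speed", ("50", "150", "250")),
    ("box_incline_deg", ("20", "30", "40")),
    ("chute_incline_deg", ("60", "70", "80")),
    ("belt_type", ("1", "2", "3")),
)

_L18_RUNS = np.array(
    [
        [0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 1, 1],
        [0, 0, 2, 2, 2, 2],
        [0, 1, 0, 0, 1, 1],
        [0, 1, 1, 1, 2, 2],
        [0, 1, 2, 2, 0, 0],
        [0, 2, 0, 1, 0, 2],
        [0, 2, 1, 2, 1, 0],
        [0, 2, 2, 0, 2, 1],
        [1, 0, 0, 2, 2, 1],
        [1, 0, 1, 0, 0, 2],
        [1, 0, 2, 1, 1, 0],
        [1, 1, 0, 1, 2, 0],
        [1, 1, 1, 2, 0, 1],
        [1, 1, 2, 0, 1, 2],
        [1, 2, 0, 2, 1, 2],
        [1, 2, 1, 0, 2, 0],
        [1, 2, 2, 1, 0, 1],
    ]
)


def l18_design() -> TaguchiDesign:
    """The packaged L18 design for the six spreading-device factors."""
    return TaguchiDesign(factors=_L18_FACTORS, runs=_L18_RUNS.copy())


@dataclass(frozen=True)
class TaguchiRunSet:
    """A design plus per-run replicate response observations.

    ``observations[i]`` holds the m_i replicate responses of run i
    (here: per-image Moran's I values, or their per-group means).
    """

    design: TaguchiDesign
    observations: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        if len(self.observations) != self.design.n_runs:
            raise ValueError("one observation list per design run is required")
        if any(len(obs) == 0 for obs in self.observations):
            raise ValueError("every run needs at least one observation")
        object.__setattr__(
            self, "observations", tuple(tuple(float(y) for y in obs) for obs in self.observations)
        )

    def run_means(self) -> np.ndarray:
        return np.array([float(np.mean(obs)) for obs in self.observations])

    def run_sn(self) -> np.ndarray:
        return np.array([sn_smaller_better(obs) for obs in self.observations])

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"run": i + 1, "replicate": j + 1, "response": y}
            for i, obs in enumerate(self.observations)
            for j, y in enumerate(obs)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, design: TaguchiDesign, path: str | Path) -> "TaguchiRunSet":
        df = pd.read_csv(path)
        obs = [
            tuple(df.loc[df["run"] == i + 1, "response"].astype(float))
            for i in range(design.n_runs)
        ]
        return cls(design=design, observations=tuple(obs))


def sn_smaller_better(observations) -> float:
    """Smaller-the-better S/N ratio in dB: -10*log10(mean of Y^2).

    All-zero observations give a mean square of 0 and hence +inf dB
    (a perfectly-on-target, perfectly stable response), reported as
    ``math.inf`` rather than raising.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.size == 0:
        raise ValueError("at least one observation is required")
    msq = float(np.mean(obs**2))
    if msq == 0.0:
        return math.inf
    return -10.0 * math.log10(msq)


def _dense_ranks_desc(deltas: np.ndarray) -> np.ndarray:
    """Dense ranks on descending delta; ties share the smaller rank."""
    order = np.unique(deltas)[::-1]
    rank_of = {d: r + 1 for r, d in enumerate(order)}
    return np.array([rank_of[d] for d in deltas], dtype=int)


@dataclass(frozen=True)
class ResponseTable:
    """Per-factor level means and level S/N with deltas and ranks.

    ``level_means[f][v]`` is the mean of run means over runs with factor
    f at level v; ``level_sn`` analogously averages per-run S/N.
    ``occurrences[f]`` is the number of runs per level. Grand values are
    the plain means over all runs.
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    level_means: dict
    level_sn: dict
    occurrences: dict
    grand_mean: float
    grand_sn: float

    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def delta(self, which: str) -> dict:
        table = self.level_means if which == "mean" else self.level_sn
        return {f: float(np.max(table[f]) - np.min(table[f])) for f in self.factor_names()}

    def ranks(self, which: str) -> dict:
        names = self.factor_names()
        deltas = np.array([self.delta(which)[f] for f in names])
        ranks = _dense_ranks_desc(deltas)
        return dict(zip(names, ranks.tolist()))

    def to_csv(self, path: str | Path) -> None:
        rows = []
        rk_mean, rk_sn = self.ranks("mean"), self.ranks("sn")
        d_mean, d_sn = self.delta("mean"), self.delta("sn")
        for name, levels in self.factors:
            for v, label in enumerate(levels):
                rows.append(
                    {
                        "factor": name,
                        "level": label,
                        "mean": self.level_means[name][v],
                        "sn_db": self.level_sn[name][v],
                        "delta_mean": d_mean[name],
                        "delta_sn": d_sn[name],
                        "rank_mean": rk_mean[name],
                        "rank_sn": rk_sn[name],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_level_stats(cls, factors, level_means, level_sn, occurrences) -> "ResponseTable":
        """Build a table directly from per-level summaries (e.g. a
        published response summary), without run-level data.

        The grand values are the occurrence-weighted averages of the
        level summaries (identical across factors up to rounding of the
        inputs; the average over factors is used).
        """
        factors = tuple((name, tuple(levels)) for name, levels in factors)
        lm = {f: np.asarray(level_means[f], dtype=float) for f, _ in factors}
        ls = {f: np.asarray(level_sn[f], dtype=float) for f, _ in factors}
        occ = {f: int(occurrences[f]) for f, _ in factors}
        grand_mean = float(np.mean([np.mean(lm[f]) for f, _ in factors]))
        grand_sn = float(np.mean([np.mean(ls[f]) for f, _ in factors]))
        return cls(factors, lm, ls, occ, grand_mean, grand_sn)


def response_table(runset: TaguchiRunSet) -> ResponseTable:
    """Compute the response table (level means, level S/N, deltas, ranks)."""
    design = runset.design
    run_means = runset.run_means()
    run_sn = runset.run_sn()
    level_means: dict = {}
    level_sn: dict = {}
    occurrences: dict = {}
    for j, (name, levels) in enumerate(design.factors):
        col = design.runs[:, j]
        level_means[name] = np.array(
            [float(run_means[col == v].mean()) for v in range(len(levels))]
        )
        level_sn[name] = np.array(
            [float(run_sn[col == v].mean()) for v in range(len(levels))]
        )
        occurrences[name] = design.occurrences(name)
    return ResponseTable(
        factors=design.factors,
        level_means=level_means,
        level_sn=level_sn,
        occurrences=occurrences,
        grand_mean=float(run_means.mean()),
        grand_sn=float(run_sn.mean()),
    )


@dataclass(frozen=True)
class FactorSS:
    """One factor's ANOVA decomposition entries."""

    ss: float
    dof: int
    ms: float


def anova_from_levels(level_means, occurrences, grand_mean: float) -> FactorSS:
    """Per-factor sum of squares from level summaries.

    SS_f = sum_v n_v (ybar_v - Ybar)^2, DOF = l - 1, MS = SS/DOF, where
    n_v is the number of runs at level v (constant within a balanced
    design) and Ybar the grand mean of the response.

    ``occurrences`` may be a scalar (runs per level) or a per-level
    sequence; a per-level sequence must be constant, matching a balanced
    design.
    """
    means = np.asarray(level_means, dtype=float)
    if means.size < 2:
        raise ValueError("a factor needs at least two levels")
    occ = np.asarray(occurrences, dtype=float)
    if occ.ndim == 0:
        occ = np.full(means.size, float(occ))
    if occ.size != means.size:
        raise ValueError("occurrence count does not match the number of levels")
    if np.any(occ <= 0) or len(set(occ.tolist())) != 1:
        raise ValueError("occurrences must be positive and equal across levels (balanced design)")
    ss = float(np.sum(occ * (means - grand_mean) ** 2))
    dof = means.size - 1
    return FactorSS(ss=ss, dof=dof, ms=ss / dof)


@dataclass(frozen=True)
class AnovaTable:
    """Per-factor SS/DOF/MS/F/P plus the residual-error row and total SS.

    The error term is the residual of the run-level decomposition:
    SS_err = total SS - sum of factor SS (floored at zero),
    DOF_err = (runs - 1) - sum of factor DOF. F compares each factor MS
    to the residual MS; P is the upper tail of F(DOF_factor, DOF_err).
    """

    response: str
    factors: tuple[str, ...]
    ss: dict
    dof: dict
    ms: dict
    f: dict
    p: dict
    ss_err: float
    dof_err: int
    ms_err: float
    total_ss: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": name,
                "dof": self.dof[name],
                "seq_ss": self.ss[name],
                "adj_ms": self.ms[name],
                "f": self.f[name],
                "p": self.p[name],
            }
            for name in self.factors
        ]
        rows.append(
            {
                "source": "error",
                "dof": self.dof_err,
                "seq_ss": self.ss_err,
                "adj_ms": self.ms_err,
                "f": float("nan"),
                "p": float("nan"),
            }
        )
        rows.append(
            {
                "source": "total",
                "dof": sum(self.dof.values()) + self.dof_err,
                "seq_ss": self.total_ss,
                "adj_ms": float("nan"),
                "f": float("nan"),
                "p": float("nan"),
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def anova(runset: TaguchiRunSet, response: str = "mean") -> AnovaTable:
    """ANOVA of the run-level response (``"mean"`` or ``"sn"``).

    The response enters at one value per run (the run mean, or the
    per-run S/N); replicate scatter within a run is summarised before
    the decomposition, as in standard Taguchi practice.
    """
    if response not in ("mean", "sn"):
        raise ValueError("response must be 'mean' or 'sn'")
    design = runset.design
    y = runset.run_means() if response == "mean" else runset.run_sn()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite run responses (all-zero run with S/N response?)")
    grand = float(y.mean())
    total_ss = float(np.sum((y - grand) ** 2))
    ss: dict = {}
    dof: dict = {}
    ms: dict = {}
    for j, (name, levels) in enumerate(design.factors):
        col = design.runs[:, j]
        level_means = [float(y[col == v].mean()) for v in range(len(levels))]
        fss = anova_from_levels(level_means, design.occurrences(name), grand)
        ss[name], dof[name], ms[name] = fss.ss, fss.dof, fss.ms
    dof_err = (design.n_runs - 1) - sum(dof.values())
    if dof_err <= 0:
        raise ValueError("no residual degrees of freedom for the error term")
    ss_err = max(total_ss - sum(ss.values()), 0.0)
    ms_err = ss_err / dof_err
    f: dict = {}
    p: dict = {}
    for name in ss:
        if ms_err == 0.0:
            f[name] = math.inf
            p[name] = 0.0
        else:
            f[name] = ms[name] / ms_err
            p[name] = float(stats.f.sf(f[name], dof[name], dof_err))
    return AnovaTable(
        response=response,
        factors=design.factor_names(),
        ss=ss,
        dof=dof,
        ms=ms,
        f=f,
        p=p,
        ss_err=ss_err,
        dof_err=dof_err,
        ms_err=ms_err,
        total_ss=total_ss,
    )


def optimal_levels(
    rt: ResponseTable, mean_rule: str = "closest_to_zero", sn_rule: str = "maximize"
) -> dict:
    """Rule-based optimal level per factor.

    The mean rule picks the level whose mean response is closest to zero
    (spatial randomness, i.e. the most uniform spreading); the S/N rule
    picks the level with the highest S/N (the most stable). Ties go to
    the lowest level index and are flagged.

    Returns ``{factor: {"level_by_mean": label, "level_by_sn": label,
    "tie_mean": bool, "tie_sn": bool}}``.
    """
    if mean_rule != "closest_to_zero":
        raise ValueError(f"unsupported mean rule {mean_rule!r}")
    if sn_rule != "maximize":
        raise ValueError(f"unsupported S/N rule {sn_rule!r}")
    out: dict = {}
    for name, levels in rt.factors:
        score_mean = np.abs(np.asarray(rt.level_means[name]))
        score_sn = np.asarray(rt.level_sn[name])
        i_mean = int(np.argmin(score_mean))
        i_sn = int(np.argmax(score_sn))
        out[name] = {
            "level_by_mean": levels[i_mean],
            "level_by_sn": levels[i_sn],
            "tie_mean": bool(np.sum(score_mean == score_mean[i_mean]) > 1),
            "tie_sn": bool(np.sum(score_sn == score_sn[i_sn]) > 1),
        }
    return out


def optimal_levels_json(selection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(selection, indent=2) + "\n")
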