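"""Seed-counting verification metrics.

Quarantine verification compares per-class true seed counts with the
counts a detector reports over a whole sample. Accuracy is the capped
count ratio 100 * min(detected, true) / true (overcounts do not earn
credit beyond 100 %), leakage is its complement, and the composition
percentage situates each weed class within the full sample
(weed count / all seeds). The composition denominator choice is recorded
in the report since conventions differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["CountRecord", "MetricsReport", "compute_metrics", "check_composition"]

SOYBEAN = "soybean"


@dataclass(frozen=True)
class CountRecord:
    """Per-class true/detected counts, optionally with sample masses (g)."""

    true_counts: dict[str, int]
    detected_counts: dict[str, int]
    masses_g: dict[str, float] | None = None

    def __post_init__(self):
        for label, k in self.detected_counts.items():
            if k < 0:
                raise ValueError(f"negative detected count for {label!r}")
        for label, k in self.true_counts.items():
            if k < 0:
                raise ValueError(f"negative true count for {label!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountRecord":
        """Read a (class, true_count, detected_count[, mass_g]) CSV."""
        df = pd.read_csv(path)
        true_counts = dict(zip(df["class"], df["true_count"].astype(int)))
        detected = dict(zip(df["class"], df["detected_count"].astype(int)))
        masses = None
        if "mass_g" in df.columns:
            masses = dict(zip(df["class"], df["mass_g"].astype(float)))
        return cls(true_counts, detected, masses)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class accuracy/leakage/composition and the overall average."""

    accuracy_pct: dict[str, float]
    leakage_pct: dict[str, float]
    composition_pct: dict[str, float]
    average_accuracy_pct: float
    composition_denominator: str = "all_seeds"

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "leakage_pct": self.leakage_pct,
            "composition_pct": self.composition_pct,
            "average_accuracy_pct": self.average_accuracy_pct,
            "composition_denominator": self.composition_denominator,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def compute_metrics(rec: CountRecord) -> MetricsReport:
    """Compute accuracy, leakage and composition percentages.

    accuracy = 100 * min(detected, true) / true per class (so accuracy
    and leakage always sum to exactly 100); composition = 100 * true /
    total true over all classes; average accuracy is the unweighted mean
    over classes.

    Raises on any zero true count: a class with no ground-truth seeds
    has no defined detection accuracy.
    """
    if not rec.true_counts:
        raise ValueError("no classes in record")
    total_true = sum(rec.true_counts.values())
    accuracy: dict[str, float] = {}
    leakage: dict[str, float] = {}
    composition: dict[str, float] = {}
    for label, true in rec.true_counts.items():
        if true <= 0:
            raise ValueError(f"true_count for {label!r} must be positive")
        detected = rec.detected_counts.get(label, 0)
        acc = 100.0 * min(detected, true) / true
        accuracy[label] = acc
        leakage[label] = 100.0 - acc
        composition[label] = 100.0 * true / total_true
    return MetricsReport(
        accuracy_pct=accuracy,
        leakage_pct=leakage,
        composition_pct=composition,
        average_accuracy_pct=sum(accuracy.values()) / len(accuracy),
    )


@dataclass(frozen=True)
class CompositionCheck:
    """Outcome of the sample-composition protocol check."""

    count_ratio_pct: float
    count_ok: bool
    mass_ratio_pct: float | None = None
    mass_ok: bool | None = None

    def to_dict(self) -> dict:
        return {
            "count_ratio_pct": self.count_ratio_pct,
            "count_ok": self.count_ok,
            "mass_ratio_pct": self.mass_ratio_pct,
            "mass_ok": self.mass_ok,
        }


def check_composition(
    rec: CountRecord,
    mass_ratio_pct: tuple[float, float] = (1.0, 0.05),
    count_ratio_pct: tuple[float, float] = (5.0, 0.5),
    soybean_label: str = SOYBEAN,
) -> CompositionCheck:
    """Check a sample against the spiking protocol.

    The count ratio is weed seeds per soybean (in %), checked against
    ``count_ratio_pct = (target, tolerance)``; the mass ratio is weed
    mass per soybean mass, checked when masses are present. Ratios are
    attached to the result regardless of pass/fail.
    """
    weeds = [c for c in rec.true_counts if c != soybean_label]
    soy = rec.true_counts.get(soybean_label, 0)
    if soy <= 0:
        raise ValueError("soybean true count required for composition check")
    weed_count = sum(rec.true_counts[c] for c in weeds)
    count_ratio = 100.0 * weed_count / soy
    target, tol = count_ratio_pct
    count_ok = abs(count_ratio - target) <= tol
    mass_ratio = None
    mass_ok = None
    if rec.masses_g is not None:
        soy_mass = rec.masses_g.get(soybean_label, 0.0)
        if soy_mass <= 0:
            raise ValueError("soybean mass required for the mass constraint")
        weed_mass = sum(rec.masses_g.get(c, 0.0) for c in weeds)
        mass_ratio = 100.0 * weed_mass / soy_mass
        m_target, m_tol = mass_ratio_pct
        mass_ok = abs(mass_ratio - m_target) <= m_tol
    return CompositionCheck(
        count_ratio_pct=count_ratio,
        count_ok=count_ok,
        mass_ratio_pct=mass_ratio,
        mass_ok=mass_ok,
    )
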