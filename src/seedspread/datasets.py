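"""Packaged reference summaries for the spreading-device study.

These small fixtures describe the physical L18 screening of the
spreading device that this package's simulator emulates: the design
matrix, the per-level response summary (level means and S/N of Moran's
I), and the verification-protocol sample composition. They let the
Taguchi analysis and the metrics checks be exercised against the real
device's published operating points without any imagery.
"""

from __future__ import annotations

from .taguchi import ResponseTable, TaguchiDesign, l18_design

__all__ = [
    "l18_design",
    "device_study_response",
    "VERIFICATION_PROTOCOL",
]

# Per-level summary of Moran's I from the 18-run device screening:
# {factor: ([level S/N in dB], [level means])}; 9 runs per level for the
# 2-level socket factor, 6 per level for the 3-level factors.
_DEVICE_LEVEL_STATS = {
    "socket_arrangement": (
        [14.366, 18.508],
        [0.2621, 0.2407],
    ),
    "roller_speed": (
        [18.627, 22.379, 8.260],
        [0.1389, 0.2102, 0.4050],
    ),
    "motor_speed": (
        [7.636, 21.201, 20.430],
        [0.4423, 0.1695, 0.1424],
    ),
    "box_incline_deg": (
        [15.423, 14.550, 19.294],
        [0.2622, 0.2539, 0.2381],
    ),
    "chute_incline_deg": (
        [18.921, 15.649, 14.696],
        [0.2149, 0.2870, 0.2523],
    ),
    "belt_type": (
        [12.339, 17.509, 19.418],
        [0.2765, 0.2491, 0.2286],
    ),
}

#: Verification-run sample composition protocol: weed seeds are spiked
#: into ~500 g (≈2000 seeds) of soybeans at a 1 ± 0.05 % mass ratio and
#: a 5 ± 0.5 % count ratio.
VERIFICATION_PROTOCOL = {
    "mass_ratio_pct": (1.0, 0.05),
    "count_ratio_pct": (5.0, 0.5),
}


def device_study_response(design: TaguchiDesign | None = None) -> ResponseTable:
    """Response table of the physical device screening.

    Built from the per-level summaries (means and S/N of Moran's I) of
    the 18-run experiment; run-level data were not released, so deltas,
    ranks, ANOVA sums of squares and optimal-level selections are the
    operations this summary supports.
    """
    design = design or l18_design()
    level_means = {f: stats[1] for f, stats in _DEVICE_LEVEL_STATS.items()}
    level_sn = {f: stats[0] for f, stats in _DEVICE_LEVEL_STATS.items()}
    occurrences = {name: design.occurrences(name) for name in design.factor_names()}
    return ResponseTable.from_level_stats(
        design.factors, level_means, level_sn, occurrences
    )
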