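"""Global spatial autocorrelation (Moran's I) on gridded proportions.

Seed-spreading quality is scored per image as Moran's I over the 48
grid-tile seed-pixel fractions: values near +1 indicate clumped seeds
(adhesion/occlusion), values near -1 indicate regular dispersion, and
values near 0 indicate spatially random — i.e. uniform — spreading.

The statistic is

    I = N * sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S0 * sum_i (x_i - xbar)^2)

with ``w`` a binary contiguity matrix on the tile grid and
``S0 = sum_ij w_ij``. Under the permutation null E[I] = -1/(N-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["WeightMatrix", "MoranResult", "build_weights", "morans_i"]


@dataclass(frozen=True)
class WeightMatrix:
    """Binary spatial contiguity weights on an ``n_rows x n_cols`` grid.

    ``w`` is the dense N x N matrix (N = n_rows * n_cols, row-major tile
    order, zero diagonal, symmetric); ``scheme`` is ``"queen"``
    (8-neighbour) or ``"rook"`` (4-neighbour); ``s0`` is the total weight.
    """

    n_rows: int
    n_cols: int
    scheme: str
    w: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def s0(self) -> float:
        return float(self.w.sum())


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its permutation-null context.

    ``expected_i_null`` is the exact permutation expectation -1/(N-1).
    ``p_perm``/``n_perm`` are present only when a permutation test was
    requested; the p-value is two-sided on |I| with add-one correction —
    an inferential extension beyond the plain descriptive statistic.
    """

    i: float
    n: int
    s0: float
    expected_i_null: float
    p_perm: float | None = None
    n_perm: int | None = None

    def to_dict(self) -> dict:
        d = {
            "I": self.i,
            "N": self.n,
            "S0": self.s0,
            "expected_I_null": self.expected_i_null,
        }
        if self.p_perm is not None:
            d["p_perm"] = self.p_perm
            d["n_perm"] = self.n_perm
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


_OFFSETS = {
    "rook": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "queen": [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)],
}


def build_weights(n_rows: int, n_cols: int, scheme: str = "queen") -> WeightMatrix:
    """Build binary grid-contiguity weights.

    Rook adjacency links horizontal/vertical neighbours, queen adds the
    diagonals. Boundary tiles simply have fewer neighbours (no torus
    wrapping). Weights are left binary: the statistic already normalises
    by S0, so no row standardisation is applied.

    Raises
    ------
    ValueError
        If the grid has fewer than two tiles or the scheme is unknown.
    """
    if scheme not in _OFFSETS:
        raise ValueError(f"unknown contiguity scheme {scheme!r}; use 'queen' or 'rook'")
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 2:
        raise ValueError("grid must contain at least two tiles")
    n = n_rows * n_cols
    w = np.zeros((n, n), dtype=float)
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in _OFFSETS[scheme]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    w[i, rr * n_cols + cc] = 1.0
    return WeightMatrix(n_rows=n_rows, n_cols=n_cols, scheme=scheme, w=w)


def _moran_stat(x: np.ndarray, w: np.ndarray, s0: float) -> float:
    z = x - x.mean()
    denom = float(z @ z)
    return float(len(x) * (z @ w @ z) / (s0 * denom))


def morans_i(
    values,
    weights: WeightMatrix,
    n_perm: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Compute global Moran's I for tile values under the given weights.

    Parameters
    ----------
    values
        The per-tile values x_i, as a flat array in the weight matrix's
        row-major tile order, or any object with a ``.flat_values()``
        method (e.g. :class:`~seedspread.segmentation.GridProportions`).
    weights
        Contiguity weights from :func:`build_weights`.
    n_perm
        If > 0, run a two-sided permutation test with this many random
        relabelings of the tile values.
    seed
        RNG seed for the permutation test.

    Raises
    ------
    ValueError
        If the value count does not match the weights, or all tile
        values are equal (the statistic is then 0/0 and undefined;
        magnitudes are interpreted downstream, so this is a hard error
        rather than a silent 0).
    """
    if hasattr(values, "flat_values"):
        x = np.asarray(values.flat_values(), dtype=float)
    else:
        x = np.asarray(values, dtype=float).ravel()
    if x.size != weights.n:
        raise ValueError(f"got {x.size} values for a {weights.n}-tile weight matrix")
    if np.ptp(x) == 0.0:
        raise ValueError("Moran's I is undefined: all tile values are equal (zero variance)")
    s0 = weights.s0
    i_obs = _moran_stat(x, weights.w, s0)
    expected = -1.0 / (weights.n - 1)
    if n_perm <= 0:
        return MoranResult(i=i_obs, n=weights.n, s0=s0, expected_i_null=expected)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        i_p = _moran_stat(rng.permutation(x), weights.w, s0)
        if abs(i_p) >= abs(i_obs):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MoranResult(
        i=i_obs, n=weights.n, s0=s0, expected_i_null=expected, p_perm=p, n_perm=n_perm
    )
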