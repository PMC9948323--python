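"""Restricted cubic spline basis (natural spline, truncated-power form).

The basis follows the standard restricted truncated-power construction:
for knots t_1 < ... < t_k the first column is x itself and, for
j = 1..k-2,

    B_j(x) = [ (x - t_j)_+^3
               - (x - t_{k-1})_+^3 (t_k - t_j) / (t_k - t_{k-1})
               + (x - t_k)_+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ]
             / (t_k - t_1)^2,

which makes the fitted function linear beyond both boundary knots and
keeps the nonlinear columns on roughly the scale of x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: conventional quantile placements for k knots (outer/inner quantiles)
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass(frozen=True)
class SplineSpec:
    """An ascending knot set on the exposure-percentile scale."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("restricted cubic spline needs >= 3 knots")
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", tuple(float(v) for v in k))

    @property
    def n_basis(self) -> int:
        """Number of basis columns: 1 linear + (k - 2) nonlinear."""
        return len(self.knots) - 1

    def column_names(self, prefix: str = "rcs") -> list[str]:
        return [f"{prefix}{j}" for j in range(1, self.n_basis + 1)]


def knots_from_quantiles(x, n_knots: int) -> SplineSpec:
    """Knots at the conventional quantiles of the observed exposure."""
    if n_knots not in KNOT_QUANTILES:
        raise ValueError(f"unsupported knot count {n_knots}; choose from {sorted(KNOT_QUANTILES)}")
    q = np.quantile(np.asarray(x, dtype=float), KNOT_QUANTILES[n_knots])
    if np.any(np.diff(q) <= 0):
        raise ValueError("degenerate exposure distribution: tied knot quantiles")
    return SplineSpec(tuple(q))


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis, shape (n, k - 1)."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("exposure percentiles must lie in [0, 1]")
    t = np.asarray(spec.knots)
    k = t.size
    out = np.empty(x.shape + (k - 1,))
    out[..., 0] = x

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    denom = t[-1] - t[-2]
    norm = (t[-1] - t[0]) ** 2
    for j in range(k - 2):
        out[..., j + 1] = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube(x - t[-1]) * (t[-2] - t[j]) / denom
        ) / norm
    return out


def select_knots(x, fit_candidate, candidates=(3, 4, 5)) -> "SplineSpec":
    """Pick the knot count minimizing AIC; ties break toward fewer knots.

    ``fit_candidate(spec) -> aic`` fits the full model for one knot set and
    returns its AIC; failures to converge are collected and re-raised only
    if every candidate fails.
    """
    best: tuple[float, int, SplineSpec] | None = None
    failures: list[str] = []
    for n in sorted(candidates):
        try:
            spec = knots_from_quantiles(x, n)
            aic = float(fit_candidate(spec))
        except Exception as exc:  # noqa: BLE001 — candidate diagnostics are collected
            failures.append(f"{n} knots: {exc}")
            continue
        if best is None or aic < best[0] - 1e-12:
            best = (aic, n, spec)
    if best is None:
        raise RuntimeError("no spline candidate converged: " + "; ".join(failures))
    return best[2]
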