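"""Sensitivity analysis: one-way (tornado) and probabilistic (Monte Carlo).

The probabilistic sensitivity analysis (PSA) re-runs a model many times
(default 10,000) with every parameter drawn simultaneously from an assumed
distribution — beta for probabilities (support [0, 1]), normal for everything
else — and reports the empirical 2.5th/97.5th percentile range of the outputs
as a 95% credible interval.

Spread specifications are resolved to a standard deviation in a fixed order
of precedence: an explicit standard error; a (min, max) range mapped to
SD = (max - min) / (2 x 1.96); otherwise a relative half-width (default
+/-20% of the central value) mapped the same way. Beta parameters are found
by method of moments from the mean and that SD. Normal draws are truncated
to the parameter's domain by resampling, so the algorithm never sees an
invalid input; at +/-20% spreads the truncation bias is negligible.

Percentiles use the nearest-rank definition on sorted draws: deterministic,
and checkable against a brute-force sort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .conversion import ConversionInputs, estimate_unique_patients
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "TornadoRow",
    "sample_parameter",
    "run_psa",
    "one_way_sensitivity",
    "nearest_rank_percentile",
    "DEFAULT_ITERATIONS",
    "DEFAULT_RELATIVE_RANGE",
]

DEFAULT_ITERATIONS = 10_000
DEFAULT_RELATIVE_RANGE = 0.20
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling specification for one model parameter.

    family
        ``"beta"`` (probabilities only), ``"normal"``, or ``"fixed"``.
    central
        The base-case value; the mean of the sampling distribution.
    se / value_range / relative
        Exactly one spread specification is used, in that order of
        precedence; if none is given, ``relative`` defaults to 0.20
        (a +/-20% range around the central value, interpreted as
        central +/- 1.96 SD).
    domain
        Closed support the draws must respect (normal draws are resampled
        into it); defaults to the whole real line, and to [0, 1] for beta.
    """

    name: str
    family: str
    central: float
    se: float | None = None
    value_range: tuple[float, float] | None = None
    relative: float | None = None
    domain: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if self.family not in ("beta", "normal", "fixed"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "beta":
            if not 0.0 <= self.central <= 1.0:
                raise ValidationError(
                    f"beta family requires central value in [0, 1], got {self.central}"
                )
            object.__setattr__(self, "domain", (0.0, 1.0))
        if self.value_range is not None:
            lo, hi = self.value_range
            if not lo <= self.central <= hi:
                raise ValidationError(
                    f"{self.name}: central {self.central} outside range ({lo}, {hi})"
                )

    @property
    def sd(self) -> float:
        """Resolved standard deviation of the sampling distribution."""
        if self.family == "fixed":
            return 0.0
        if self.se is not None:
            return self.se
        if self.value_range is not None:
            lo, hi = self.value_range
            return (hi - lo) / (2.0 * _Z95)
        rel = self.relative if self.relative is not None else DEFAULT_RELATIVE_RANGE
        return abs(self.central) * rel / _Z95


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a beta distribution."""
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValidationError(
            f"beta variance {var:.4g} not achievable for mean {mean} (must be < {bound:.4g})"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_parameter(
    dist: ParameterDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw from a parameter's distribution (scalar, or an array of ``size``).

    Beta draws lie in [0, 1] by construction; a degenerate beta (central at an
    endpoint, or zero spread) collapses to the fixed central value. Normal
    draws are truncated to ``dist.domain`` by resampling.
    """
    n = 1 if size is None else size
    if dist.family == "fixed":
        out = np.full(n, dist.central)
    elif dist.family == "beta":
        if dist.sd == 0.0 or dist.central in (0.0, 1.0):
            out = np.full(n, dist.central)  # degenerate-endpoint rule
        else:
            a, b = _beta_moments(dist.central, dist.sd)
            out = rng.beta(a, b, size=n)
    else:  # normal
        if dist.sd == 0.0:
            out = np.full(n, dist.central)
        else:
            out = rng.normal(dist.central, dist.sd, size=n)
            lo, hi = dist.domain
            bad = (out < lo) | (out > hi)
            while bad.any():
                out[bad] = rng.normal(dist.central, dist.sd, size=int(bad.sum()))
                bad = (out < lo) | (out > hi)
    return float(out[0]) if size is None else out


def nearest_rank_percentile(sorted_draws: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: element at rank ceil(q*n) of the sorted draws."""
    n = sorted_draws.size
    rank = min(max(int(math.ceil(q * n)), 1), n)
    return float(sorted_draws[rank - 1])


@dataclass(frozen=True)
class PSAResult:
    """Outcome of a probabilistic sensitivity analysis."""

    point_estimate: float
    n_draws: int
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    median: float
    seed: int
    draws: np.ndarray | None = None

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def run_psa(
    model: Callable[..., float],
    dists: Sequence[ParameterDistribution],
    n_iter: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    retain_draws: bool = False,
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through *model*.

    *model* is called with one keyword argument per distribution, named by
    ``dist.name``. All parameters are drawn simultaneously each iteration,
    in the listed order from a single seeded stream, so identical seeds give
    bit-identical results. The credible interval is the empirical
    2.5th-97.5th nearest-rank percentile range; the point estimate is the
    model at every parameter's central value.

    Fewer than 100 iterations make the tail percentiles unreliable; a
    ``ConfigurationError`` is raised rather than returning a misleading
    interval.
    """
    if n_iter < 100:
        raise ConfigurationError(
            f"n_iter={n_iter} is too few draws for stable 2.5/97.5 percentiles (need >= 100)"
        )
    names = [d.name for d in dists]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate parameter names in {names}")
    rng = np.random.default_rng(seed)
    # draw parameter-by-parameter in listed order: documented, reproducible
    samples = {d.name: sample_parameter(d, rng, size=n_iter) for d in dists}
    outputs = np.empty(n_iter)
    for i in range(n_iter):
        outputs[i] = model(**{name: float(samples[name][i]) for name in names})
    point = model(**{d.name: d.central for d in dists})
    ordered = np.sort(outputs)
    return PSAResult(
        point_estimate=float(point),
        n_draws=n_iter,
        lower=nearest_rank_percentile(ordered, 0.025),
        upper=nearest_rank_percentile(ordered, 0.975),
        median=nearest_rank_percentile(ordered, 0.5),
        seed=seed,
        draws=outputs if retain_draws else None,
    )


@dataclass(frozen=True)
class TornadoRow:
    """One bar of a tornado diagram: output at a parameter's low/high extremes."""

    parameter: str
    output_low: float
    output_high: float

    @property
    def swing(self) -> float:
        return abs(self.output_high - self.output_low)


def one_way_sensitivity(
    base: ConversionInputs,
    ranges: Mapping[str, tuple[float, float]],
    model: Callable[[ConversionInputs], float] = estimate_unique_patients,
) -> list[TornadoRow]:
    """Vary each parameter alone over its (low, high) range, others at base.

    Keys of *ranges* are :class:`ConversionInputs` field names. Rows are
    returned sorted by descending swing (ties broken by parameter name), the
    ordering of a tornado diagram. A zero-width range is legal and yields a
    zero swing.
    """
    valid = {"ctx_donated", "destruction_rate", "ctx_per_visit", "revisit_rate"}
    rows = []
    for name, (lo, hi) in ranges.items():
        if name not in valid:
            raise ConfigurationError(f"unknown parameter {name!r}; expected one of {sorted(valid)}")
        base_val = getattr(base, name)
        if not lo <= base_val <= hi:
            raise ValidationError(
                f"{name}: base value {base_val} outside range ({lo}, {hi})"
            )
        rows.append(
            TornadoRow(
                parameter=name,
                output_low=model(replace(base, **{name: lo})),
                output_high=model(replace(base, **{name: hi})),
            )
        )
    return sorted(rows, key=lambda r: (-r.swing, r.parameter))
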