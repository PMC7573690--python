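"""The resource-precision model of homo-oligomer frequencies.

Synthesizing a complex of k identical subunits costs energy linearly in k
(E(k) = 4.5 ATP/aa x L x k), while the precision of the binding reaction a
k-mer can implement scales with the reciprocal of its 2^k binary occupancy
arrangements (Prec ~ 2^-k). Balancing the two predicts the proteome frequency
of k-mers, f_s(k) ~ k / 2^k, and the capacity statistic c(k) = f_s(k) x k
interprets k as a bit count (M = 2^k signal levels). For cyclic complexes the
arrangement count can instead be taken modulo rotation: the binary necklace
count (1/k) sum_{d | k} phi(d) 2^{k/d}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "EnergyParams",
    "HillParams",
    "ResourceModelFit",
    "CapacityCurve",
    "energy_cost",
    "n_arrangements",
    "precision",
    "model_frequency",
    "fit_resource_model",
    "capacity",
    "necklace_count",
    "euler_totient",
    "hill_response",
]

#: Even supports used throughout: the four-point fit of the study design.
DEFAULT_SUPPORT: tuple[int, ...] = (2, 4, 6, 8)


@dataclass(frozen=True)
class EnergyParams:
    """Constants of the synthesis-energy estimate.

    atp_per_aa: ATP molecules hydrolyzed per amino acid polymerized (4.5).
    length_aa: average protein length L in amino acids (~270 in bacteria,
        ~360 in eukaryotes).
    """

    atp_per_aa: float = 4.5
    length_aa: float = 270.0

    def __post_init__(self) -> None:
        if self.atp_per_aa <= 0 or self.length_aa <= 0:
            raise InvalidParameterError("atp_per_aa and length_aa must be positive")


@dataclass(frozen=True)
class HillParams:
    """Hill response parameters: coefficient n > 0, dissociation constant
    Kd > 0, unbound concentration s >= 0."""

    n: float
    Kd: float
    s: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise InvalidParameterError("Hill coefficient n must be > 0")
        if self.Kd <= 0:
            raise InvalidParameterError("Kd must be > 0")
        if self.s < 0:
            raise InvalidParameterError("concentration s must be >= 0")


@dataclass(frozen=True)
class ResourceModelFit:
    """Result of fitting f_s(k) = A * k/2^k to empirical frequencies."""

    support: tuple[int, ...]
    mode: str  # "normalized" | "scaled"
    scale: float
    predicted: dict[int, float]
    r_squared: float
    residuals: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CapacityCurve:
    """Pointwise capacity c(k) = f_s(k) * k of a frequency distribution."""

    values: dict[int, float]
    label: str = ""


def energy_cost(k: int, params: EnergyParams = EnergyParams()) -> float:
    """ATP cost of synthesizing a k-mer: atp_per_aa * L * k."""
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    return params.atp_per_aa * params.length_aa * k


def n_arrangements(k: int, M: int = 2) -> int:
    """Number of statistical arrangements of k subunits with M states each.

    M^k exactly, in integer arithmetic; M=2 is the binary occupancy case
    (each subunit's binding site occupied or not).
    """
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    if M < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    return M**k

def precision(k: int) -> float:
    """Relative precision of a k-subunit binding reaction: 2^-k."""
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    return 2.0**-k


def model_frequency(
    support: Iterable[int], mode: str = "normalized"
) -> dict[int, float]:
    """Model weights w(k) = k/2^k over the support.

    "normalized" divides by the sum over the support (a probability
    distribution on the support); "scaled" returns the raw weights for a
    later least-squares scale fit.
    """
    ks = sorted(set(int(k) for k in support))
    if not ks:
        raise InvalidParameterError("support must be nonempty")
    if ks[0] < 1:
        raise InvalidParameterError("support values must be >= 1")
    if mode not in ("normalized", "scaled"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    w = {k: k / 2.0**k for k in ks}
    if mode == "scaled":
        return w
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def fit_resource_model(
    empirical: Mapping[int, float],
    support: Optional[Sequence[int]] = None,
    mode: str = "scaled",
) -> ResourceModelFit:
    """Fit the resource-precision prediction A * k/2^k to empirical f_s.

    In "scaled" mode A minimizes sum_k (f_emp(k) - A w(k))^2, which has the
    closed form A = sum f w / sum w^2; in "normalized" mode A is fixed by
    normalization over the support. r_squared is 1 - SS_res/SS_tot against the
    empirical mean over the support.

    ``empirical`` may be a plain k -> frequency mapping or an
    :class:`~oligodist.distributions.OligomerDistribution` (its freqs are used).
    """
    freqs = getattr(empirical, "freqs", empirical)
    ks = tuple(sorted(support)) if support is not None else DEFAULT_SUPPORT
    missing = [k for k in ks if k not in freqs or not np.isfinite(freqs[k])]
    if missing:
        raise InvalidParameterError(
            f"empirical distribution lacks finite frequencies at k={missing}"
        )
    f = np.array([freqs[k] for k in ks], dtype=float)
    w = np.array([k / 2.0**k for k in ks], dtype=float)

    if mode == "scaled":
        scale = float(np.dot(f, w) / np.dot(w, w))
    elif mode == "normalized":
        scale = float(1.0 / w.sum())
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")

    pred = scale * w
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return ResourceModelFit(
        support=ks,
        mode=mode,
        scale=scale,
        predicted={k: float(p) for k, p in zip(ks, pred)},
        r_squared=r2,
        residuals={k: float(fi - pi) for k, fi, pi in zip(ks, f, pred)},
    )


def capacity(distribution, label: str = "") -> CapacityCurve:
    """Capacity c(k) = f_s(k) * k of a frequency distribution.

    For a normalized distribution, sum_k c(k) is the mean subunit number.
    """
    freqs = getattr(distribution, "freqs", distribution)
    lab = label or getattr(distribution, "label", "")
    return CapacityCurve(values={k: f * k for k, f in freqs.items()}, label=lab)


def euler_totient(d: int) -> int:
    """Euler's totient phi(d): integers in [1, d] coprime to d.

    Computed from the prime factorization by trial division; exact for any
    positive integer.
    """
    if d < 1:
        raise InvalidParameterError(f"d must be >= 1, got {d}")
    result = d
    n = d
    p = 2
    while p * p <= n:
        if n % p == 0:
            while n % p == 0:
                n //= p
            result -= result // p
        p += 1 if p == 2 else 2
    if n > 1:
        result -= result // n
    return result


def necklace_count(k: int) -> int:
    """Binary necklaces of length k: (1/k) sum over divisors d of k of
    phi(d) * 2^(k/d). Counts occupancy arrangements of a cyclic k-mer up to
    rotation; exact integer arithmetic."""
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    total = 0
    for d in range(1, k + 1):
        if k % d == 0:
            total += euler_totient(d) * 2 ** (k // d)
    assert total % k == 0
    return total // k


def hill_response(params: HillParams, kd_power: bool = False) -> float:
    """Fractional Hill response H = s^n / (s^n + Kd).

    As printed in the source model, Kd enters un-exponentiated (dimensionally
    inconsistent unless concentrations are scaled); ``kd_power=True`` selects
    the conventional H = s^n / (s^n + Kd^n) variant. n=1 reduces to
    Michaelis-Menten.
    """
    sn = params.s**params.n
    denom = sn + (params.Kd**params.n if kd_power else params.Kd)
    return sn / denom
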