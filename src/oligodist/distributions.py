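"""Homo-oligomer frequency distributions over a proteome.

f_s(k) = N_k / N_T, where N_k is the number of proteins with k identical
subunits and N_T the chosen denominator. The denominator is either every
protein with a known homo-oligomer state ("all-known", the whole-proteome
convention, monomers included) or the parity subset itself
("parity-subset", used when even-k frequencies are renormalized before
model fitting). Weighting can count proteins or sum their abundance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, InvalidParameterError
from .io import ProteinRecord

__all__ = [
    "OligomerDistribution",
    "AverageDistribution",
    "oligomer_frequency",
    "stratified_frequency",
    "average_across",
]

#: k values above this are pooled into an overflow bin excluded from freqs.
DEFAULT_K_MAX = 24


@dataclass(frozen=True)
class OligomerDistribution:
    """Counts N_k and frequencies f_s(k) over subunit numbers k."""

    label: str
    counts: dict[int, float]
    total: float
    freqs: dict[int, float]
    parity: str = "all"  # all | even | odd
    weighting: str = "count"  # count | abundance
    overflow: float = 0.0  # pooled mass above k_max, excluded from freqs

    def to_tidy_rows(self) -> list[dict]:
        return [
            {"label": self.label, "k": k, "count": self.counts[k], "freq": self.freqs[k]}
            for k in sorted(self.counts)
        ]


@dataclass(frozen=True)
class AverageDistribution:
    """Per-k mean and population standard deviation across organisms."""

    mean_freqs: dict[int, float]
    std_freqs: dict[int, float]
    n_organisms: int


def _known_homo(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    return [r for r in records if r.is_homo and r.oligomer_k is not None]


def oligomer_frequency(
    records: Iterable[ProteinRecord],
    parity: str = "all",
    denominator: str = "all-known",
    weighting: str = "count",
    label: str = "",
    k_max: int = DEFAULT_K_MAX,
) -> OligomerDistribution:
    """Frequency distribution of subunit numbers among known homo-oligomers.

    parity selects which k enter the counts ("all", "even", "odd");
    denominator chooses N_T = all known states or the parity subset only;
    weighting="abundance" sums each protein's abundance instead of counting
    (records without abundance contribute 0).
    """
    if parity not in ("all", "even", "odd"):
        raise InvalidParameterError(f"unknown parity {parity!r}")
    if denominator not in ("all-known", "parity-subset"):
        raise InvalidParameterError(f"unknown denominator mode {denominator!r}")
    if weighting not in ("count", "abundance"):
        raise InvalidParameterError(f"unknown weighting {weighting!r}")

    known = _known_homo(records)
    if not known:
        raise EmptyInputError("no records with a known homo-oligomer state")

    def weight(r: ProteinRecord) -> float:
        if weighting == "count":
            return 1.0
        return r.abundance if r.abundance is not None else 0.0

    def keep(k: int) -> bool:
        if parity == "even":
            return k % 2 == 0
        if parity == "odd":
            return k % 2 == 1
        return True

    counts: dict[int, float] = defaultdict(float)
    overflow = 0.0
    total_all = 0.0
    total_subset = 0.0
    for r in known:
        w = weight(r)
        total_all += w
        k = r.oligomer_k
        if not keep(k):
            continue
        total_subset += w
        if k > k_max:
            overflow += w
        else:
            counts[k] += w

    total = total_all if denominator == "all-known" else total_subset
    if total <= 0:
        raise EmptyInputError("qualifying records carry zero total weight")
    freqs = {k: c / total for k, c in counts.items()}
    return OligomerDistribution(
        label=label,
        counts=dict(counts),
        total=total,
        freqs=freqs,
        parity=parity,
        weighting=weighting,
        overflow=overflow,
    )


def stratified_frequency(
    records: Iterable[ProteinRecord],
    category_label: str,
    **kwargs,
) -> OligomerDistribution:
    """oligomer_frequency restricted to records carrying a category label.

    The denominator is the known homo-oligomers within the category, so
    strata are directly comparable to the whole-proteome distribution.
    """
    subset = [r for r in records if category_label in r.go_terms]
    if not subset:
        raise EmptyInputError(f"no records carry category {category_label!r}")
    kwargs.setdefault("label", category_label)
    return oligomer_frequency(subset, **kwargs)


def average_across(
    distributions: Sequence[OligomerDistribution],
) -> AverageDistribution:
    """Per-k mean and population std of f_s across organisms.

    A k absent from a distribution contributes frequency 0 there. All inputs
    must share parity and weighting settings.
    """
    if not distributions:
        raise EmptyInputError("need at least one distribution")
    parities = {d.parity for d in distributions}
    weightings = {d.weighting for d in distributions}
    if len(parities) > 1 or len(weightings) > 1:
        raise InvalidParameterError(
            f"mixed parity/weighting settings: {parities}, {weightings}"
        )
    all_k = sorted({k for d in distributions for k in d.freqs})
    mat = np.array(
        [[d.freqs.get(k, 0.0) for k in all_k] for d in distributions], dtype=float
    )
    return AverageDistribution(
        mean_freqs={k: float(m) for k, m in zip(all_k, mat.mean(axis=0))},
        std_freqs={k: float(s) for k, s in zip(all_k, mat.std(axis=0, ddof=0))},
        n_organisms=len(distributions),
    )
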