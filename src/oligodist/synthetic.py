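"""Synthetic proteomes and interaction networks with the structure the
analysis assumes.

The proteome generator emulates an annotation extract in which only a
fraction of proteins have a known oligomer state, even-k frequencies decay
roughly as k/2^k, odd k are suppressed relative to their even neighbors, and
monomers carry their own (large) weight. The network generator produces a
degree sequence with a discrete power-law tail above a cutoff k_min and a
Poisson head below it, realized as a simple graph by stub matching.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .errors import InvalidParameterError
from .io import PPIGraph, ProteinRecord, write_proteome_table, write_string_edges
from .powerlaw import sample_discrete_powerlaw

__all__ = [
    "ProteomeSimParams",
    "NetworkSimParams",
    "generate_proteome",
    "generate_degree_sequence",
    "realize_edges",
    "assign_categories",
    "oligomer_state_weights",
    "write_simulation",
]


@dataclass(frozen=True)
class ProteomeSimParams:
    """Conditions of a simulated proteome annotation extract.

    known_fraction: share of proteins with an annotated oligomer state
        (annotation coverage in real proteomes is small; default 0.3).
    k_support: subunit numbers that occur (default 1..12, the range covered
        by the Greek-numeral annotation vocabulary).
    odd_suppression: multiplier in [0, 1] on the model weight of odd k > 1
        (the observed even/odd asymmetry; default 0.3).
    monomer_weight: free weight of k=1 (monomers sit outside the k/2^k fit;
        default 0.5, comparable to the dimer weight).
    mean_length_aa: average protein length L (270 bacterial, 360 eukaryotic).
    abundance_dispersion: sigma of the log-normal abundance draw (default
        1.5, a few orders of magnitude spread as in real proteomes).
    """

    n_proteins: int
    known_fraction: float = 0.3
    k_support: tuple[int, ...] = tuple(range(1, 13))
    odd_suppression: float = 0.3
    monomer_weight: float = 0.5
    mean_length_aa: float = 270.0
    abundance_dispersion: float = 1.5
    organism: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise InvalidParameterError("n_proteins must be >= 0")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise InvalidParameterError("known_fraction must be in [0, 1]")
        if not 0.0 <= self.odd_suppression <= 1.0:
            raise InvalidParameterError("odd_suppression must be in [0, 1]")
        ks = list(self.k_support)
        if not ks or any(b <= a for a, b in zip(ks, ks[1:])) or ks[0] < 1:
            raise InvalidParameterError(
                "k_support must be nonempty, strictly increasing, min >= 1"
            )
        if self.monomer_weight < 0:
            raise InvalidParameterError("monomer_weight must be >= 0")
        if self.mean_length_aa <= 0 or self.abundance_dispersion <= 0:
            raise InvalidParameterError(
                "mean_length_aa and abundance_dispersion must be positive"
            )


@dataclass(frozen=True)
class NetworkSimParams:
    """Conditions of a simulated interaction-network degree sequence.

    Degrees >= k_min follow the discrete power law p(k) ∝ k^-gamma truncated
    at k_max; degrees below come from a Poisson head with mean ``head_mean``.
    ``tail_fraction`` is the share of nodes in the power-law tail.
    """

    n_nodes: int
    gamma: float = 2.5
    k_min: int = 5
    head_mean: float = 2.0
    tail_fraction: float = 0.5
    k_max: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise InvalidParameterError("n_nodes must be >= 0")
        if self.gamma <= 1:
            raise InvalidParameterError(f"gamma must be > 1, got {self.gamma}")
        if self.k_min < 1:
            raise InvalidParameterError("k_min must be >= 1")
        if self.head_mean < 0:
            raise InvalidParameterError("head_mean must be >= 0")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise InvalidParameterError("tail_fraction must be in [0, 1]")
        if self.k_max < self.k_min:
            raise InvalidParameterError("k_max must be >= k_min")


def oligomer_state_weights(params: ProteomeSimParams) -> dict[int, float]:
    """Normalized sampling weights over k_support.

    w(k) ∝ k/2^k for even k, odd_suppression * k/2^k for odd k > 1, and
    monomer_weight for k = 1.
    """
    w: dict[int, float] = {}
    for k in params.k_support:
        if k == 1:
            w[k] = params.monomer_weight
        elif k % 2 == 0:
            w[k] = k / 2.0**k
        else:
            w[k] = params.odd_suppression * k / 2.0**k
    total = sum(w.values())
    if total <= 0:
        raise InvalidParameterError("all state weights are zero")
    return {k: v / total for k, v in w.items()}


def generate_proteome(params: ProteomeSimParams) -> list[ProteinRecord]:
    """Draw a proteome of n_proteins records under the given conditions.

    A known_fraction share of proteins carry an oligomer state sampled from
    :func:`oligomer_state_weights`; lengths are log-normal around
    mean_length_aa, abundances log-normal with the given dispersion.
    Identical seeds reproduce identical record lists.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    if n == 0:
        return []

    weights = oligomer_state_weights(params)
    ks = np.array(list(weights), dtype=np.int64)
    probs = np.array(list(weights.values()), dtype=float)

    known = rng.random(n) < params.known_fraction
    states = rng.choice(ks, size=n, p=probs)
    # log-normal lengths: sigma 0.45 gives a realistic right skew; the
    # location is solved so the mean equals mean_length_aa
    sigma_len = 0.45
    mu_len = np.log(params.mean_length_aa) - sigma_len**2 / 2
    lengths = np.maximum(30, rng.lognormal(mu_len, sigma_len, size=n)).astype(int)
    abundances = rng.lognormal(np.log(100.0), params.abundance_dispersion, size=n)

    records = []
    for i in range(n):
        k = int(states[i]) if known[i] else None
        records.append(
            ProteinRecord(
                protein_id=f"SYN{i:06d}",
                organism=params.organism,
                length_aa=int(lengths[i]),
                oligomer_k=k,
                is_homo=k is not None,
                abundance=float(np.round(abundances[i], 6)),
            )
        )
    return records


def generate_degree_sequence(params: NetworkSimParams) -> np.ndarray:
    """Degree sequence with Poisson head below k_min, power-law tail above.

    The degree sum is forced even by incrementing the largest entry if
    needed (so the tail's truncation boundary is preserved).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    in_tail = rng.random(n) < params.tail_fraction
    n_tail = int(in_tail.sum())
    degrees = np.empty(n, dtype=np.int64)
    if n_tail:
        degrees[in_tail] = sample_discrete_powerlaw(
            n_tail, params.gamma, params.k_min, rng, k_max=params.k_max
        )
    n_head = n - n_tail
    if n_head:
        head = rng.poisson(params.head_mean, size=n_head)
        # resample any head draw that reaches the tail region
        while np.any(head >= params.k_min):
            bad = head >= params.k_min
            head[bad] = rng.poisson(params.head_mean, size=int(bad.sum()))
        degrees[~in_tail] = head
    if degrees.sum() % 2 == 1:
        degrees[np.argmax(degrees)] += 1
    return degrees


def realize_edges(
    degree_sequence: Sequence[int],
    seed: Optional[int] = None,
    max_attempt_factor: int = 100,
) -> PPIGraph:
    """Realize a degree sequence as a simple graph by random stub matching.

    Self-loops and duplicate edges are rejected and their stubs rematched;
    after ``max_attempt_factor * E`` pairing attempts any unmatched stubs are
    discarded, their count reported in ``G.graph['discarded_stubs']``.
    """
    degrees = np.asarray(degree_sequence, dtype=np.int64)
    if np.any(degrees < 0):
        raise InvalidParameterError("degrees must be nonnegative")
    if degrees.sum() % 2 != 0:
        raise InvalidParameterError("degree sum must be even")
    rng = np.random.default_rng(seed)

    g: PPIGraph = nx.Graph()
    g.add_nodes_from(range(len(degrees)))
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    n_edges_target = stubs.size // 2
    budget = max_attempt_factor * max(n_edges_target, 1)
    attempts = 0
    while stubs.size >= 2 and attempts < budget:
        rng.shuffle(stubs)
        leftover = []
        for i in range(0, stubs.size - 1, 2):
            a, b = int(stubs[i]), int(stubs[i + 1])
            attempts += 1
            if a == b or g.has_edge(a, b):
                leftover.extend((a, b))
            else:
                g.add_edge(a, b)
        if stubs.size % 2 == 1:  # cannot happen (even sum) but keep safe
            leftover.append(int(stubs[-1]))
        stubs = np.array(leftover, dtype=np.int64)
    g.graph["discarded_stubs"] = int(stubs.size)
    return g


def assign_categories(
    records: Sequence[ProteinRecord],
    category_weights: dict[str, float],
    seed: Optional[int] = None,
) -> list[ProteinRecord]:
    """Assign one category label per record, proportional to the weights."""
    if not category_weights:
        raise InvalidParameterError("category_weights must be nonempty")
    labels = sorted(category_weights)
    w = np.array([category_weights[l] for l in labels], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise InvalidParameterError("weights must be nonnegative, not all zero")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(labels), size=len(records), p=p)
    return [
        r.with_go_terms(r.go_terms | {labels[int(j)]})
        for r, j in zip(records, drawn)
    ]


def write_simulation(records, graph, outdir, params_list=()) -> None:
    """Write a simulated dataset in the canonical TSV schemas plus a JSON
    sidecar echoing all simulation parameters and seeds."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if records is not None:
        write_proteome_table(records, out / "proteome.tsv")
    if graph is not None:
        write_string_edges(graph, out / "interactions.tsv")
    sidecar = [asdict(p) for p in params_list]
    (out / "simulation_params.json").write_text(json.dumps(sidecar, indent=2))
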