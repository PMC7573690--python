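"""Readers and writers for proteome annotation tables and interaction edge lists.

The proteome table is a TSV with header columns ``protein_id``, ``organism``,
``length_aa`` and either an explicit ``oligomer_k`` column or a free-text
``subunit_annotation`` column in the style of UniProt's subunit-structure
subsection ("Homotetramer.", "Heterodimer of A and B.", ...). Optional columns:
``go_terms`` (pipe-separated labels) and ``abundance``.

Interaction files follow a STRING-style TSV schema with two protein-id columns
and an optional confidence ``score`` column; edges are undirected and
deduplicated on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Undirected simple graph of protein-protein interactions. Node names are
#: protein ids; the graph carries bookkeeping counters in ``G.graph``.
PPIGraph = nx.Graph


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identity, length, homo-oligomer state and annotations.

    ``oligomer_k`` is the number of identical subunits (1 for a monomer) or
    ``None`` when the state is unknown. ``is_homo`` is False when the
    annotation describes a hetero-complex only.
    """

    protein_id: str
    organism: str = ""
    length_aa: int = 1
    oligomer_k: Optional[int] = None
    is_homo: bool = False
    go_terms: frozenset[str] = field(default_factory=frozenset)
    abundance: Optional[float] = None
    ambiguity_note: str = ""

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise InvalidParameterError(f"length_aa must be >= 1, got {self.length_aa}")
        if self.oligomer_k is not None and self.oligomer_k < 1:
            raise InvalidParameterError(f"oligomer_k must be >= 1, got {self.oligomer_k}")

    def with_go_terms(self, terms: Iterable[str]) -> "ProteinRecord":
        return replace(self, go_terms=frozenset(terms))


# Greek-numeral oligomer names, lowest k first. Hyphens/spaces are tolerated
# ("homo-tetramer", "homo tetramer") via the separator pattern below.
_GREEK_NAMES = {
    "monomer": 1,
    "dimer": 2,
    "trimer": 3,
    "tetramer": 4,
    "pentamer": 5,
    "hexamer": 6,
    "heptamer": 7,
    "octamer": 8,
    "nonamer": 9,
    "decamer": 10,
    "undecamer": 11,
    "dodecamer": 12,
}

_SEP = r"[\s\-]?"
_HOMO_NAMED = re.compile(
    r"\bhomo" + _SEP + r"(" + "|".join(_GREEK_NAMES) + r")s?\b", re.IGNORECASE
)
_MONOMER = re.compile(r"\bmonomer(?:ic)?s?\b", re.IGNORECASE)
# numeric forms: "homo-12-mer", "homo 24 mer", "homo-3-mer"
_HOMO_NUMERIC = re.compile(r"\bhomo" + _SEP + r"(\d+)" + _SEP + r"mers?\b", re.IGNORECASE)
_HOMO_BARE = re.compile(r"\bhomo" + _SEP + r"oligomer(?:ic)?s?\b", re.IGNORECASE)
_HETERO = re.compile(r"\bhetero[\s\-]?\w*", re.IGNORECASE)


def parse_subunit_annotation(
    text: str, policy: str = "first"
) -> tuple[Optional[int], bool, str]:
    """Extract the homo-oligomer subunit number from free annotation text.

    Returns ``(k, is_homo, ambiguity_note)``. Recognizes Greek-numeral names
    (monomer -> 1, homodimer -> 2, ... homododecamer -> 12) and numeric
    "homo-N-mer" forms. Annotations mentioning several homo states yield one k
    chosen by ``policy`` ("first" mention, "min" or "max"), with all candidate
    states listed in the ambiguity note. Hetero-only annotations return
    ``(None, False, "")``; unparseable text returns ``(None, False, "")`` as
    well, never an exception. A bare "Homooligomer" with no number yields
    ``(None, True, ...)`` — homo-oligomeric but with unassignable k.
    """
    if policy not in ("first", "min", "max"):
        raise InvalidParameterError(f"unknown policy {policy!r}")
    if not text:
        return None, False, ""

    matches: list[tuple[int, int]] = []  # (position, k)
    for m in _HOMO_NAMED.finditer(text):
        matches.append((m.start(), _GREEK_NAMES[m.group(1).lower()]))
    for m in _HOMO_NUMERIC.finditer(text):
        k = int(m.group(1))
        if k >= 1:
            matches.append((m.start(), k))
    for m in _MONOMER.finditer(text):
        matches.append((m.start(), 1))

    if not matches:
        if _HOMO_BARE.search(text):
            return None, True, "homo-oligomer without stated subunit number"
        return None, False, ""

    matches.sort()
    ks_in_order = [k for _, k in matches]
    if policy == "first":
        k = ks_in_order[0]
    elif policy == "min":
        k = min(ks_in_order)
    else:
        k = max(ks_in_order)
    distinct = sorted(set(ks_in_order))
    note = f"multiple states {distinct}" if len(distinct) > 1 else ""
    return k, True, note


_REQUIRED = ("protein_id", "length_aa")


def read_proteome_table(path, policy: str = "first") -> list[ProteinRecord]:
    """Read a proteome TSV into records.

    Requires ``protein_id``, ``length_aa`` and one of ``oligomer_k`` /
    ``subunit_annotation``. Malformed rows (non-positive length, oligomer_k of
    0, unparseable numbers) are counted and logged, not fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if "oligomer_k" not in df.columns and "subunit_annotation" not in df.columns:
        raise FormatError(
            f"need column 'oligomer_k' or 'subunit_annotation' in {path}"
        )

    records: list[ProteinRecord] = []
    malformed = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            length = int(d["length_aa"])
        except ValueError:
            malformed += 1
            continue
        if length < 1:
            malformed += 1
            continue

        k: Optional[int] = None
        is_homo = False
        note = ""
        raw_k = d.get("oligomer_k", "").strip()
        if raw_k:
            try:
                k = int(raw_k)
            except ValueError:
                malformed += 1
                continue
            if k < 1:
                malformed += 1
                continue
            is_homo = True
        else:
            k, is_homo, note = parse_subunit_annotation(
                d.get("subunit_annotation", ""), policy=policy
            )

        go_raw = d.get("go_terms", "").strip()
        go = frozenset(t for t in go_raw.split("|") if t) if go_raw else frozenset()
        ab_raw = d.get("abundance", "").strip()
        abundance = float(ab_raw) if ab_raw else None
        records.append(
            ProteinRecord(
                protein_id=d["protein_id"],
                organism=d.get("organism", ""),
                length_aa=length,
                oligomer_k=k,
                is_homo=is_homo,
                go_terms=go,
                abundance=abundance,
                ambiguity_note=note,
            )
        )
    if malformed:
        logger.warning("read_proteome_table: %d malformed rows skipped", malformed)
    return records


def write_proteome_table(records: Sequence[ProteinRecord], path) -> None:
    """Write records in the canonical proteome TSV schema (round-trips)."""
    rows = []
    for r in records:
        rows.append(
            {
                "protein_id": r.protein_id,
                "organism": r.organism,
                "length_aa": r.length_aa,
                "oligomer_k": "" if r.oligomer_k is None else r.oligomer_k,
                "subunit_annotation": "",
                "go_terms": "|".join(sorted(r.go_terms)),
                "abundance": "" if r.abundance is None else repr(r.abundance),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# STRING-style column names; only the two id columns are mandatory.
STRING_ID_COLS = ("ecoli_interaction_id_a", "ecoli_interaction_id_b")


def read_string_edges(path, score_min: float = 0.0) -> PPIGraph:
    """Read a STRING-style edge list into a simple undirected graph.

    Rows with ``score`` below ``score_min`` are dropped; (a, b)/(b, a)
    duplicates collapse to a single undirected edge; self-pairs are dropped
    and counted in ``G.graph['self_loops_dropped']``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_a, id_b = _resolve_id_columns(df.columns)
    if "score" in df.columns and score_min > 0:
        score = pd.to_numeric(df["score"], errors="coerce").fillna(0.0)
        df = df[score >= score_min]

    g: PPIGraph = nx.Graph()
    self_loops = 0
    for a, b in zip(df[id_a], df[id_b]):
        if a == b:
            self_loops += 1
            continue
        g.add_edge(a, b)
    g.graph["self_loops_dropped"] = self_loops
    return g


def _resolve_id_columns(columns) -> tuple[str, str]:
    cols = list(columns)
    if STRING_ID_COLS[0] in cols and STRING_ID_COLS[1] in cols:
        return STRING_ID_COLS
    # tolerate generic schemas
    for a, b in (("protein_a", "protein_b"), ("id_a", "id_b"), ("source", "target")):
        if a in cols and b in cols:
            return a, b
    raise FormatError(
        f"no interaction id columns found among {cols}; expected {STRING_ID_COLS}"
    )


def write_string_edges(graph: PPIGraph, path) -> None:
    """Write a graph in the six-column STRING-like TSV schema."""
    rows = [
        {
            "ecoli_interaction_id_a": a,
            "ecoli_interaction_id_b": b,
            "ecoli_interaction_mode": "binding",
            "ecoli_interaction_action": "",
            "a_is_acting": "f",
            "score": 500,
        }
        for a, b in graph.edges()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "ecoli_interaction_id_a",
            "ecoli_interaction_id_b",
            "ecoli_interaction_mode",
            "ecoli_interaction_action",
            "a_is_acting",
            "score",
        ],
    ).to_csv(path, sep="\t", index=False)
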