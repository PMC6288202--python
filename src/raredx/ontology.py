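"""Phenotype ontology parsing, indexing, information content and term weighting.

The ontology is a rooted DAG of terms connected by ``is_a`` edges.  On top of
it this module computes:

* annotation-frequency information content (IC): ``ic(t) = -ln(freq(t)/N)``
  where ``freq(t)`` counts diseases annotated to ``t`` or any descendant,
* the most informative common ancestor (MICA) of a term pair, and
* per-disease term weight rows (binary membership on the ancestor-propagated
  annotation set, scaled by IC) that serve as the disease feature vectors.

Only ``is_a`` edges are traversed; other relationship types are ignored.
Obsolete terms are kept out of the graph but resolvable through their
``replaced_by`` target, and ``alt_id`` aliases resolve to their primary term.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import InputError, LookupError_, StructuralError

TERM_ID_RE = re.compile(r"^[A-Za-z]+:[0-9]+$")


def is_term_id(value: str) -> bool:
    """True if ``value`` looks like ``PREFIX:NNNN``."""
    return bool(TERM_ID_RE.match(value))


@dataclass
class Term:
    term_id: str
    name: str = ""
    parents: frozenset[str] = frozenset()
    alt_ids: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """DAG of non-obsolete terms with child->parent ``is_a`` edges.

    ``aliases`` maps alt_ids and replaced-by sources to primary term ids.
    """

    terms: dict[str, Term] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _desc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._children:
            self._children = {t: set() for t in self.terms}
            for tid, term in self.terms.items():
                for p in term.parents:
                    self._children.setdefault(p, set()).add(tid)

    @property
    def roots(self) -> set[str]:
        return {t for t, term in self.terms.items() if not term.parents}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.aliases

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map a term id (primary, alt_id or obsolete-with-replacement) to its
        primary id; raise :class:`LookupError_` if it is unknown."""
        if term_id in self.terms:
            return term_id
        if term_id in self.aliases:
            return self.aliases[term_id]
        raise LookupError_(f"unknown term: {term_id!r}")

    def try_resolve(self, term_id: str) -> str | None:
        try:
            return self.resolve(term_id)
        except LookupError_:
            return None

    def parents_of(self, term_id: str) -> frozenset[str]:
        return self.terms[self.resolve(term_id)].parents

    def children_of(self, term_id: str) -> set[str]:
        return set(self._children.get(self.resolve(term_id), set()))

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive ``is_a`` closure toward the roots."""
        tid = self.resolve(term_id)
        closure = self._closure(tid)
        return set(closure) | {tid} if include_self else set(closure)

    def _closure(self, tid: str) -> frozenset[str]:
        cached = self._anc_cache.get(tid)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.terms[tid].parents)
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.terms[p].parents)
        result = frozenset(out)
        self._anc_cache[tid] = result
        return result

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        tid = self.resolve(term_id)
        cached = self._desc_cache.get(tid)
        if cached is None:
            out: set[str] = set()
            stack = list(self._children.get(tid, ()))
            while stack:
                c = stack.pop()
                if c not in out:
                    out.add(c)
                    stack.extend(self._children.get(c, ()))
            cached = frozenset(out)
            self._desc_cache[tid] = cached
        return set(cached) | {tid} if include_self else set(cached)

    def propagate(self, terms: Iterable[str]) -> set[str]:
        """Union of ancestor closures (self included) of resolvable terms."""
        out: set[str] = set()
        for t in terms:
            tid = self.resolve(t)
            out.add(tid)
            out |= self._closure(tid)
        return out


def parse_obo(stream: IO[str] | str) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Recognized tags inside ``[Term]`` stanzas: ``id``, ``name``, ``is_a``,
    ``alt_id``, ``is_obsolete``, ``replaced_by``.  Everything else (including
    non-``is_a`` relationships) is ignored.  Obsolete terms are dropped from
    the graph; when they carry ``replaced_by`` they remain resolvable as
    aliases of the replacement.

    Raises :class:`StructuralError` on an ``is_a`` cycle or an edge pointing
    at an unknown id.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    stanzas: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] | None = None
    in_term = False
    for raw in lines:
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = {} if in_term else None
            if in_term:
                stanzas.append(current)  # type: ignore[arg-type]
            continue
        if current is None or ":" not in line:
            continue
        tag, _, value = line.partition(":")
        current.setdefault(tag.strip(), []).append(value.strip())

    terms: dict[str, Term] = {}
    aliases: dict[str, str] = {}
    obsolete_repl: dict[str, str] = {}
    parents_raw: dict[str, set[str]] = {}
    for st in stanzas:
        ids = st.get("id", [])
        if not ids:
            continue
        tid = ids[0]
        if st.get("is_obsolete", ["false"])[0].lower() == "true":
            repl = st.get("replaced_by", [])
            if repl:
                obsolete_repl[tid] = repl[0]
            continue
        name = st.get("name", [""])[0]
        alt = tuple(st.get("alt_id", []))
        terms[tid] = Term(term_id=tid, name=name, alt_ids=alt)
        parents_raw[tid] = {v.split()[0] for v in st.get("is_a", [])}

    for tid, parents in parents_raw.items():
        for p in parents:
            if p not in terms:
                raise StructuralError(f"is_a target {p!r} of {tid!r} is not a known term")
        terms[tid] = Term(
            term_id=tid,
            name=terms[tid].name,
            parents=frozenset(parents),
            alt_ids=terms[tid].alt_ids,
        )

    _check_acyclic(terms)

    for tid, term in terms.items():
        for alt in term.alt_ids:
            aliases[alt] = tid
    for old, new in obsolete_repl.items():
        target = aliases.get(new, new)
        if target in terms:
            aliases[old] = target

    return OntologyGraph(terms=terms, aliases=aliases)


def _check_acyclic(terms: dict[str, Term]) -> None:
    # Kahn's algorithm on child->parent edges; leftovers form a cycle.
    out_deg = {t: len(term.parents) for t, term in terms.items()}
    children: dict[str, list[str]] = {t: [] for t in terms}
    for tid, term in terms.items():
        for p in term.parents:
            children[p].append(tid)
    queue = [t for t, d in out_deg.items() if d == 0]
    seen = 0
    while queue:
        node = queue.pop()
        seen += 1
        for c in children[node]:
            out_deg[c] -= 1
            if out_deg[c] == 0:
                queue.append(c)
    if seen != len(terms):
        member = sorted(t for t, d in out_deg.items() if d > 0)[0]
        raise StructuralError(f"is_a cycle detected involving {member!r}")


@dataclass
class InformationContentTable:
    """Per-term IC in nats, derived from disease annotation frequencies."""

    ic: dict[str, float]
    n_diseases: int

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)

    def max_ic(self, terms: Iterable[str] | None = None) -> float:
        pool = self.ic.values() if terms is None else (self.ic.get(t, 0.0) for t in terms)
        return max(pool, default=0.0)


def compute_ic(graph: OntologyGraph, kb) -> InformationContentTable:
    """Annotation-frequency IC over every graph term.

    ``freq(t)`` counts the kb diseases whose ancestor-propagated annotation
    set contains ``t``; ``ic(t) = -ln(max(freq(t), 1) / N)``.  The floor of 1
    keeps unannotated terms finite and scorable (they get the rarest observed
    level, ``ln N``).
    """
    disease_ids = kb.disease_ids()
    n = len(disease_ids)
    if n == 0:
        raise InputError("knowledge base has no diseases")
    freq: dict[str, int] = {t: 0 for t in graph.terms}
    for did in disease_ids:
        for t in graph.propagate(kb.phenotypes_of(did)):
            freq[t] += 1
    ic = {t: -math.log(max(f, 1) / n) for t, f in freq.items()}
    return InformationContentTable(ic=ic, n_diseases=n)


def mica(
    graph: OntologyGraph, ic: InformationContentTable, t1: str, t2: str
) -> tuple[str | None, float]:
    """Most informative common ancestor of two terms and its IC.

    Ancestor sets include the terms themselves.  Ties break on the
    lexicographically smallest term id; no common ancestor (disjoint root
    subtrees in a multi-root graph) yields ``(None, 0.0)``.
    """
    a1 = graph.ancestors(t1, include_self=True)
    a2 = graph.ancestors(t2, include_self=True)
    common = a1 & a2
    if not common:
        return None, 0.0
    best = min(common, key=lambda t: (-ic.get(t, 0.0), t))
    return best, ic.get(best, 0.0)


@dataclass
class WeightMatrix:
    """Sparse disease x term weight rows over a fixed, ordered vocabulary."""

    vocabulary: list[str]
    rows: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.vocabulary)}

    def row(self, disease_id: str) -> dict[str, float]:
        if disease_id not in self.rows:
            raise LookupError_(f"unknown disease: {disease_id!r}")
        return self.rows[disease_id]


def tfidf_hierarchy_weights(
    graph: OntologyGraph, kb, ic: InformationContentTable
) -> WeightMatrix:
    """Disease feature rows: ancestor-propagated membership scaled by IC.

    Each disease's annotation set is propagated to all ancestors; a term in
    the propagated set gets weight ``ic(term)``, everything else 0.  The
    vocabulary is the sorted set of terms with a nonzero weight for at least
    one disease (terms with zero IC, e.g. the root, never enter it).
    """
    rows: dict[str, dict[str, float]] = {}
    vocab: set[str] = set()
    for did in kb.disease_ids():
        propagated = graph.propagate(kb.phenotypes_of(did))
        row = {t: ic[t] for t in propagated if ic[t] > 0.0}
        rows[did] = row
        vocab |= row.keys()
    return WeightMatrix(vocabulary=sorted(vocab), rows=rows)
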