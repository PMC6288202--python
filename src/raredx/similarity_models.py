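"""Similarity-based candidate ranking.

Two models live here:

* the term-space model ("pics"): cosine and Tanimoto over IC-weighted
  disease/query vectors, a set-mismatch score, and symmetric best-match
  MICA similarity — four classifier scores combined by weighted averaging;
* the gene-space model ("pgas"): per-phenotype-pair similarity through
  binary gene incidence vectors, lifted to disease level by symmetric
  best-match averaging, under cosine and Tanimoto metrics.

Ties in every ranking break on the lexicographically smaller disease id so
outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import ensemble as ens
from .errors import InputError
from .knowledge_base import DiseasePhenotypeKB, PhenotypeGeneMap, query_vector
from .ontology import InformationContentTable, OntologyGraph, WeightMatrix, mica

SparseVec = dict[str, float]


@dataclass
class RankedResult:
    """Candidate diseases in descending score order."""

    items: list[tuple[str, float]]
    query_terms: list[str] = field(default_factory=list)
    model: str = ""

    def rank_of(self, disease_id: str) -> int | None:
        """1-based rank of a disease, or None if absent."""
        for i, (d, _) in enumerate(self.items, start=1):
            if d == disease_id:
                return i
        return None

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.items[:k]

    def abstained(self) -> bool:
        """True when no candidate received a positive score."""
        return not self.items or all(s <= 0.0 for _, s in self.items)


def _sort_items(scores: dict[str, float]) -> list[tuple[str, float]]:
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def _dot(a: SparseVec, b: SparseVec) -> float:
    if len(a) > len(b):
        a, b = b, a
    return sum(v * b[k] for k, v in a.items() if k in b)


def _norm_sq(a: SparseVec) -> float:
    return sum(v * v for v in a.values())


def cosine_similarity(a: SparseVec, b: SparseVec) -> float:
    """a.b / (|a||b|); 0 when either vector is all-zero."""
    na, nb = _norm_sq(a), _norm_sq(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return _dot(a, b) / math.sqrt(na * nb)


def tanimoto(a: SparseVec, b: SparseVec) -> float:
    """a.b / (|a|^2 + |b|^2 - a.b); 0 when both vectors are all-zero."""
    dot = _dot(a, b)
    denom = _norm_sq(a) + _norm_sq(b) - dot
    if denom == 0.0:
        return 0.0
    return dot / denom


def psi_score(query: set[str], disease_terms: set[str]) -> float:
    """1 - |symmetric difference| / max(|query|, |disease|), clamped to [0,1].

    The raw value goes negative for mostly-disjoint sets; clamping keeps the
    score commensurable with the other [0,1] classifiers.
    """
    if not query or not disease_terms:
        raise InputError("psi_score requires two non-empty term sets")
    n = len(query ^ disease_terms)
    raw = 1.0 - n / max(len(query), len(disease_terms))
    return min(1.0, max(0.0, raw))


def mica_similarity_directed(
    from_set: set[str],
    to_set: set[str],
    graph: OntologyGraph,
    ic: InformationContentTable,
) -> float:
    """Mean over ``from_set`` of the best-match IC(MICA) into ``to_set``."""
    if not from_set or not to_set:
        raise InputError("MICA similarity requires two non-empty term sets")
    total = 0.0
    for t in from_set:
        total += max(mica(graph, ic, t, s)[1] for s in to_set)
    return total / len(from_set)


def mica_similarity_symmetric(
    a: set[str], b: set[str], graph: OntologyGraph, ic: InformationContentTable
) -> float:
    """Average of the two directed best-match MICA similarities."""
    return 0.5 * mica_similarity_directed(a, b, graph, ic) + 0.5 * mica_similarity_directed(
        b, a, graph, ic
    )


def gene_vector(term: str, gm: PhenotypeGeneMap) -> SparseVec:
    """Binary gene incidence vector of one phenotype term."""
    return {g: 1.0 for g in gm.get(term)}


def pgas_phenotype_similarity(
    p1: str, p2: str, gm: PhenotypeGeneMap, metric: str = "cosine"
) -> float:
    """Similarity of two phenotypes through their gene incidence vectors."""
    a, b = gene_vector(p1, gm), gene_vector(p2, gm)
    if metric == "cosine":
        return cosine_similarity(a, b)
    if metric == "tanimoto":
        return tanimoto(a, b)
    raise InputError(f"unknown metric: {metric!r}")


def pgas_disease_score(
    query: set[str], disease_terms: set[str], gm: PhenotypeGeneMap, metric: str = "cosine"
) -> float:
    """Symmetric best-match average of per-phenotype gene-vector similarity."""
    if not query or not disease_terms:
        raise InputError("pgas_disease_score requires two non-empty term sets")

    def directed(src: set[str], dst: set[str]) -> float:
        return sum(
            max(pgas_phenotype_similarity(t, s, gm, metric) for s in dst) for t in src
        ) / len(src)

    return 0.5 * directed(query, disease_terms) + 0.5 * directed(disease_terms, query)


def _resolve_query(query: Sequence[str], graph: OntologyGraph) -> set[str]:
    resolved = {r for t in query if (r := graph.try_resolve(t)) is not None}
    if not resolved:
        raise InputError("no query term resolves in the ontology")
    return resolved


def rank_pics(
    query: Sequence[str],
    kb: DiseasePhenotypeKB,
    graph: OntologyGraph,
    ic: InformationContentTable,
    wm: WeightMatrix,
    weights: Sequence[float] | None = None,
) -> RankedResult:
    """Rank every KB disease by the four term-space classifier scores.

    Classifiers: cosine and Tanimoto on IC-weighted propagated vectors,
    the set-mismatch score, and max-IC-normalized symmetric MICA similarity.
    ``weights`` (default uniform) weight the four classifiers in the
    combined average.
    """
    resolved = _resolve_query(query, graph)
    qv, _ = query_vector(resolved, graph, ic, wm.vocabulary)
    ic_cap = ic.max_ic(wm.vocabulary)

    cos_scores: dict[str, float] = {}
    tan_scores: dict[str, float] = {}
    psi_scores: dict[str, float] = {}
    mica_scores: dict[str, float] = {}
    for did in kb.disease_ids():
        dv = wm.row(did)
        dterms = kb.phenotypes_of(did)
        cos_scores[did] = cosine_similarity(qv, dv)
        tan_scores[did] = tanimoto(qv, dv)
        psi_scores[did] = psi_score(resolved, dterms)
        raw_mica = mica_similarity_symmetric(resolved, dterms, graph, ic)
        mica_scores[did] = raw_mica / ic_cap if ic_cap > 0 else 0.0

    member_maps = [cos_scores, tan_scores, psi_scores, mica_scores]
    if weights is None:
        weights = [1.0] * len(member_maps)
    combined = ens.bayesian_average(
        [(ens.normalize_scores(m), w) for m, w in zip(member_maps, weights, strict=True)]
    )
    return RankedResult(
        items=_sort_items(combined.scores), query_terms=sorted(resolved), model="pics"
    )


def rank_pgas(
    query: Sequence[str],
    kb: DiseasePhenotypeKB,
    graph: OntologyGraph,
    gm: PhenotypeGeneMap,
    weights: Sequence[float] | None = None,
) -> RankedResult:
    """Rank every KB disease by gene-space similarity under both metrics."""
    resolved = _resolve_query(query, graph)
    cos_scores: dict[str, float] = {}
    tan_scores: dict[str, float] = {}
    for did in kb.disease_ids():
        dterms = kb.phenotypes_of(did)
        cos_scores[did] = pgas_disease_score(resolved, dterms, gm, "cosine")
        tan_scores[did] = pgas_disease_score(resolved, dterms, gm, "tanimoto")

    member_maps = [cos_scores, tan_scores]
    if weights is None:
        weights = [1.0] * len(member_maps)
    combined = ens.bayesian_average(
        [(ens.normalize_scores(m), w) for m, w in zip(member_maps, weights, strict=True)]
    )
    return RankedResult(
        items=_sort_items(combined.scores), query_terms=sorted(resolved), model="pgas"
    )


def ranked_result_to_tsv(result: RankedResult, kb: DiseasePhenotypeKB | None = None) -> str:
    lines = ["rank\tdisease_id\tname\tscore"]
    for i, (did, score) in enumerate(result.items, start=1):
        name = kb.name_of(did) if kb is not None and did in kb else ""
        lines.append(f"{i}\t{did}\t{name}\t{score:.12g}")
    return "\n".join(lines) + "\n"


def ranked_result_to_json(result: RankedResult) -> dict:
    return {
        "model": result.model,
        "query_terms": list(result.query_terms),
        "items": [{"rank": i, "disease_id": d, "score": s} for i, (d, s) in enumerate(result.items, 1)],
    }


def pics_classifier_scores(
    query: Iterable[str],
    kb: DiseasePhenotypeKB,
    graph: OntologyGraph,
    ic: InformationContentTable,
    wm: WeightMatrix,
) -> dict[str, dict[str, float]]:
    """Raw (unnormalized-for-averaging) per-classifier score maps, exposed for
    inspection and tests; mirrors the maps used inside :func:`rank_pics`."""
    resolved = _resolve_query(list(query), graph)
    qv, _ = query_vector(resolved, graph, ic, wm.vocabulary)
    ic_cap = ic.max_ic(wm.vocabulary)
    out: dict[str, dict[str, float]] = {"cosine": {}, "tanimoto": {}, "psi": {}, "mica": {}}
    for did in kb.disease_ids():
        dv = wm.row(did)
        dterms = kb.phenotypes_of(did)
        out["cosine"][did] = cosine_similarity(qv, dv)
        out["tanimoto"][did] = tanimoto(qv, dv)
        out["psi"][did] = psi_score(resolved, dterms)
        raw = mica_similarity_symmetric(resolved, dterms, graph, ic)
        out["mica"][did] = raw / ic_cap if ic_cap > 0 else 0.0
    return out
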