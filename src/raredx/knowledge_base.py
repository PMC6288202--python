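"""Disease-phenotype and phenotype-gene association loading and indexing.

Readers accept the classic ``phenotype_annotation.tab`` TSV dialect
(``DB, DB_Object_ID, DB_Name, Qualifier, HPO_ID, ...``) and a two-column
``term<TAB>gene`` TSV.  The knowledge base exposes each disease's phenotype
set filtered by provenance mode: ``curated_only`` or
``curated_plus_textmined``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import ConsistencyError, InputError, LookupError_, ParseError
from .ontology import InformationContentTable, OntologyGraph, WeightMatrix

CURATED = "curated"
TEXT_MINED = "text_mined"
MODE_CURATED = "curated_only"
MODE_ALL = "curated_plus_textmined"


@dataclass
class DiseaseRecord:
    disease_id: str
    name: str = ""
    phenotypes: dict[str, str] = field(default_factory=dict)  # term -> provenance
    genes: set[str] = field(default_factory=set)


@dataclass
class PhenotypeGeneMap:
    genes_of: dict[str, set[str]] = field(default_factory=dict)

    @property
    def gene_universe(self) -> list[str]:
        universe: set[str] = set()
        for genes in self.genes_of.values():
            universe |= genes
        return sorted(universe)

    def get(self, term_id: str) -> set[str]:
        return self.genes_of.get(term_id, set())


@dataclass
class DiseasePhenotypeKB:
    """Indexed disease records with a provenance-filtering mode."""

    diseases: dict[str, DiseaseRecord]
    mode: str = MODE_CURATED

    def __post_init__(self) -> None:
        if self.mode not in (MODE_CURATED, MODE_ALL):
            raise InputError(f"unknown KB mode: {self.mode!r}")

    def disease_ids(self) -> list[str]:
        return sorted(self.diseases)

    def __len__(self) -> int:
        return len(self.diseases)

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.diseases

    def name_of(self, disease_id: str) -> str:
        return self._record(disease_id).name

    def _record(self, disease_id: str) -> DiseaseRecord:
        if disease_id not in self.diseases:
            raise LookupError_(f"unknown disease: {disease_id!r}")
        return self.diseases[disease_id]

    def phenotypes_of(self, disease_id: str) -> set[str]:
        """Exposed phenotype term set under the current mode."""
        rec = self._record(disease_id)
        if self.mode == MODE_ALL:
            return set(rec.phenotypes)
        return {t for t, prov in rec.phenotypes.items() if prov == CURATED}

    @property
    def term_universe(self) -> set[str]:
        out: set[str] = set()
        for did in self.diseases:
            out |= self.phenotypes_of(did)
        return out


def read_hpo_annotations(
    stream: IO[str] | str, graph: OntologyGraph
) -> list[tuple[str, str, str, str]]:
    """Parse annotation rows into ``(disease_id, name, term_id, qualifier)``.

    ``disease_id`` is ``DB:DB_Object_ID``.  Rows qualified ``NOT`` are
    dropped, term ids are resolved through the alias map, duplicates are
    collapsed, and rows with unresolvable terms are skipped with a single
    summary warning.
    """
    text = stream if isinstance(stream, str) else stream.read()
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str, str, str]] = []
    skipped = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise ParseError(f"expected >=5 tab-separated columns, got {len(cols)}", lineno)
        db, obj_id, name, qualifier, hpo_id = (c.strip() for c in cols[:5])
        if qualifier.upper() == "NOT":
            continue
        term = graph.try_resolve(hpo_id)
        if term is None:
            skipped += 1
            continue
        disease_id = f"{db}:{obj_id}"
        key = (disease_id, term)
        if key in seen:
            continue
        seen.add(key)
        out.append((disease_id, name, term, qualifier))
    if skipped:
        warnings.warn(f"skipped {skipped} annotation row(s) with unresolvable term ids")
    return out


def read_gene_associations(stream: IO[str] | str, graph: OntologyGraph) -> PhenotypeGeneMap:
    """Parse ``term<TAB>gene`` rows into a deduplicated phenotype-gene map."""
    text = stream if isinstance(stream, str) else stream.read()
    genes_of: dict[str, set[str]] = {}
    skipped = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise ParseError(f"expected 2 tab-separated columns, got {len(cols)}", lineno)
        term_raw, gene = cols[0].strip(), cols[1].strip()
        term = graph.try_resolve(term_raw)
        if term is None:
            skipped += 1
            continue
        genes_of.setdefault(term, set()).add(gene)
    if skipped:
        warnings.warn(f"skipped {skipped} gene-association row(s) with unresolvable term ids")
    return PhenotypeGeneMap(genes_of=genes_of)


def build_kb(
    curated: Iterable[tuple[str, str, str, str]],
    text_mined: Iterable[tuple[str, str, str, str]] = (),
    mode: str = MODE_CURATED,
) -> DiseasePhenotypeKB:
    """Assemble a KB from curated and optional text-mined association rows.

    A term annotated both ways keeps the curated provenance.  Diseases whose
    exposed phenotype set is empty under ``mode`` are dropped (with a
    warning tallying how many).
    """
    if mode not in (MODE_CURATED, MODE_ALL):
        raise InputError(f"unknown KB mode: {mode!r}")
    diseases: dict[str, DiseaseRecord] = {}

    def _add(rows: Iterable[tuple[str, str, str, str]], provenance: str) -> None:
        for disease_id, name, term, _qualifier in rows:
            rec = diseases.setdefault(disease_id, DiseaseRecord(disease_id, name))
            if name and not rec.name:
                rec.name = name
            if term not in rec.phenotypes or provenance == CURATED:
                rec.phenotypes[term] = provenance

    _add(curated, CURATED)
    _add(text_mined, TEXT_MINED)

    kb = DiseasePhenotypeKB(diseases=diseases, mode=mode)
    empty = [d for d in list(diseases) if not kb.phenotypes_of(d)]
    for d in empty:
        del diseases[d]
    if empty:
        warnings.warn(f"dropped {len(empty)} disease(s) with no exposed phenotypes")
    return kb


def disease_vector(
    kb: DiseasePhenotypeKB, disease_id: str, wm: WeightMatrix
) -> dict[str, float]:
    """The disease's sparse weight row (term -> weight) from ``wm``."""
    if disease_id not in kb:
        raise LookupError_(f"unknown disease: {disease_id!r}")
    return dict(wm.row(disease_id))


def query_vector(
    terms: Iterable[str],
    graph: OntologyGraph,
    ic: InformationContentTable,
    vocabulary: Iterable[str],
) -> tuple[dict[str, float], int]:
    """IC-weighted, ancestor-propagated sparse vector for a term query.

    Returns ``(entries, n_dropped)`` where ``n_dropped`` counts query terms
    that did not resolve in the ontology.  Raises :class:`InputError` when no
    term resolves at all.
    """
    vocab = set(vocabulary)
    resolved: list[str] = []
    dropped = 0
    for t in terms:
        r = graph.try_resolve(t)
        if r is None:
            dropped += 1
        else:
            resolved.append(r)
    if not resolved:
        raise InputError("no query term resolves in the ontology")
    propagated = graph.propagate(resolved)
    entries = {t: ic[t] for t in propagated if t in vocab and ic[t] > 0.0}
    return entries, dropped


def kb_to_json(kb: DiseasePhenotypeKB) -> str:
    """Serialize a KB snapshot (order-insensitive, reload-equal)."""
    payload = {
        "mode": kb.mode,
        "diseases": [
            {
                "disease_id": rec.disease_id,
                "name": rec.name,
                "phenotypes": {t: rec.phenotypes[t] for t in sorted(rec.phenotypes)},
                "genes": sorted(rec.genes),
            }
            for rec in (kb.diseases[d] for d in kb.disease_ids())
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def kb_from_json(text: str) -> DiseasePhenotypeKB:
    payload = json.loads(text)
    diseases = {
        d["disease_id"]: DiseaseRecord(
            disease_id=d["disease_id"],
            name=d.get("name", ""),
            phenotypes=dict(d.get("phenotypes", {})),
            genes=set(d.get("genes", ())),
        )
        for d in payload["diseases"]
    }
    return DiseasePhenotypeKB(diseases=diseases, mode=payload.get("mode", MODE_CURATED))


def check_same_diseases(kb: DiseasePhenotypeKB, wm: WeightMatrix) -> None:
    """Guard that a weight matrix was built over this KB's disease set."""
    if set(kb.disease_ids()) != set(wm.rows):
        raise ConsistencyError("weight matrix disease set does not match the KB")
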