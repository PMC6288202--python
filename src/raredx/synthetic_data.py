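"""Deterministic fixture generators: ontologies, knowledge bases, gene maps
and patient cohorts with controlled statistical structure.

Everything is reproducible from a :class:`SyntheticSpec` plus its seed, and
every emitted file is a valid input to the corresponding reader, so the full
pipeline is testable without external downloads.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .knowledge_base import (
    CURATED,
    MODE_CURATED,
    TEXT_MINED,
    DiseasePhenotypeKB,
    DiseaseRecord,
    PhenotypeGeneMap,
)
from .ml_models import PatientRecord, generate_training_patients
from .ontology import OntologyGraph, parse_obo

TERM_PREFIX = "SYN"
DISEASE_DB = "RD"


@dataclass
class SyntheticSpec:
    """Knobs for the generators; defaults are desk-scale (seconds, not minutes)."""

    n_terms: int = 300
    depth: int = 5
    branching: int = 4
    n_diseases: int = 50
    terms_per_disease: tuple[int, int] = (5, 12)
    n_genes: int = 200
    genes_per_term: tuple[int, int] = (1, 10)
    dropout: float = 0.2
    noise_rate: float = 2.0
    patients_per_disease: int = 10
    textmined_per_disease: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_terms", "depth", "branching", "n_diseases", "n_genes",
                     "patients_per_disease"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise InputError("dropout must be in [0, 1)")
        if self.noise_rate < 0.0:
            raise InputError("noise_rate must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)


def _term_id(i: int) -> str:
    return f"{TERM_PREFIX}:{i:07d}"


def _disease_id(i: int) -> str:
    return f"{DISEASE_DB}:{i:05d}"


def make_toy_ontology(spec: SyntheticSpec) -> tuple[OntologyGraph, str]:
    """Build a rooted DAG level by level and emit it as OBO text.

    Each non-root term gets one parent drawn from the previous level and a
    second distinct parent (same level) with probability 0.2.  The OBO text
    round-trips through the parser to an equal graph.
    """
    capacity = sum(spec.branching**d for d in range(spec.depth))
    if capacity < spec.n_terms:
        raise InputError(
            f"cannot place {spec.n_terms} terms in depth {spec.depth} "
            f"with branching {spec.branching} (capacity {capacity})"
        )
    rng = np.random.default_rng([spec.seed, 1])
    levels: list[list[int]] = [[1]]
    next_id = 2
    parents: dict[int, set[int]] = {}
    while next_id <= spec.n_terms:
        prev = levels[-1]
        level: list[int] = []
        cap = len(prev) * spec.branching
        while next_id <= spec.n_terms and len(level) < cap:
            tid = next_id
            next_id += 1
            p1 = prev[int(rng.integers(len(prev)))]
            ps = {p1}
            if len(prev) > 1 and rng.random() < 0.2:
                p2 = prev[int(rng.integers(len(prev)))]
                ps.add(p2)
            parents[tid] = ps
            level.append(tid)
        levels.append(level)

    lines = ["format-version: 1.2", ""]
    for i in range(1, spec.n_terms + 1):
        lines.append("[Term]")
        lines.append(f"id: {_term_id(i)}")
        lines.append(f"name: synthetic term {i}")
        for p in sorted(parents.get(i, ())):
            lines.append(f"is_a: {_term_id(p)} ! synthetic term {p}")
        lines.append("")
    obo_text = "\n".join(lines)
    return parse_obo(obo_text), obo_text


def make_toy_kb(
    graph: OntologyGraph,
    spec: SyntheticSpec,
    disjoint_support: bool = False,
    mode: str = MODE_CURATED,
) -> DiseasePhenotypeKB:
    """Draw per-disease annotation sets from the ontology's non-root terms.

    Sampling is leaf-biased (probability proportional to 1/(1 + number of
    descendants)) which mirrors the practice of annotating specific terms.
    With ``disjoint_support`` the non-root terms are partitioned so
    annotation sets are pairwise disjoint (for separability tests).
    ``textmined_per_disease`` in the spec adds extra terms flagged as
    text-mined provenance.
    """
    lo, hi = spec.terms_per_disease
    if not (1 <= lo <= hi):
        raise InputError("terms_per_disease bounds must satisfy 1 <= min <= max")
    non_root = sorted(set(graph.terms) - graph.roots)
    if hi > len(non_root):
        raise InputError(
            f"terms_per_disease max {hi} exceeds available non-root terms ({len(non_root)})"
        )
    rng = np.random.default_rng([spec.seed, 2])
    weights = np.array([1.0 / (1 + len(graph.descendants(t))) for t in non_root])
    weights = weights / weights.sum()

    tm_lo, tm_hi = spec.textmined_per_disease
    diseases: dict[str, DiseaseRecord] = {}
    if disjoint_support:
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_diseases)]
        if sum(sizes) + (tm_hi * spec.n_diseases) > len(non_root):
            raise InputError("not enough terms for disjoint annotation supports")
        perm = [non_root[i] for i in rng.permutation(len(non_root))]
        cursor = 0
        for i in range(1, spec.n_diseases + 1):
            did = _disease_id(i)
            size = sizes[i - 1]
            chosen = perm[cursor : cursor + size]
            cursor += size
            n_tm = int(rng.integers(tm_lo, tm_hi + 1)) if tm_hi else 0
            tm = perm[cursor : cursor + n_tm]
            cursor += n_tm
            phen = {t: CURATED for t in chosen}
            phen.update({t: TEXT_MINED for t in tm})
            diseases[did] = DiseaseRecord(did, f"synthetic disease {i}", phen)
    else:
        for i in range(1, spec.n_diseases + 1):
            did = _disease_id(i)
            size = int(rng.integers(lo, hi + 1))
            idx = rng.choice(len(non_root), size=size, replace=False, p=weights)
            chosen = {non_root[j] for j in idx}
            phen = {t: CURATED for t in sorted(chosen)}
            if tm_hi:
                n_tm = int(rng.integers(tm_lo, tm_hi + 1))
                pool = [t for t in non_root if t not in chosen]
                if n_tm > 0 and pool:
                    idx2 = rng.choice(len(pool), size=min(n_tm, len(pool)), replace=False)
                    for j in idx2:
                        phen[pool[j]] = TEXT_MINED
            diseases[did] = DiseaseRecord(did, f"synthetic disease {i}", phen)
    return DiseasePhenotypeKB(diseases=diseases, mode=mode)


def make_gene_map(graph: OntologyGraph, spec: SyntheticSpec) -> PhenotypeGeneMap:
    """Attach each non-root term to a random draw from the gene pool."""
    lo, hi = spec.genes_per_term
    if not (1 <= lo <= hi <= spec.n_genes):
        raise InputError("genes_per_term bounds must satisfy 1 <= min <= max <= n_genes")
    rng = np.random.default_rng([spec.seed, 3])
    pool = [f"GENE{i:05d}" for i in range(1, spec.n_genes + 1)]
    genes_of: dict[str, set[str]] = {}
    for t in sorted(set(graph.terms) - graph.roots):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(spec.n_genes, size=size, replace=False)
        genes_of[t] = {pool[j] for j in idx}
    return PhenotypeGeneMap(genes_of=genes_of)


def make_patient_cohort(
    kb: DiseasePhenotypeKB,
    spec: SyntheticSpec,
    target_mean_terms: float | None = None,
    per_disease: int | None = None,
) -> list[PatientRecord]:
    """EMR-like test cohort via the training-patient mechanics.

    When ``target_mean_terms`` is set, dropout is tuned so the expected
    record size (kept terms + noise) approximately matches the target; an
    unattainable target falls back to dropout 0 with a warning.
    """
    dropout = spec.dropout
    if target_mean_terms is not None:
        mean_size = float(
            np.mean([len(kb.phenotypes_of(d)) for d in kb.disease_ids()])
        )
        achievable_max = mean_size + spec.noise_rate
        if target_mean_terms > achievable_max:
            warnings.warn(
                f"target mean {target_mean_terms} exceeds attainable {achievable_max:.2f}; "
                "using dropout=0"
            )
            dropout = 0.0
        else:
            dropout = 1.0 - (target_mean_terms - spec.noise_rate) / mean_size
            dropout = min(max(dropout, 0.0), 0.999)
    return generate_training_patients(
        kb,
        per_disease=per_disease if per_disease is not None else spec.patients_per_disease,
        dropout=dropout,
        noise_rate=spec.noise_rate,
        seed=spec.seed + 10_000,
        source="synthetic_test",
    )


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def emit_annotations_tsv(kb: DiseasePhenotypeKB) -> tuple[str, str]:
    """KB as two annotation TSVs (curated, text-mined) in the classic
    ``DB, DB_Object_ID, DB_Name, Qualifier, HPO_ID`` dialect."""
    curated_lines = ["#DB\tDB_Object_ID\tDB_Name\tQualifier\tHPO_ID"]
    tm_lines = ["#DB\tDB_Object_ID\tDB_Name\tQualifier\tHPO_ID"]
    for did in kb.disease_ids():
        rec = kb.diseases[did]
        db, _, obj = did.partition(":")
        for term in sorted(rec.phenotypes):
            row = f"{db}\t{obj}\t{rec.name}\t\t{term}"
            if rec.phenotypes[term] == CURATED:
                curated_lines.append(row)
            else:
                tm_lines.append(row)
    return "\n".join(curated_lines) + "\n", "\n".join(tm_lines) + "\n"


def emit_gene_tsv(gm: PhenotypeGeneMap) -> str:
    lines = [
        f"{t}\t{g}"
        for t in sorted(gm.genes_of)
        for g in sorted(gm.genes_of[t])
    ]
    return "\n".join(lines) + "\n"


def emit_patients_json(cohort: list[PatientRecord]) -> str:
    return json.dumps(
        [
            {
                "patient_id": p.patient_id,
                "phenotypes": list(p.phenotypes),
                "true_disease": p.true_disease,
                "source": p.source,
            }
            for p in cohort
        ],
        indent=1,
    )


def read_patients_json(text: str) -> list[PatientRecord]:
    return [
        PatientRecord(
            patient_id=d["patient_id"],
            phenotypes=list(d["phenotypes"]),
            true_disease=d.get("true_disease"),
            source=d.get("source", "emr"),
        )
        for d in json.loads(text)
    ]


def write_fixture_bundle(
    path: str | Path,
    graph_obo: str,
    kb: DiseasePhenotypeKB,
    gm: PhenotypeGeneMap,
    cohort: list[PatientRecord],
    spec: SyntheticSpec | None = None,
) -> dict:
    """Write OBO + annotation TSVs + gene TSV + patients JSON + manifest.

    Returns the manifest (also written as ``manifest.json``) with content
    hashes so identical seeds yield identical bundles.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    curated_tsv, tm_tsv = emit_annotations_tsv(kb)
    files = {
        "ontology.obo": graph_obo,
        "annotations.tab": curated_tsv,
        "annotations_textmined.tab": tm_tsv,
        "genes.tsv": emit_gene_tsv(gm),
        "patients.json": emit_patients_json(cohort),
    }
    for name, content in files.items():
        (path / name).write_text(content)
    manifest = {
        "spec": spec.as_dict() if spec is not None else None,
        "files": {name: _sha256(content) for name, content in files.items()},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
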