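# raredx

Phenotype-driven rare-disease candidate ranking. Given a phenotype ontology
(OBO), disease–phenotype annotations and an optional phenotype–gene map, the
package ranks candidate diseases for a patient's phenotype term list with
four models and evaluates rankings with top-k metrics:

- **pics** — term-space similarity: cosine and Tanimoto over IC-weighted,
  ancestor-propagated disease/query vectors, a set-mismatch score, and
  symmetric best-match MICA (most-informative-common-ancestor) similarity,
  combined by a weighted score average.
- **pgas** — gene-space similarity: phenotype pairs are compared through
  binary gene incidence vectors (cosine / Tanimoto), lifted to disease level
  by symmetric best-match averaging.
- **cpml / apml** — classifier ensembles (logistic regression, k-NN, random
  forest, extra trees, naive Bayes, MLP) trained on synthetic patients
  simulated from the knowledge base; `apml` additionally uses text-mined
  annotations. Member predictions are combined by a validation-accuracy-
  weighted convex average.

A synthetic-data module generates reproducible ontologies, knowledge bases,
gene maps and noisy patient cohorts, so the whole pipeline runs end to end
with no external downloads.

## CLI

```sh
# 1. generate a synthetic fixture bundle (ontology, annotations, genes, patients)
raredx simulate --out bundle/ --seed 7

# 2. build the knowledge base + term weight matrix
raredx build-kb --ontology bundle/ontology.obo --annotations bundle/annotations.tab \
    --gene-map bundle/genes.tsv --out kb/

# 3. train the classifier ensemble (cpml/apml models)
raredx train --kb kb/ --out ens/ --classifiers logistic_regression,naive_bayes,random_forest

# 4. rank candidates for a query or a patient file
raredx rank --kb kb/ --model pics --terms SYN:0000042,SYN:0000108 --top-k 10
raredx rank --kb kb/ --model cpml --ensemble ens/ --patients bundle/patients.json

# 5. evaluate a labelled cohort (metrics JSON, confusion TSV, rank distribution)
raredx evaluate --kb kb/ --model pics --patients bundle/patients.json --out eval/
```

Every command writes a `run_manifest.json` (config, seed, input hashes);
re-running with identical inputs reproduces identical outputs. Exit codes:
0 success, 1 runtime/data error, 2 usage error.

## Library quick start

```python
from raredx.ontology import compute_ic, parse_obo, tfidf_hierarchy_weights
from raredx.knowledge_base import build_kb, read_hpo_annotations
from raredx.similarity_models import rank_pics

graph = parse_obo(open("hp.obo").read())
kb = build_kb(read_hpo_annotations(open("phenotype_annotation.tab").read(), graph))
ic = compute_ic(graph, kb)
wm = tfidf_hierarchy_weights(graph, kb, ic)
result = rank_pics(["HP:0001250", "HP:0001263"], kb, graph, ic, wm)
print(result.top(10))
```

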