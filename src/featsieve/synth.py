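"""Synthetic study-world generators.

Real cohort data (UK Biobank-like feature tables), biomedical knowledge
graphs (SemMedDB-like triple dumps) and literature hit counts are all
license-restricted.  This module generates structurally faithful stand-ins
at toy scale so every stage of the cascade runs and can be validated
offline:

* a participant table whose binary target follows a logistic model over
  planted features and baseline-covariate confounders, with MCAR
  missingness,
* a triple file with citation counts and first-report years, where chosen
  feature-target associations are "known" edges and the rest is random
  background,
* a deterministic term/pair hit-count table consumable by the literature
  filter's provider interface,
* an entity lexicon and a scripted LLM provider wired to the ground truth.

Ground truth per feature (planted? known to the KG? known to the
literature?) is returned alongside, so tests can assert that the cascade
recovers planted novel signals and suppresses planted known ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ._common import derive_seed, logger
from .linking import EntityLexicon
from .prep import CohortTable

TARGET_ENTITY = "C0000999"


class PlantedFeature(BaseModel):
    """A feature with a real effect on the target.

    ``effect`` is the log-odds change in the target per standard deviation
    of the feature.  ``kg_known``/``lit_known`` control whether the toy
    knowledge graph / literature table records the association, i.e.
    whether the cascade should suppress it as non-novel.
    """

    feature_id: str
    effect: float
    kg_known: bool = False
    lit_known: bool = False


class Confounder(BaseModel):
    """A baseline covariate entering both the outcome and feature models."""

    covariate: str = Field(pattern="^(age|sex|bmi)$")
    strength: float


class SyntheticSpec(BaseModel):
    n_patients: int = Field(default=2000, ge=1)
    n_features: int = Field(default=50, ge=1)
    prevalence: float = Field(default=0.1, gt=0.0, lt=1.0)
    planted_features: list[PlantedFeature] = Field(default_factory=list)
    confounders: list[Confounder] = Field(default_factory=list)
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    binary_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    target_name: str = "toy disease"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        ids = [p.feature_id for p in self.planted_features]
        if len(ids) != len(set(ids)):
            raise ValueError("planted feature ids must be unique")
        for p in self.planted_features:
            if not np.isfinite(p.effect):
                raise ValueError(f"non-finite effect for {p.feature_id}")
        if len(self.planted_features) + len(self.confounders) > self.n_features:
            raise ValueError("n_features too small for planted + confounder proxies")
        if self.n_patients * self.prevalence < 10:
            raise ValueError("expected cases < 10; enlarge n_patients or prevalence")
        return self


@dataclass
class GroundTruth:
    """Per-feature labels describing what the cascade should recover."""

    table: pd.DataFrame  # index: feature; planted, kg_known, lit_known, expected

    @classmethod
    def build(cls, spec: SyntheticSpec, all_features: list[str]) -> "GroundTruth":
        planted = {p.feature_id: p for p in spec.planted_features}
        rows = []
        for f in all_features:
            p = planted.get(f)
            rows.append(
                {
                    "feature": f,
                    "planted": p is not None,
                    "kg_known": bool(p and p.kg_known),
                    "lit_known": bool(p and p.lit_known),
                }
            )
        df = pd.DataFrame(rows).set_index("feature")
        df["expected_final_candidate"] = (
            df["planted"] & ~df["kg_known"] & ~df["lit_known"]
        )
        return cls(df)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _solve_intercept(linpred: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept matching the target mean risk."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _sigmoid(linpred + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, GroundTruth]:
    """Sample a participant table from the planted logistic model.

    Baseline covariates: age ~ N(57, 8), sex ~ Bernoulli(0.5),
    BMI ~ N(27, 4.5) (UK-cohort-like scales).  Planted features are unit
    normals; each confounder additionally spawns a proxy feature
    ``<covariate>_proxy`` = strength * z_covariate + noise, so confounding
    flows through both the outcome and the feature model.  Remaining
    features are independent noise (a ``binary_fraction`` of them
    Bernoulli(0.2), the rest standard normal).  The intercept is solved so
    mean risk equals ``prevalence``; missingness is injected completely at
    random on feature columns.  Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    age = rng.normal(57.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(27.0, 4.5, n)
    cov = {"age": age, "sex": sex, "bmi": bmi}
    z_cov = {k: (v - v.mean()) / v.std() for k, v in cov.items()}

    frame = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi})
    linpred = np.zeros(n)
    feature_cols: list[str] = []

    for p in spec.planted_features:
        x = rng.normal(0.0, 1.0, n)
        frame[p.feature_id] = x
        feature_cols.append(p.feature_id)
        linpred += p.effect * x
    for c in spec.confounders:
        name = f"{c.covariate}_proxy"
        frame[name] = c.strength * z_cov[c.covariate] + rng.normal(0.0, 1.0, n)
        feature_cols.append(name)
        linpred += c.strength * z_cov[c.covariate]

    n_null = spec.n_features - len(feature_cols)
    n_binary = int(round(spec.binary_fraction * n_null))
    for i in range(n_null):
        name = f"noise_{i:03d}"
        if i < n_binary:
            frame[name] = rng.binomial(1, 0.2, n).astype(float)
        else:
            frame[name] = rng.normal(0.0, 1.0, n)
        feature_cols.append(name)

    b0 = _solve_intercept(linpred, spec.prevalence)
    y = rng.binomial(1, _sigmoid(linpred + b0))
    frame["target"] = y

    if spec.missing_rate > 0:
        mask = rng.random((n, len(feature_cols))) < spec.missing_rate
        vals = frame[feature_cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        frame[feature_cols] = vals

    metadata = {f: f.replace("_", " ") for f in feature_cols}
    table = CohortTable(frame=frame, feature_cols=feature_cols, metadata=metadata)
    return table, GroundTruth.build(spec, feature_cols)


# ------------------------------------------------------------------ toy KG

def generate_toy_kg(
    entities: list[str],
    known_pairs: list[tuple[str, str, int, int]],
    seed: int = 0,
    n_background: int = 20,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """SemMed-style triple table with planted known edges plus background.

    ``known_pairs`` rows are (subject, object, n_citations, first_year);
    a duplicate pair with a conflicting year is rejected.  Background
    edges connect auto-generated filler entities among themselves and to
    the given entities, never recreating a known pair, so planted novelty
    structure is preserved.
    """
    if len(entities) != len(set(entities)):
        raise ValueError("entity ids must be unique")
    seen: dict[tuple[str, str], int] = {}
    for s, o, _c, year in known_pairs:
        key = (s, o) if s <= o else (o, s)
        if key in seen and seen[key] != year:
            raise ValueError(f"duplicate pair {key} with conflicting years")
        seen[key] = year
    rng = np.random.default_rng(derive_seed(seed, "toy-kg"))
    rows = [
        {
            "subject_cui": s,
            "object_cui": o,
            "predicate": "ASSOCIATED_WITH",
            "n_citations": c,
            "first_year": y,
        }
        for s, o, c, y in known_pairs
    ]
    background = [f"C9{i:06d}" for i in range(max(n_background // 2, 2))]
    pool = list(entities) + background
    made = set(seen)
    for _ in range(n_background):
        a = background[rng.integers(len(background))]
        b = pool[rng.integers(len(pool))]
        key = (a, b) if a <= b else (b, a)
        if a == b or key in made:
            continue
        made.add(key)
        rows.append(
            {
                "subject_cui": a,
                "object_cui": b,
                "predicate": "COEXISTS_WITH",
                "n_citations": int(rng.integers(2, 6)),
                "first_year": int(rng.integers(1990, 2021)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["subject_cui", "predicate", "object_cui", "n_citations", "first_year"]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ------------------------------------------------------- literature counts

def _stable_count(term: str, lo: int = 100, span: int = 5000) -> int:
    return lo + zlib.crc32(term.lower().encode()) % span


def generate_literature_counts(
    terms: list[str],
    pair_overrides: dict[tuple[str, str], int] | None = None,
    corpus_size: int = 37_000_000,
    term_overrides: dict[str, int] | None = None,
) -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    """Deterministic hit-count tables for the offline literature provider.

    Unoverridden terms get a stable pseudo-count (CRC-derived, so no RNG
    state is involved); pairs default to 0 co-mentions.  Overrides that
    violate n_xy <= min(n_x, n_y), or term counts above the corpus size,
    are rejected.
    """
    term_counts = {t: _stable_count(t) for t in terms}
    term_counts.update(term_overrides or {})
    if term_counts and max(term_counts.values()) > corpus_size:
        raise ValueError("term count exceeds corpus size")
    pair_counts: dict[tuple[str, str], int] = {}
    for (a, b), n_xy in (pair_overrides or {}).items():
        for t in (a, b):
            if t not in term_counts:
                term_counts[t] = _stable_count(t)
        if n_xy > min(term_counts[a], term_counts[b]):
            raise ValueError(f"pair count {n_xy} exceeds a marginal for ({a}, {b})")
        pair_counts[(a, b)] = n_xy
    return term_counts, pair_counts


def write_count_tables(
    term_counts: dict[str, int],
    pair_counts: dict[tuple[str, str], int],
    term_file: str | Path,
    pair_file: str | Path,
) -> None:
    pd.DataFrame(
        sorted(term_counts.items()), columns=["term", "count"]
    ).to_csv(term_file, index=False)
    pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(pair_counts.items())],
        columns=["term_a", "term_b", "pair_count"],
    ).to_csv(pair_file, index=False)


def recovery_study_spec(seed: int) -> SyntheticSpec:
    """Canonical planted-feature recovery study conditions.

    A 5000-participant cohort with one planted novel risk factor (1.2
    log-odds/SD), thirteen planted already-known risk factors (1.0
    log-odds/SD; nine recorded in the knowledge graph, four heavily
    co-mentioned in the literature — together ~20% of the feature table),
    fifty null features and an age confounder.  Used to measure end-to-end
    recovery of the novel signal and suppression of the known ones.
    """
    known = [
        PlantedFeature(feature_id=f"known_kg_{i:02d}", effect=1.0, kg_known=True)
        for i in range(9)
    ] + [
        PlantedFeature(feature_id=f"known_lit_{i:02d}", effect=1.0, lit_known=True)
        for i in range(4)
    ]
    return SyntheticSpec(
        n_patients=5000,
        n_features=64,
        prevalence=0.15,
        planted_features=[PlantedFeature(feature_id="novel_marker", effect=1.2)] + known,
        confounders=[Confounder(covariate="age", strength=0.5)],
        missing_rate=0.02,
        seed=seed,
    )


# ------------------------------------------------------------------ bundle

@dataclass
class SyntheticBundle:
    """Everything the pipeline needs, generated from one spec + seed."""

    spec: SyntheticSpec
    cohort: CohortTable
    truth: GroundTruth
    lexicon: EntityLexicon
    kg_triples: pd.DataFrame
    term_counts: dict[str, int]
    pair_counts: dict[tuple[str, str], int]
    llm_script: dict[str, tuple[int, int, int]]
    target_name: str
    target_entities: list[str]
    corpus_docs: dict[str, str]


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate a coherent synthetic study world.

    Planted features get lexicon entities named after them, so the offline
    token-overlap linker resolves them; kg_known features get a >=2-citation
    edge to the target entity; lit_known features get heavy term and
    co-mention counts so the literature filter drops them.  Null features
    have no lexicon entry (unlinked -> novel-by-default) and rare terms.
    The scripted LLM scores expected final candidates (4,4,4) and
    everything else (2,2,2), so selection hinges on the upstream filters.
    """
    cohort, truth = generate_cohort(spec)
    target = spec.target_name
    entries = {TARGET_ENTITY: (target, "Disease or Syndrome")}
    llm_script: dict[str, tuple[int, int, int]] = {}
    known_pairs: list[tuple[str, str, int, int]] = []
    term_over: dict[str, int] = {target: 80_000}
    pair_over: dict[tuple[str, str], int] = {}

    for i, p in enumerate(spec.planted_features):
        cui = f"C{1000 + i:07d}"
        name = p.feature_id.replace("_", " ")
        entries[cui] = (name, "Finding")
        if p.kg_known:
            known_pairs.append((cui, TARGET_ENTITY, 3, 2005))
        if p.lit_known:
            term_over[name] = 50_000
            pair_over[(name, target)] = 5_000
        else:
            term_over[name] = 10  # rare term: literature filter passes it through
            pair_over[(name, target)] = 0
        expected = p.feature_id in truth.table.index[
            truth.table["expected_final_candidate"]
        ]
        llm_script[p.feature_id] = (4, 4, 4) if expected else (2, 2, 2)

    lexicon = EntityLexicon(entries=entries)
    kg_triples = generate_toy_kg(
        list(entries), known_pairs, seed=spec.seed, n_background=30
    )
    for cui in pd.unique(
        pd.concat([kg_triples["subject_cui"], kg_triples["object_cui"]])
    ):
        lexicon.entries.setdefault(cui, (cui, "Background"))
    all_terms = [cohort.description_of(f) for f in cohort.feature_cols] + [target]
    term_counts, pair_counts = generate_literature_counts(
        all_terms, pair_over, term_overrides=term_over
    )
    # null feature names are cohort-specific variable names: rare in print
    for f in cohort.feature_cols:
        name = cohort.description_of(f)
        if name not in term_over:
            term_counts[name] = 5

    corpus_docs = {
        f"doc{i:03d}": f"Report on {entries[cui][0]} and {target} in cohort studies."
        for i, cui in enumerate(list(entries)[:8])
    }
    return SyntheticBundle(
        spec=spec,
        cohort=cohort,
        truth=truth,
        lexicon=lexicon,
        kg_triples=kg_triples,
        term_counts=term_counts,
        pair_counts=pair_counts,
        llm_script=llm_script,
        target_name=target,
        target_entities=[TARGET_ENTITY],
        corpus_docs=corpus_docs,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all bundle artifacts as plain-text files; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "truth": out / "ground_truth.csv",
        "lexicon": out / "lexicon.csv",
        "kg": out / "kg_triples.csv",
        "terms": out / "term_counts.csv",
        "pairs": out / "pair_counts.csv",
        "llm_script": out / "llm_script.json",
        "corpus": out / "corpus.jsonl",
    }
    bundle.cohort.frame.to_csv(paths["cohort"], index=False)
    bundle.truth.table.to_csv(paths["truth"])
    bundle.lexicon.to_csv(paths["lexicon"])
    bundle.kg_triples.to_csv(paths["kg"], index=False)
    write_count_tables(bundle.term_counts, bundle.pair_counts, paths["terms"], paths["pairs"])
    paths["llm_script"].write_text(
        json.dumps({"script": bundle.llm_script, "default": [2, 2, 2]}, indent=1)
    )
    with open(paths["corpus"], "w") as fh:
        for doc_id, text in bundle.corpus_docs.items():
            fh.write(json.dumps({"id": doc_id, "text": text}) + "\n")
    logger.info("synthetic bundle written to %s", out)
    return paths
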