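"""Pipeline orchestration: prep -> utility -> KG -> literature -> LLM.

``run_cascade`` drives the whole screening cascade over in-memory inputs
and returns the ranked shortlist plus a per-stage funnel report (counts of
surviving features, necessarily non-increasing).  ``run_pipeline`` is the
file-based wrapper: it loads every input from a ``PipelineConfig``, runs
the cascade, and writes ``selected.csv``, ``funnel.csv`` and
``run_meta.json`` (config hash, seed, versions) to the output directory.
Every source of randomness derives from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from ._common import derive_seed, logger
from .annotate import (
    BM25Index,
    Candidate,
    LLMConfig,
    ScriptedLLMProvider,
    annotate_candidates,
    load_template,
    select_candidates,
)
from .kg import KnowledgeGraph, is_known, load_kg
from .linking import EntityLexicon, LexiconLinker, LinkConfig, link_and_gate
from .literature import LitConfig, OfflineCountProvider, counts_for_pair, literature_filter
from .prep import CohortTable, PrepConfig, prepare
from .utility import UtilityConfig, apply_utility_filter, compute_utility_scores


class StageToggles(BaseModel):
    ipw: bool = False
    corr_dedup: bool = True
    kg: bool = True
    literature: bool = True
    llm: bool = True
    rag: bool = True


class PipelineConfig(BaseModel):
    """Run configuration: paths, per-stage settings, target identity, seed."""

    cohort_path: str
    kg_path: str
    lexicon_path: str
    term_counts_path: str
    pair_counts_path: str
    llm_script_path: str | None = None
    corpus_path: str | None = None
    target_name: str = "target disease"
    target_entities: list[str] = Field(default_factory=list)
    seed: int = 0
    stages: StageToggles = Field(default_factory=StageToggles)
    prep: PrepConfig = Field(default_factory=PrepConfig)
    utility: UtilityConfig = Field(default_factory=UtilityConfig)
    link: LinkConfig = Field(default_factory=LinkConfig)
    min_citations: int = 2
    literature: LitConfig = Field(default_factory=LitConfig)
    llm: LLMConfig = Field(default_factory=LLMConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        for name in (
            "cohort_path", "kg_path", "lexicon_path",
            "term_counts_path", "pair_counts_path",
        ):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


@dataclass
class FunnelReport:
    """Counts of features surviving each cascade stage."""

    prepared: int
    utility_pass: int
    kg_pass: int
    literature_pass: int
    llm_selected: int

    def counts(self) -> list[int]:
        return [
            self.prepared, self.utility_pass, self.kg_pass,
            self.literature_pass, self.llm_selected,
        ]

    def __post_init__(self) -> None:
        c = self.counts()
        if any(a < b for a, b in zip(c, c[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {c}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["prepared", "utility", "kg", "literature", "selected"],
                "n_features": self.counts(),
            }
        )


def effect_direction(x: np.ndarray, y: np.ndarray) -> str:
    """Sign of the feature-target association ("positive"/"negative").

    The mean difference of x between cases and controls carries the sign
    of both the point-biserial correlation (continuous x) and the
    univariate log-odds (binary x).  An exactly-zero difference returns
    "positive" with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(np.unique(x)) <= 1:
        raise ValueError("effect_direction requires non-constant x")
    diff = x[y == 1].mean() - x[y == 0].mean()
    if diff == 0.0:
        logger.warning("zero-magnitude association; direction 'positive'")
        return "positive"
    return "positive" if diff > 0 else "negative"


@dataclass
class CascadeResult:
    selected: pd.DataFrame
    funnel: FunnelReport
    scores: pd.DataFrame
    verdicts: dict[str, dict] = field(default_factory=dict)


def run_cascade(
    cohort: CohortTable,
    kg: KnowledgeGraph,
    lexicon: EntityLexicon,
    count_provider,
    llm_provider,
    target_name: str,
    target_entities: list[str],
    config: PipelineConfig | None = None,
    corpus_docs: dict[str, str] | None = None,
) -> CascadeResult:
    """Run the full cascade over in-memory inputs."""
    cfg = config or PipelineConfig(
        cohort_path="", kg_path="", lexicon_path="",
        term_counts_path="", pair_counts_path="",
        target_name=target_name, target_entities=target_entities,
    )
    toggles = cfg.stages

    prep_cfg = cfg.prep.model_copy(
        update={
            "ipw_enabled": toggles.ipw,
            "corr_dedup_enabled": toggles.corr_dedup,
            "seed": derive_seed(cfg.seed, "prep"),
        }
    )
    table, prep_log = prepare(cohort, prep_cfg)
    prepared = list(table.feature_cols)

    util_cfg = cfg.utility.model_copy(update={"seed": derive_seed(cfg.seed, "utility")})
    scores = compute_utility_scores(table.X, table.y, util_cfg)
    utility_pass = [f for f in prepared if scores.loc[f, "pass_utility"]]

    provider = LexiconLinker(lexicon)
    links_by_feature = {}
    verdicts: dict[str, dict] = {f: {"stage": "utility"} for f in prepared}
    kg_pass: list[str] = []
    for f in utility_pass:
        links = link_and_gate(f, cohort.description_of(f), provider, lexicon, cfg.link)
        links_by_feature[f] = links
        if toggles.kg:
            verdict = is_known(links, target_entities, kg, cfg.link.theta_sim)
            verdicts[f]["kg"] = verdict.reason
            if verdict.known:
                continue
        kg_pass.append(f)

    lit_pass: list[str] = []
    for f in kg_pass:
        if toggles.literature:
            counts = counts_for_pair(count_provider, cohort.description_of(f), target_name)
            retain, reason = literature_filter(counts, cfg.literature)
            verdicts[f]["literature"] = reason
            if not retain:
                continue
        lit_pass.append(f)

    candidates = [
        Candidate(
            feature_id=f,
            feature_text=cohort.description_of(f),
            target_name=target_name,
            direction=effect_direction(table.frame[f].to_numpy(), table.y),
            fimp=float(scores.loc[f, "fimp"]),
            pval=float(scores.loc[f, "pval"]),
            mi=float(scores.loc[f, "mi"]),
        )
        for f in lit_pass
    ]

    if toggles.llm and candidates:
        index = (
            BM25Index(sorted((corpus_docs or {}).items()))
            if (toggles.rag and corpus_docs)
            else None
        )
        llm_cfg = cfg.llm.model_copy(update={"rag_enabled": toggles.rag and index is not None})
        annotations, failed = annotate_candidates(
            candidates, llm_provider, load_template(), index, llm_cfg, corpus_docs
        )
        for fid in failed:
            verdicts[fid]["llm"] = "unannotated"
        fimp_by_id = {c.feature_id: c.fimp for c in candidates}
        selected_ann = select_candidates(
            annotations, fimp_by_id,
            llm_cfg.min_interestingness_exclusive, llm_cfg.top_k,
        )
        by_id = {c.feature_id: c for c in candidates}
        rows = [
            {
                "rank": i + 1,
                "feature": a.candidate_id,
                "direction": by_id[a.candidate_id].direction,
                "novelty": a.novelty,
                "plausibility": a.plausibility,
                "interestingness": a.interestingness,
                "confidence": a.confidence,
                "pval": by_id[a.candidate_id].pval,
                "mi": by_id[a.candidate_id].mi,
                "fimp": by_id[a.candidate_id].fimp,
                "explanation": a.explanations.get("interestingness", ""),
            }
            for i, a in enumerate(selected_ann)
        ]
        selected = pd.DataFrame(
            rows,
            columns=[
                "rank", "feature", "direction", "novelty", "plausibility",
                "interestingness", "confidence", "pval", "mi", "fimp", "explanation",
            ],
        )
    else:
        # LLM stage off: pass-through, ranked by model importance
        rows = [
            {
                "rank": i + 1, "feature": c.feature_id, "direction": c.direction,
                "novelty": "", "plausibility": "", "interestingness": "",
                "confidence": "", "pval": c.pval, "mi": c.mi, "fimp": c.fimp,
                "explanation": "",
            }
            for i, c in enumerate(
                sorted(candidates, key=lambda c: (-c.fimp, c.feature_id))
            )
        ]
        selected = pd.DataFrame(
            rows,
            columns=[
                "rank", "feature", "direction", "novelty", "plausibility",
                "interestingness", "confidence", "pval", "mi", "fimp", "explanation",
            ],
        )

    funnel = FunnelReport(
        prepared=len(prepared),
        utility_pass=len(utility_pass),
        kg_pass=len(kg_pass),
        literature_pass=len(lit_pass),
        llm_selected=len(selected),
    )
    return CascadeResult(selected=selected, funnel=funnel, scores=scores, verdicts=verdicts)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> CascadeResult:
    """Load all inputs from config paths, run the cascade, write outputs."""
    config.validate_paths()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = CohortTable.from_csv(config.cohort_path)
    cohort.metadata.update({f: f.replace("_", " ") for f in cohort.feature_cols})
    lexicon = EntityLexicon.from_csv(config.lexicon_path)
    kg = load_kg(config.kg_path, config.min_citations, lexicon)
    counts = OfflineCountProvider.from_csv(
        config.term_counts_path, config.pair_counts_path, config.literature.corpus_size
    )
    if config.llm_script_path:
        llm = ScriptedLLMProvider.from_json(config.llm_script_path)
    else:
        llm = ScriptedLLMProvider({}, default=(2, 2, 2))
    corpus_docs: dict[str, str] = {}
    if config.corpus_path and Path(config.corpus_path).exists():
        with open(config.corpus_path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    corpus_docs[rec["id"]] = rec["text"]

    result = run_cascade(
        cohort, kg, lexicon, counts, llm,
        config.target_name, config.target_entities, config, corpus_docs,
    )
    result.selected.to_csv(out / "selected.csv", index=False)
    result.funnel.to_frame().to_csv(out / "funnel.csv", index=False)
    (out / "run_meta.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "version": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            indent=1,
        )
    )
    logger.info("pipeline run complete; funnel %s", result.funnel.counts())
    return result


def threshold_sensitivity(
    scores: pd.DataFrame,
    reference_set: list[str],
    theta_p_grid: list[float],
    config: UtilityConfig | None = None,
    criteria: str = "pval",
) -> pd.DataFrame:
    """Recall of a reference feature set as the p-value threshold tightens.

    ``criteria="pval"`` (default) sweeps the p-value criterion alone,
    which is the informative sensitivity sweep: under a disjunctive filter
    the MI/FImp criteria would mask the effect of theta_p.
    ``criteria="full"`` applies the complete utility filter with theta_p
    replaced by each grid value.
    """
    if not reference_set:
        raise ValueError("reference_set must be nonempty")
    cfg = config or UtilityConfig()
    present = [f for f in reference_set if f in scores.index]
    rows = []
    for theta in theta_p_grid:
        if criteria == "pval":
            passed = [f for f in present if scores.loc[f, "pval"] < theta]
        else:
            flagged = apply_utility_filter(scores, cfg.model_copy(update={"theta_p": theta}))
            passed = [f for f in present if flagged.loc[f, "pass_utility"]]
        rows.append(
            {"theta_p": theta, "recall": len(passed) / len(reference_set)}
        )
    return pd.DataFrame(rows)
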