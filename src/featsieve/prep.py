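"""Cohort table container and preparation stage.

The preparation stage turns a raw participant-level feature table into the
matrix the utility filter scores:

1. drop features with too few observed values,
2. mean-impute remaining missingness and append per-feature missing flags,
3. drop one member of every highly correlated feature pair,
4. optionally downsample control (negative) participants by inverse
   propensity weighting on the baseline covariates (age, sex, BMI) to a
   fixed controls:cases ratio, so that retained controls resemble cases on
   those confounders.

All steps are deterministic; every dropped feature is logged with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._common import derive_seed, logger

MISSING_FLAG_SUFFIX = "__missing"
BASELINE_COVARIATES = ("age", "sex", "bmi")


@dataclass
class CohortTable:
    """Participants x features matrix with a binary target and covariates.

    ``frame`` holds one row per participant: the candidate feature columns,
    the binary ``target`` column and the baseline covariates.  ``metadata``
    maps a feature name to a human-readable description used for entity
    linking and prompts.
    """

    frame: pd.DataFrame
    feature_cols: list[str]
    target_col: str = "target"
    covariate_cols: tuple[str, ...] = BASELINE_COVARIATES
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_col not in self.frame.columns:
            raise ValueError(f"target column {self.target_col!r} missing")
        y = self.frame[self.target_col]
        if not set(y.dropna().unique()) <= {0, 1}:
            raise ValueError("target must be binary 0/1")
        if len(self.feature_cols) != len(set(self.feature_cols)):
            raise ValueError("feature names must be unique")
        missing = [c for c in self.feature_cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature columns not in frame: {missing[:5]}")

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.target_col].to_numpy()

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_cols]

    def description_of(self, feature: str) -> str:
        """Human-readable text for a feature (falls back to its name)."""
        base = feature.removesuffix(MISSING_FLAG_SUFFIX)
        text = self.metadata.get(feature) or self.metadata.get(base) or feature
        return text

    @classmethod
    def from_csv(
        cls,
        path,
        target_col: str = "target",
        covariate_cols: tuple[str, ...] = BASELINE_COVARIATES,
        metadata: dict[str, str] | None = None,
        sep: str = ",",
    ) -> "CohortTable":
        frame = pd.read_csv(path, sep=sep)
        reserved = {target_col, *covariate_cols, "participant_id"}
        feats = [c for c in frame.columns if c not in reserved]
        return cls(frame, feats, target_col, covariate_cols, metadata or {})


class PrepConfig(BaseModel):
    """Preparation-stage settings (defaults follow the reference protocol)."""

    min_nonmissing: int = Field(default=30, ge=1)
    corr_threshold: float = Field(default=0.9, gt=0.0, le=1.0)
    corr_dedup_enabled: bool = True
    ipw_enabled: bool = False
    ipw_ratio: int = Field(default=9, ge=1)
    seed: int = 0


@dataclass
class PrepLog:
    """Per-feature drop records accumulated over the prep stages."""

    sparse_dropped: list[str] = field(default_factory=list)
    correlated_dropped: list[tuple[str, str, float]] = field(default_factory=list)
    flags_added: list[str] = field(default_factory=list)
    ipw_applied: bool = False


def drop_sparse_features(
    table: CohortTable, min_nonmissing: int = 30
) -> tuple[CohortTable, list[str]]:
    """Drop features with fewer than ``min_nonmissing`` observed values."""
    if min_nonmissing < 1:
        raise ValueError("min_nonmissing must be >= 1")
    counts = table.X.notna().sum(axis=0)
    dropped = [c for c in table.feature_cols if counts[c] < min_nonmissing]
    kept = [c for c in table.feature_cols if c not in set(dropped)]
    if not kept:
        raise ValueError("all features dropped as sparse")
    for c in dropped:
        logger.info("drop sparse feature %s (%d non-missing)", c, counts[c])
    frame = table.frame.drop(columns=dropped)
    return replace(table, frame=frame, feature_cols=kept), dropped


def impute_and_flag(table: CohortTable) -> tuple[CohortTable, list[str]]:
    """Mean-impute missing values, appending a binary flag per affected feature.

    Features that are fully observed are untouched and get no flag.  A
    feature with zero observed values is an error (it should have been
    dropped by the sparsity screen).
    """
    frame = table.frame.copy()
    flags: list[str] = []
    flag_cols: dict[str, pd.Series] = {}
    for c in table.feature_cols:
        col = frame[c]
        n_miss = int(col.isna().sum())
        if n_miss == 0:
            continue
        if n_miss == len(col):
            raise ValueError(f"feature {c!r} has no observed values")
        flag_name = f"{c}{MISSING_FLAG_SUFFIX}"
        flag_cols[flag_name] = col.isna().astype(int)
        frame[c] = col.fillna(col.mean())
        flags.append(flag_name)
    if flag_cols:
        frame = pd.concat([frame, pd.DataFrame(flag_cols, index=frame.index)], axis=1)
    return (
        replace(table, frame=frame, feature_cols=table.feature_cols + flags),
        flags,
    )


def drop_correlated(
    table: CohortTable, corr_threshold: float = 0.9
) -> tuple[CohortTable, list[tuple[str, str, float]]]:
    """Greedy first-seen correlation deduplication.

    Features are scanned in declared column order; a feature is dropped if
    its absolute Pearson correlation with an already-kept feature exceeds
    the threshold (the kept partner and r are logged).  Constant features
    carry no correlation signal: they are excluded from the screen and
    retained with a warning.
    """
    X = table.X
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=0)
    constant = sd == 0.0
    for c in X.columns[constant]:
        logger.warning("constant feature %s excluded from correlation screen", c)
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    centered = values - values.mean(axis=0)
    n = values.shape[0]
    for j, name in enumerate(X.columns):
        if constant[j]:
            kept_idx.append(j)
            continue
        partner = None
        for i in kept_idx:
            if constant[i]:
                continue
            r = float(centered[:, i] @ centered[:, j] / (n * sd[i] * sd[j]))
            if abs(r) > corr_threshold:
                partner = (X.columns[i], name, r)
                break
        if partner is None:
            kept_idx.append(j)
        else:
            dropped.append(partner)
            logger.info(
                "drop correlated feature %s (kept %s, r=%.3f)",
                partner[1], partner[0], partner[2],
            )
    kept = [X.columns[i] for i in kept_idx]
    frame = table.frame.drop(columns=[d for _, d, _ in dropped])
    return replace(table, frame=frame, feature_cols=kept), dropped


def ipw_downsample(table: CohortTable, ipw_ratio: int = 9, seed: int = 0) -> CohortTable:
    """Propensity-weighted downsampling of controls to ``ipw_ratio``:1.

    A regularized logistic regression P(y=1 | age, sex, BMI) is fit on the
    full table; controls are then sampled without replacement with
    probability proportional to their predicted propensity, down to
    ``ipw_ratio`` controls per case.  Cases are always kept.  Controls that
    resemble cases on the baseline covariates are preferentially retained,
    which blunts confounding by those covariates downstream.
    """
    y = table.y
    n_pos = int(y.sum())
    if n_pos < 1:
        raise ValueError("ipw_downsample requires at least one positive")
    missing_cov = [c for c in table.covariate_cols if c not in table.frame.columns]
    if missing_cov:
        raise ValueError(f"covariates missing for IPW: {missing_cov}")
    neg_idx = np.flatnonzero(y == 0)
    n_keep = ipw_ratio * n_pos
    if len(neg_idx) <= n_keep:
        logger.info("ipw_downsample no-op: %d negatives <= %d", len(neg_idx), n_keep)
        return table

    Z = StandardScaler().fit_transform(
        table.frame[list(table.covariate_cols)].to_numpy(dtype=float)
    )
    model = LogisticRegression(max_iter=1000)
    model.fit(Z, y)
    propensity = model.predict_proba(Z)[:, 1]
    w = propensity[neg_idx]
    rng = np.random.default_rng(derive_seed(seed, "ipw"))
    chosen = rng.choice(neg_idx, size=n_keep, replace=False, p=w / w.sum())
    keep_mask = np.zeros(len(y), dtype=bool)
    keep_mask[y == 1] = True
    keep_mask[chosen] = True
    frame = table.frame.loc[keep_mask].reset_index(drop=True)
    return replace(table, frame=frame)


def prepare(table: CohortTable, config: PrepConfig) -> tuple[CohortTable, PrepLog]:
    """Full preparation pass: sparse -> impute+flag -> dedup -> IPW."""
    log = PrepLog()
    table, log.sparse_dropped = drop_sparse_features(table, config.min_nonmissing)
    table, log.flags_added = impute_and_flag(table)
    if config.corr_dedup_enabled:
        table, log.correlated_dropped = drop_correlated(table, config.corr_threshold)
    if config.ipw_enabled:
        n_before = len(table.frame)
        table = ipw_downsample(table, config.ipw_ratio, config.seed)
        log.ipw_applied = len(table.frame) != n_before
    return table, log
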