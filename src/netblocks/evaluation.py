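"""Topological and functional goodness criteria for sampled subgraphs.

Topological: delta(M, G) — the squared deviation between the motif
frequency vectors of a sample M and its host G, reported both as the raw
sum and as the per-class mean ("MSE").

Functional: a gradient-boosted regression predicting the host's SI
transient time tau(G) from a sample's motif features, scored by the
coefficient of determination R^2 under a fixed protocol: 5 seeded shuffle
splits with 30% test fraction and 100 boosting iterations, R^2 averaged
over splits.

Ranking: samplers ordered by mean delta (ascending) and mean R^2
(descending); the recommended method is the first to appear in both top
lists, and the recommended sample size is the smallest after which both
curves flatten (changes below 10% of their range over the size grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import ShuffleSplit

from .errors import EvaluationError, GraphDomainError
from .motifs import FrequencyVariant, MotifCensus, motif_frequencies, n_connected_classes

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionConfig",
    "DeltaResult",
    "EvalReport",
    "motif_mse",
    "feature_vector",
    "build_feature_table",
    "evaluate_prediction",
    "rank_and_select",
]

TOP_LIST_SIZE = 5
PLATEAU_FRACTION = 0.10


@dataclass(frozen=True)
class RegressionConfig:
    """Fixed learning protocol for transient-time prediction."""

    n_folds: int = 5
    test_fraction: float = 0.30
    boosting_iterations: int = 100
    model_seed: int = 0
    model: str = "boosted"  # "boosted" (gradient-boosted trees) or "linear"


@dataclass(frozen=True)
class DeltaResult:
    """delta(M, G): raw squared deviation and its per-class mean."""

    raw: float
    mean: float


def motif_mse(freq_host: np.ndarray, freq_sample: np.ndarray) -> DeltaResult:
    """Squared deviation between two motif frequency vectors.

    Vectors must share length and class ordering; the mean divides the raw
    sum by the class count.
    """
    a = np.asarray(freq_host, dtype=float)
    b = np.asarray(freq_sample, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise GraphDomainError(f"frequency vectors must match: {a.shape} vs {b.shape}")
    raw = float(np.sum((a - b) ** 2))
    return DeltaResult(raw=raw, mean=raw / len(a))


def feature_vector(census: MotifCensus, variant: FrequencyVariant) -> np.ndarray:
    """Per-class frequencies plus the disjoint-total scalar, fixed order."""
    variant = FrequencyVariant(variant)
    if variant is FrequencyVariant.DISJOINT_TOTAL_RATIO:
        raise GraphDomainError("feature vectors need a per-class variant")
    vec = motif_frequencies(census, variant)
    scalar = motif_frequencies(census, FrequencyVariant.DISJOINT_TOTAL_RATIO)
    return np.concatenate([vec, [scalar]])


def feature_columns(k: int) -> list[str]:
    return [f"f{i}" for i in range(n_connected_classes(k))] + ["disjoint_total"]


def build_feature_table(
    samples: list,
    censuses: dict,
    taus: dict,
    variant: FrequencyVariant = FrequencyVariant.JOINT_RATIO,
) -> pd.DataFrame:
    """One row per sample: motif features of the sample, tau of its host.

    ``censuses`` maps sample index -> MotifCensus of the sample's subgraph;
    ``taus`` maps host_id -> TransientEstimate of the host.  Rows whose
    features are all zero (no k-subgraph in the sample) are kept and
    flagged.
    """
    rows = []
    for i, sample in enumerate(samples):
        if i not in censuses:
            raise EvaluationError(f"sample {i} (host {sample.host_id}) has no census")
        if sample.host_id not in taus:
            raise EvaluationError(f"host {sample.host_id} has no transient estimate")
        census = censuses[i]
        feats = feature_vector(census, variant)
        row = {
            "host_id": sample.host_id,
            "method": sample.spec.method.value,
            "sample_size": sample.spec.target_size,
            "k": census.k,
            "variant": FrequencyVariant(variant).value,
            "all_zero": bool(np.all(feats == 0.0)),
            "target_tau": taus[sample.host_id].mean_tau,
        }
        row.update(zip(feature_columns(census.k), feats))
        rows.append(row)
    return pd.DataFrame(rows)


def _make_model(cfg: RegressionConfig, seed: int):
    if cfg.model == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression()
    from lightgbm import LGBMRegressor

    return LGBMRegressor(
        n_estimators=cfg.boosting_iterations,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
    )


def evaluate_prediction(rows: pd.DataFrame, cfg: RegressionConfig) -> float:
    """Mean test R^2 of the tau regression over seeded shuffle splits.

    ``rows`` is a feature table restricted to one (method, size, variant)
    cell; needs at least 20 rows and a non-constant target.
    """
    if len(rows) < 20:
        raise EvaluationError(f"need >= 20 rows to evaluate, got {len(rows)}")
    y = rows["target_tau"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        raise EvaluationError("target tau is constant; R^2 undefined")
    feat_cols = [c for c in rows.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.append("disjoint_total")
    X = rows[feat_cols].astype(float).reset_index(drop=True)
    splitter = ShuffleSplit(
        n_splits=cfg.n_folds, test_size=cfg.test_fraction, random_state=cfg.model_seed
    )
    scores = []
    for fold, (train, test) in enumerate(splitter.split(X)):
        model = _make_model(cfg, cfg.model_seed + fold)
        model.fit(X.iloc[train], y[train])
        scores.append(float(model.score(X.iloc[test], y[test])))
    logger.debug("per-fold R^2: %s", scores)
    return float(np.mean(scores))


@dataclass
class EvalReport:
    """Per-cell criteria tables plus the method/size recommendation.

    ``mse_table`` and ``r2_table`` map (method, sample_size, variant) to the
    corpus-mean delta and fold-mean R^2.
    """

    mse_table: dict = field(default_factory=dict)
    r2_table: dict = field(default_factory=dict)
    ranking_by_mse: list = field(default_factory=list)
    ranking_by_r2: list = field(default_factory=list)
    recommended_method: str | None = None
    recommended_size: int | None = None
    config_echo: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)


def _method_means(table: dict) -> dict[str, float]:
    acc: dict[str, list[float]] = {}
    for (method, _size, _variant), value in table.items():
        acc.setdefault(method, []).append(value)
    return {m: float(np.mean(v)) for m, v in acc.items()}


def rank_and_select(report: EvalReport, size_grid: list[int]) -> tuple[str, int]:
    """Rank methods by both criteria and pick a method and sample size.

    The method is the first to appear in both the ascending-delta and the
    descending-R^2 top lists (ties broken by delta rank); the size is the
    smallest grid point from which both curves change by less than 10% of
    their range over the grid.  Results are written back into ``report``.
    """
    if not report.mse_table or not report.r2_table:
        raise EvaluationError("report tables are empty")
    mse_by_method = _method_means(report.mse_table)
    r2_by_method = _method_means(report.r2_table)
    mse_rank = sorted(mse_by_method, key=lambda m: (mse_by_method[m], m))
    r2_rank = sorted(r2_by_method, key=lambda m: (-r2_by_method[m], m))
    report.ranking_by_mse = mse_rank
    report.ranking_by_r2 = r2_rank

    top_mse = mse_rank[:TOP_LIST_SIZE]
    top_r2 = r2_rank[:TOP_LIST_SIZE]
    method = None
    for depth in range(1, TOP_LIST_SIZE + 1):
        joint = set(top_mse[:depth]) & set(top_r2[:depth])
        if joint:
            method = min(joint, key=lambda m: mse_rank.index(m))
            break
    if method is None:
        logger.warning("top-%d lists are disjoint; falling back to best R^2",
                       TOP_LIST_SIZE)
        method = r2_rank[0]

    def curve(table: dict) -> np.ndarray:
        values = []
        for s in size_grid:
            cell = [v for (m, size, _var), v in table.items()
                    if m == method and size == s]
            values.append(float(np.mean(cell)) if cell else np.nan)
        return np.asarray(values)

    mse_curve = curve(report.mse_table)
    r2_curve = curve(report.r2_table)
    sizes = sorted(size_grid)
    size = sizes[-1]
    mse_range = np.nanmax(mse_curve) - np.nanmin(mse_curve)
    r2_range = np.nanmax(r2_curve) - np.nanmin(r2_curve)
    for i, s in enumerate(sizes[:-1]):
        d_mse = abs(mse_curve[i + 1] - mse_curve[i])
        d_r2 = abs(r2_curve[i + 1] - r2_curve[i])
        flat_mse = mse_range == 0 or d_mse < PLATEAU_FRACTION * mse_range
        flat_r2 = r2_range == 0 or d_r2 < PLATEAU_FRACTION * r2_range
        if flat_mse and flat_r2:
            size = s
            break
    report.recommended_method = method
    report.recommended_size = int(size)
    return method, int(size)
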