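"""Distributive-mode weighted-sum ranking of interventions.

Each criterion column of the interventions x criteria matrix is divided by
its column sum ("distributive mode"), so entries become dimensionless
shares and the weighted sum of shares is itself a share: composite scores
sum to 1 across the interventions of a run.  Rankings are therefore
invariant to the units of any single criterion.

The five default criteria and their weights:

======================  ======  =========================================
criterion               weight  raw unit
======================  ======  =========================================
people_affected          0.133  persons potentially affected
cost_effectiveness       0.293  tier score (best buy 3 / >I$100 2 / none 1)
attributable_burden      0.337  DALY per 100,000
hospitalization          0.160  preventable admissions (4x4 model)
income_level_difference  0.077  absolute prevalence gap between income levels
======================  ======  =========================================

Risk-factor (objective 3) and clinical (objective 4) interventions are
always ranked in separate runs, never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "McdaError",
    "CRITERIA",
    "REFERENCE_WEIGHTS",
    "DEFAULT_TIEBREAK",
    "CE_TIER_SCORES",
    "reference_weight_vector",
    "normalize_distributive",
    "aggregate_scores",
    "rank_interventions",
    "build_ranking",
    "plot_ranking",
    "weight_sensitivity",
    "SensitivityResult",
]

#: Default criterion labels, in matrix column order.
CRITERIA = (
    "people_affected",
    "cost_effectiveness",
    "attributable_burden",
    "hospitalization",
    "income_level_difference",
)

#: Published expert-elicited weights for the five criteria.
REFERENCE_WEIGHTS = (0.133, 0.293, 0.337, 0.160, 0.077)

#: Ties are broken by the largest-weight criterion, then by code.
DEFAULT_TIEBREAK = ("attributable_burden",)

#: Numeric encoding of the three cost-effectiveness tiers.
CE_TIER_SCORES = {"best_buy": 3.0, "effective_gt_100": 2.0, "no_cea": 1.0}


class McdaError(ValueError):
    """Invalid ranking input."""


def reference_weight_vector() -> pd.Series:
    """The published five-criterion weight vector as a labelled Series."""
    return pd.Series(REFERENCE_WEIGHTS, index=list(CRITERIA), name="weight")


def _as_weight_series(weights: Union[pd.Series, Mapping, Sequence[float]],
                      columns: Sequence[str]) -> pd.Series:
    if isinstance(weights, pd.Series):
        w = weights.astype(float)
    elif isinstance(weights, Mapping):
        w = pd.Series(weights, dtype=float)
    else:
        w = pd.Series(list(weights), index=list(columns), dtype=float)
    missing = [c for c in columns if c not in w.index]
    extra = [c for c in w.index if c not in columns]
    if missing or extra:
        raise McdaError(
            f"weight labels do not match criteria columns "
            f"(missing {missing}, extra {extra})"
        )
    if (w < 0).any() or not np.isfinite(w.to_numpy()).all():
        raise McdaError("weights must be finite and nonnegative")
    return w.reindex(list(columns))


def normalize_distributive(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide every column by its sum.

    Negative entries are rejected (naming row and column).  An all-zero
    column is left as zeros and a warning recorded: it contributes nothing
    to the composite score.
    """
    arr = matrix.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise McdaError("criteria matrix contains non-finite values")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise McdaError(
            f"negative criterion value at row {matrix.index[i]!r}, "
            f"column {matrix.columns[j]!r}"
        )
    sums = arr.sum(axis=0)
    zero = sums == 0
    if zero.any():
        cols = list(matrix.columns[zero])
        warnings.warn(
            f"all-zero criterion column(s) {cols}: left as zeros",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, sums)
    return pd.DataFrame(
        arr / safe, index=matrix.index, columns=matrix.columns
    )


def aggregate_scores(
    norm: pd.DataFrame,
    weights: Union[pd.Series, Mapping, Sequence[float]],
) -> pd.Series:
    """Composite score per intervention: the weighted sum of its shares.

    With weights summing to 1 and no all-zero column, the scores sum to 1.
    """
    w = _as_weight_series(weights, norm.columns)
    scores = norm.to_numpy(dtype=float) @ w.to_numpy()
    return pd.Series(scores, index=norm.index, name="score")


def rank_interventions(
    scores: Union[pd.Series, Mapping[str, float]],
    tiebreak_values: Optional[pd.DataFrame] = None,
    tiebreak: Sequence[str] = DEFAULT_TIEBREAK,
) -> pd.DataFrame:
    """Order interventions by descending composite score.

    Exact ties are broken by the higher value on each criterion of
    ``tiebreak`` in turn (looked up in ``tiebreak_values``), then by
    lexicographic code, so the ordering is total and deterministic.
    Returns a frame with columns ``rank`` (1-based, dense), ``code``,
    ``score``.
    """
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        bad = list(s.index[s.isna()])
        raise McdaError(f"NaN score for {bad[:5]}")
    if not np.isfinite(s.to_numpy()).all():
        raise McdaError("scores must be finite")
    frame = pd.DataFrame({"code": s.index.astype(str), "score": s.to_numpy()})
    sort_cols = ["score"]
    ascending = [False]
    if tiebreak_values is not None:
        for crit in tiebreak:
            if crit not in tiebreak_values.columns:
                raise McdaError(f"tiebreak criterion {crit!r} not in matrix")
            frame[f"_tb_{crit}"] = (
                tiebreak_values[crit].reindex(s.index).to_numpy(dtype=float)
            )
            sort_cols.append(f"_tb_{crit}")
            ascending.append(False)
    sort_cols.append("code")
    ascending.append(True)
    frame = frame.sort_values(
        sort_cols, ascending=ascending, kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame[["rank", "code", "score"]]


def build_ranking(
    matrix: pd.DataFrame,
    weights: Union[pd.Series, Mapping, Sequence[float]],
    tiebreak: Sequence[str] = DEFAULT_TIEBREAK,
) -> pd.DataFrame:
    """Full ranking from a raw criteria matrix.

    Normalizes in distributive mode, scores, ranks, and attaches
    per-criterion contribution shares (``contrib_<criterion>``, summing to
    the composite score row-wise) and per-criterion ranks
    (``rank_<criterion>``, rank of the intervention within that column).
    """
    norm = normalize_distributive(matrix)
    w = _as_weight_series(weights, norm.columns)
    scores = aggregate_scores(norm, w)
    ranking = rank_interventions(scores, tiebreak_values=norm, tiebreak=tiebreak)
    contrib = norm.mul(w, axis=1)
    crit_ranks = norm.rank(ascending=False, method="min").astype(int)
    for crit in norm.columns:
        ranking[f"contrib_{crit}"] = (
            contrib[crit].reindex(ranking["code"]).to_numpy()
        )
    for crit in norm.columns:
        ranking[f"rank_{crit}"] = (
            crit_ranks[crit].reindex(ranking["code"]).to_numpy()
        )
    return ranking


def plot_ranking(ranking: pd.DataFrame, path, top: int = 20) -> None:
    """Horizontal bar chart of the top composite scores (PNG/PDF export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    head = ranking.nsmallest(top, "rank").iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(head) + 1.2))
    ax.barh(head["code"], head["score"], color="#31688e")
    ax.set_xlabel("composite score (share)")
    ax.set_title(f"Top {len(head)} prioritized interventions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class SensitivityResult:
    """Rank stability under random weight perturbation."""

    rank_range: pd.DataFrame  # columns: code, base_rank, min_rank, max_rank
    top1_code: str
    top1_stability: float
    reps: int
    perturbation: float

    def to_dict(self) -> dict:
        return {
            "top1_code": self.top1_code,
            "top1_stability": self.top1_stability,
            "reps": self.reps,
            "perturbation": self.perturbation,
            "rank_range": self.rank_range.to_dict(orient="records"),
        }


def weight_sensitivity(
    matrix: pd.DataFrame,
    weights: Union[pd.Series, Mapping, Sequence[float]],
    perturbation: float = 0.2,
    reps: int = 500,
    seed: int = 0,
    tiebreak: Sequence[str] = DEFAULT_TIEBREAK,
) -> SensitivityResult:
    """Re-rank under multiplicatively jittered weights.

    Each rep multiplies every weight by an independent Uniform(1-p, 1+p)
    draw and renormalizes.  Reports, per intervention, the range of ranks
    observed, and the fraction of reps in which the base top-ranked
    intervention stays on top.
    """
    if not 0 < perturbation < 1:
        raise McdaError("perturbation must be in (0, 1)")
    if reps < 1:
        raise McdaError("reps must be >= 1")
    norm = normalize_distributive(matrix)
    w = _as_weight_series(weights, norm.columns)
    base = rank_interventions(
        aggregate_scores(norm, w), tiebreak_values=norm, tiebreak=tiebreak
    )
    codes = base["code"].tolist()
    base_rank = dict(zip(base["code"], base["rank"]))
    top1 = base.loc[0, "code"]
    rng = np.random.default_rng(seed)
    min_rank = {c: base_rank[c] for c in codes}
    max_rank = {c: base_rank[c] for c in codes}
    hits = 0
    for _ in range(reps):
        factors = rng.uniform(1 - perturbation, 1 + perturbation, size=len(w))
        wp = w * factors
        wp = wp / wp.sum()
        rep = rank_interventions(
            aggregate_scores(norm, wp), tiebreak_values=norm, tiebreak=tiebreak
        )
        if rep.loc[0, "code"] == top1:
            hits += 1
        for code, rank in zip(rep["code"], rep["rank"]):
            if rank < min_rank[code]:
                min_rank[code] = rank
            if rank > max_rank[code]:
                max_rank[code] = rank
    rank_range = pd.DataFrame(
        {
            "code": codes,
            "base_rank": [base_rank[c] for c in codes],
            "min_rank": [min_rank[c] for c in codes],
            "max_rank": [max_rank[c] for c in codes],
        }
    )
    return SensitivityResult(
        rank_range=rank_range,
        top1_code=str(top1),
        top1_stability=hits / reps,
        reps=reps,
        perturbation=perturbation,
    )
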