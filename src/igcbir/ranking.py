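"""Ranking evaluation with DCG/nDCG under a linear relevance scheme.

The ground-truth rank of each catalogue image determines its relevance
gain: for a catalogue of p images, rel(rank i) = 1 + 0.5 · (p − i), so a
10-image catalogue spans 5.5 (most similar) down to 1 (least similar) in
steps of 0.5.  A ranking is scored by

    DCG_p = Σ_{i=1..p} (2^{rel_i} − 1) / log2(i + 1),
    nDCG_p = DCG_p / IDCG_p,

where IDCG is the DCG of the ground-truth ordering itself.  Truncated
("Top-k") evaluation keeps the relevances of the full p-item scheme and
truncates both sums at k.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RelevanceScheme:
    min_relevance: float = 1.0
    step: float = 0.5
    p: int = 10

    def rel(self, rank: int) -> float:
        """Relevance of ground-truth rank ``rank`` (1-based)."""
        if not 1 <= rank <= self.p:
            raise ValueError(f"rank must be in 1..{self.p}, got {rank}")
        return self.min_relevance + self.step * (self.p - rank)


@dataclass(frozen=True)
class RankingAnnotation:
    """An ordered catalogue as produced by a method or a human rater."""
    split_id: str
    rater_or_method_id: str
    ranked_ids: tuple[str, ...]


@dataclass
class EvalResult:
    rows: pd.DataFrame      # split_id, method, p_eval, ndcg
    summary: pd.DataFrame   # method, p_eval, min, q1, median, q3, max

    def to_csv(self, rows_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.rows.to_csv(rows_path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, index=False)


# ---------------------------------------------------------------------------
# Core metric
# ---------------------------------------------------------------------------

def assign_relevance(ground_truth: list[str] | tuple[str, ...],
                     scheme: RelevanceScheme) -> dict[str, float]:
    """Map each catalogue id to its relevance given the ground-truth order."""
    if len(ground_truth) != scheme.p:
        raise ValueError(f"ground truth has {len(ground_truth)} items, scheme expects p={scheme.p}")
    if len(set(ground_truth)) != len(ground_truth):
        raise ValueError("duplicate ids in ground truth")
    return {cid: scheme.rel(i + 1) for i, cid in enumerate(ground_truth)}


def dcg(ranking: list[str] | tuple[str, ...], relevance: dict[str, float],
        p_eval: int | None = None) -> float:
    """Discounted cumulative gain of ``ranking`` truncated at ``p_eval``."""
    p_eval = len(ranking) if p_eval is None else p_eval
    if p_eval > len(ranking):
        raise ValueError(f"p_eval={p_eval} exceeds ranking length {len(ranking)}")
    total = 0.0
    for i, cid in enumerate(ranking[:p_eval], start=1):
        if cid not in relevance:
            raise ValueError(f"item {cid!r} has no assigned relevance")
        total += (2.0 ** relevance[cid] - 1.0) / np.log2(i + 1)
    return total


def ndcg(ranking, ground_truth, scheme: RelevanceScheme | None = None,
         p_eval: int | None = None) -> float:
    """nDCG of ``ranking`` against ``ground_truth`` (ideal) order, in (0, 1]."""
    if set(ranking) != set(ground_truth) or len(ranking) != len(ground_truth):
        raise ValueError("ranking and ground truth must be permutations of the same id set")
    scheme = scheme or RelevanceScheme(p=len(ground_truth))
    relevance = assign_relevance(ground_truth, scheme)
    return dcg(ranking, relevance, p_eval) / dcg(ground_truth, relevance, p_eval)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _five_number(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def _summarize(rows: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for (method, p_eval), grp in rows.groupby(["method", "p_eval"], sort=False):
        recs.append({"method": method, "p_eval": p_eval,
                     **_five_number(grp["ndcg"].to_numpy()),
                     "mean": float(grp["ndcg"].mean()), "n": len(grp)})
    return pd.DataFrame(recs)


def evaluate_methods(splits, results, p_evals=(10, 3)) -> EvalResult:
    """Score retrieval results / annotations against the splits' ground truth.

    ``results`` may mix :class:`~igcbir.retrieval.RetrievalResult` and
    :class:`RankingAnnotation`; the ground truth is each split's stored
    catalogue order.
    """
    gt = {sp.split_id: tuple(sp.catalogue_ids) for sp in splits}
    rows = []
    for res in results:
        if res.split_id not in gt:
            raise ValueError(f"result references unknown split {res.split_id!r}")
        name = getattr(res, "method_id", None) or res.rater_or_method_id
        truth = gt[res.split_id]
        scheme = RelevanceScheme(p=len(truth))
        for p_eval in p_evals:
            rows.append({"split_id": res.split_id, "method": name, "p_eval": p_eval,
                         "ndcg": ndcg(res.ranked_ids, truth, scheme, p_eval)})
    df = pd.DataFrame(rows)
    return EvalResult(rows=df, summary=_summarize(df))


def interrater(annotations: list[RankingAnnotation], ground_truth_rater: str,
               p_evals=(10, 3)) -> EvalResult:
    """Score each rater's rankings against a designated reference rater."""
    ref = {a.split_id: a.ranked_ids for a in annotations
           if a.rater_or_method_id == ground_truth_rater}
    if not ref:
        raise ValueError(f"reference rater {ground_truth_rater!r} has no annotations")
    rows = []
    for a in annotations:
        if a.rater_or_method_id == ground_truth_rater:
            continue
        if a.split_id not in ref:
            raise ValueError(f"reference rater missing split {a.split_id!r}")
        truth = ref[a.split_id]
        scheme = RelevanceScheme(p=len(truth))
        for p_eval in p_evals:
            rows.append({"split_id": a.split_id, "method": a.rater_or_method_id,
                         "p_eval": p_eval, "ndcg": ndcg(a.ranked_ids, truth, scheme, p_eval)})
    df = pd.DataFrame(rows)
    return EvalResult(rows=df, summary=_summarize(df))


# ---------------------------------------------------------------------------
# Annotation IO and plots
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[RankingAnnotation]:
    """CSV ``split_id,rater_id,rank,sample_id`` -> annotations (rank-ordered)."""
    df = pd.read_csv(path, dtype={"split_id": str, "rater_id": str, "sample_id": str})
    out = []
    for (split_id, rater), grp in df.groupby(["split_id", "rater_id"], sort=True):
        grp = grp.sort_values("rank")
        if list(grp["rank"]) != list(range(1, len(grp) + 1)):
            raise ValueError(f"{split_id}/{rater}: ranks must be 1..p without gaps")
        out.append(RankingAnnotation(split_id, rater, tuple(grp["sample_id"])))
    return out


def write_annotations(annotations: list[RankingAnnotation], path: str | Path) -> None:
    rows = [{"split_id": a.split_id, "rater_id": a.rater_or_method_id,
             "rank": i + 1, "sample_id": sid}
            for a in annotations for i, sid in enumerate(a.ranked_ids)]
    pd.DataFrame(rows).to_csv(path, index=False)


def boxplot(result: EvalResult, p_eval: int, path: str | Path) -> None:
    """Box-and-whisker plot of per-split nDCG by method, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    sub = result.rows[result.rows["p_eval"] == p_eval]
    methods = list(dict.fromkeys(sub["method"]))
    data = [sub.loc[sub["method"] == m, "ndcg"].to_numpy() for m in methods]
    fig, ax = plt.subplots(figsize=(1.2 * len(methods) + 2, 4))
    ax.boxplot(data, tick_labels=methods)
    ax.set_ylabel(f"nDCG (Top-{p_eval})")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
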