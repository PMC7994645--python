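"""Within-sample drug ranking and prediction-quality metrics.

Drugs are ranked within each sample by predicted AAC (descending, so rank 1
is the drug predicted most effective). Evaluation against measured responses
reports per-sample Spearman rho (BH-adjusted across samples), RMSE/MSE,
the proportion of predictions within absolute-error cutoffs, rank-position
differences, and the same restricted to each sample's top-k measured drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import benjamini_hochberg

ERROR_CUTOFFS = (0.05, 0.10, 0.15, 0.25)
RANK_CUTOFFS = (20, 50)


@dataclass
class RankingReport:
    per_sample: pd.DataFrame  # rho, p, q, rmse, mse, n per sample
    per_entry: pd.DataFrame   # sample, drug, pred, measured, abs_err, ranks, rank_delta
    summary: dict = field(default_factory=dict)


def rank_drugs(predictions: pd.Series) -> list[str]:
    """Drugs ordered most-effective-first; ties break lexicographically by id."""
    obs = predictions.dropna()
    if len(obs) < 2:
        raise ValueError("need >= 2 drugs to rank")
    return sorted(obs.index, key=lambda d: (-obs[d], d))


def evaluate(pred: pd.DataFrame, measured: pd.DataFrame, top_k: int = 20,
             error_cutoffs=ERROR_CUTOFFS, rank_cutoffs=RANK_CUTOFFS,
             min_drugs: int = 5, anchor: str = "measured") -> RankingReport:
    """Compare predicted with measured AAC over the overlapping drugs/samples.

    Rank deltas |rank_pred - rank_meas| use average ranks on ties; the top-k
    analysis restricts to each sample's ``top_k`` best drugs by measured
    response (``anchor='predicted'`` switches to predicted ranks). Samples
    with fewer than ``min_drugs`` overlapping drugs are excluded.
    """
    if anchor not in ("measured", "predicted"):
        raise ValueError("anchor must be 'measured' or 'predicted'")
    drugs = pred.index.intersection(measured.index)
    samples = pred.columns.intersection(measured.columns)
    per_sample_rows, entry_rows = [], []
    excluded = []
    for sample in samples:
        p = pred.loc[drugs, sample]
        m = measured.loc[drugs, sample]
        ok = p.notna() & m.notna()
        if ok.sum() < min_drugs:
            excluded.append(sample)
            continue
        p, m = p[ok], m[ok]
        err = (p - m).abs()
        rank_p = (-p).rank(method="average")
        rank_m = (-m).rank(method="average")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant inputs give NaN rho
            rho, pval = stats.spearmanr(p.to_numpy(), m.to_numpy())
        mse = float(np.mean((p - m) ** 2))
        per_sample_rows.append({"sample": sample, "rho": float(rho), "p": float(pval),
                                "rmse": float(np.sqrt(mse)), "mse": mse, "n": int(ok.sum())})
        for d in p.index:
            entry_rows.append({
                "sample": sample, "drug": d, "pred": float(p[d]), "measured": float(m[d]),
                "abs_err": float(err[d]), "rank_pred": float(rank_p[d]),
                "rank_meas": float(rank_m[d]),
                "rank_delta": float(abs(rank_p[d] - rank_m[d])),
            })
    per_sample = pd.DataFrame(per_sample_rows,
                              columns=["sample", "rho", "p", "rmse", "mse", "n"])
    if not per_sample.empty:
        per_sample["q"] = benjamini_hochberg(per_sample["p"].to_numpy())
    per_entry = pd.DataFrame(entry_rows, columns=["sample", "drug", "pred", "measured",
                                                  "abs_err", "rank_pred", "rank_meas",
                                                  "rank_delta"])

    summary: dict = {"n_samples": len(per_sample), "excluded_samples": excluded,
                     "top_k": top_k, "anchor": anchor}
    if not per_entry.empty:
        errs = per_entry["abs_err"].to_numpy()
        deltas = per_entry["rank_delta"].to_numpy()
        summary["error_within"] = {str(c): float(np.mean(errs <= c)) for c in error_cutoffs}
        summary["rank_delta_within"] = {str(c): float(np.mean(deltas < c)) for c in rank_cutoffs}
        anchor_col = "rank_meas" if anchor == "measured" else "rank_pred"
        top = per_entry[per_entry[anchor_col] <= top_k]
        if not top.empty:
            t_err = top["abs_err"].to_numpy()
            t_del = top["rank_delta"].to_numpy()
            summary["top_k_error_within"] = {str(c): float(np.mean(t_err <= c)) for c in error_cutoffs}
            summary["top_k_rank_delta_within"] = {str(c): float(np.mean(t_del < c)) for c in rank_cutoffs}
        summary["median_rho"] = float(per_sample["rho"].median())
        summary["mean_rho"] = float(per_sample["rho"].mean())
        summary["median_mse"] = float(per_sample["mse"].median())
        summary["max_mse"] = float(per_sample["mse"].max())
    return RankingReport(per_sample=per_sample, per_entry=per_entry, summary=summary)
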