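"""Selection of predictor D features for each target drug.

Every drug's D profile is a candidate predictor for every other drug (and
for itself): D profiles of drugs with a shared mode of action correlate.
Per target drug, candidates are Spearman-correlated with the target's
responses across training cell lines and the strongest are kept per
direction: significant candidates up to a cap of 30 per direction, and at
least 7 per direction (taken by |rho| irrespective of significance when
fewer than 7 are significant), giving 14-60 predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix


@dataclass
class PredictorSet:
    target_drug: str
    predictors: list[dict] = field(default_factory=list)  # {drug, rho, p, direction}
    cap: int = 30
    floor: int = 7
    flagged: bool = False  # fewer than `floor` candidates existed in a direction

    @property
    def predictor_ids(self) -> list[str]:
        return [p["drug"] for p in self.predictors]

    def __post_init__(self):
        ids = self.predictor_ids
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate predictors for {self.target_drug}")


def spearman_with_response(d_matrix: DistanceMatrix, target_aac: pd.Series,
                           min_pairs: int = 5) -> pd.DataFrame:
    """Spearman rho (average ranks on ties) of every drug's D profile vs the target AAC.

    Pairs with missing values on either side are dropped per candidate;
    candidates with < ``min_pairs`` complete pairs or a constant vector are
    skipped. Two-sided p from the t approximation with n-2 df.
    """
    rows = []
    y_all = target_aac
    for drug in d_matrix.drug_ids:
        x_all = d_matrix.d.loc[drug]
        common = x_all.index.intersection(y_all.index)
        x = x_all[common].to_numpy(dtype=float)
        y = y_all[common].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            continue
        x, y = x[ok], y[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        res = stats.spearmanr(x, y)
        rows.append({"drug": drug, "rho": float(res.statistic), "p": float(res.pvalue),
                     "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["drug", "rho", "p", "n"])


def select_predictors(correlations: pd.DataFrame, target_drug: str,
                      alpha: float = 0.05, cap: int = 30, floor: int = 7) -> PredictorSet:
    """Apply the per-direction cap/floor rule to a correlation table.

    Per direction (rho > 0 / rho < 0): keep the significant (p < alpha)
    candidates ranked by |rho|, truncated to ``cap``; when fewer than
    ``floor`` are significant, take the top ``floor`` by |rho| from all
    candidates in that direction regardless of significance. Ties on |rho|
    break lexicographically by drug id for determinism.
    """
    if correlations.empty:
        raise ValueError(f"no correlation candidates for {target_drug}")
    chosen: list[dict] = []
    flagged = False
    for direction, sign in (("+", 1), ("-", -1)):
        cand = correlations[np.sign(correlations["rho"]) == sign].copy()
        cand = cand.sort_values(["rho", "drug"], key=lambda s: -s.abs() if s.name == "rho" else s,
                                kind="mergesort")
        sig = cand[cand["p"] < alpha]
        if len(sig) >= floor:
            take = sig.head(cap)
        else:
            take = cand.head(floor)
            if len(cand) < floor:
                flagged = True
        for _, row in take.iterrows():
            chosen.append({"drug": row["drug"], "rho": float(row["rho"]),
                           "p": float(row["p"]), "direction": direction})
    if not chosen:
        raise ValueError(f"no predictors selectable for {target_drug}")
    return PredictorSet(target_drug=target_drug, predictors=chosen, cap=cap,
                        floor=floor, flagged=flagged)


def select_all(d_matrix: DistanceMatrix, responses, alpha: float = 0.05,
               cap: int = 30, floor: int = 7, min_pairs: int = 5) -> dict[str, PredictorSet]:
    """Predictor sets for every drug present in both the D matrix and responses."""
    out: dict[str, PredictorSet] = {}
    for drug in d_matrix.drug_ids:
        if drug not in responses.aac.index:
            continue
        corr = spearman_with_response(d_matrix, responses.aac.loc[drug], min_pairs)
        if corr.empty:
            continue
        try:
            out[drug] = select_predictors(corr, drug, alpha=alpha, cap=cap, floor=floor)
        except ValueError:
            continue
    return out


def write_predictor_sets(sets: dict[str, PredictorSet], path) -> None:
    with open(path, "w") as fh:
        json.dump({d: asdict(s) for d, s in sets.items()}, fh, indent=1)


def load_predictor_sets(path) -> dict[str, PredictorSet]:
    with open(path) as fh:
        payload = json.load(fh)
    return {d: PredictorSet(**s) for d, s in payload.items()}
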