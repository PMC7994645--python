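"""The internally normalized drug-response distance D.

For drug d and sample b,

    D(d, b) = (S_Q2 - R_Q2) + (S_Q3 - R_Q3)

where S_Q2/S_Q3 are the median and third quartile of the sample's
sensitivity-marker values and R_Q2/R_Q3 the same statistics of its
resistance-marker values. Because both sides are summaries of the same
sample, D needs no reference sample: adding a constant to all of a sample's
marker values leaves D unchanged. Higher D means the sample looks more like
a sensitive one for that drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsMatrix
from .discovery import EMDRCatalog, EMDREntry


class InsufficientCoverage(ValueError):
    """Too few non-missing marker values on one side to form quartiles."""


@dataclass
class DistanceMatrix:
    """D values (drugs x samples) with quartile components and marker coverage."""

    d: pd.DataFrame
    components: dict[str, pd.DataFrame] = field(default_factory=dict)  # S_Q2, S_Q3, R_Q2, R_Q3
    coverage_sens: pd.DataFrame | None = None
    coverage_res: pd.DataFrame | None = None
    norm_params: dict[str, tuple[float, float]] | None = None
    normalized: bool = False

    @property
    def drug_ids(self):
        return list(self.d.index)

    @property
    def sample_ids(self):
        return list(self.d.columns)


def compute_distance(sample_profile, entry: EMDREntry, min_markers: int = 5):
    """D for one sample against one drug's marker sets.

    ``sample_profile`` maps feature id -> value (missing values allowed).
    Requires at least ``min_markers`` non-missing values on each side;
    otherwise :class:`InsufficientCoverage` names the thin side rather than
    silently returning zero. Returns (D, components, coverage).
    """
    profile = pd.Series(sample_profile, dtype=float)

    def side_values(markers):
        vals = profile.reindex(pd.unique(pd.Index(markers))).to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    s_vals = side_values(entry.sensitivity)
    r_vals = side_values(entry.resistance)
    if len(s_vals) < min_markers:
        raise InsufficientCoverage(
            f"{entry.drug}: {len(s_vals)} sensitivity-marker values (< {min_markers})"
        )
    if len(r_vals) < min_markers:
        raise InsufficientCoverage(
            f"{entry.drug}: {len(r_vals)} resistance-marker values (< {min_markers})"
        )
    s_q2, s_q3 = np.quantile(s_vals, [0.5, 0.75])
    r_q2, r_q3 = np.quantile(r_vals, [0.5, 0.75])
    d = (s_q2 - r_q2) + (s_q3 - r_q3)
    components = {"S_Q2": float(s_q2), "S_Q3": float(s_q3), "R_Q2": float(r_q2), "R_Q3": float(r_q3)}
    coverage = {"sensitivity": int(len(s_vals)), "resistance": int(len(r_vals))}
    return float(d), components, coverage


def distance_matrix(omics: OmicsMatrix, catalog: EMDRCatalog, min_markers: int = 5) -> DistanceMatrix:
    """D for every (drug, sample); entries without coverage stay missing (NaN).

    ``omics`` should be cell-line averaged (one column per sample to score).
    Quartiles are computed per sample over the non-missing marker values only,
    so sporadic missing markers degrade coverage rather than biasing D.
    """
    if not catalog.entries:
        raise ValueError("empty EMDR catalog")
    samples = omics.sample_ids
    drugs = list(catalog.entries)
    shape = (len(drugs), len(samples))
    d = np.full(shape, np.nan)
    comps = {k: np.full(shape, np.nan) for k in ("S_Q2", "S_Q3", "R_Q2", "R_Q3")}
    cov_s = np.zeros(shape, dtype=int)
    cov_r = np.zeros(shape, dtype=int)

    arr = omics.values.to_numpy(dtype=float)
    feature_index = pd.Index(omics.feature_ids)
    for gi, drug in enumerate(drugs):
        entry = catalog.entries[drug]
        s_rows = feature_index.get_indexer_for(pd.unique(pd.Index(entry.sensitivity)))
        r_rows = feature_index.get_indexer_for(pd.unique(pd.Index(entry.resistance)))
        s_rows = s_rows[s_rows >= 0]
        r_rows = r_rows[r_rows >= 0]
        s_block = arr[s_rows, :]
        r_block = arr[r_rows, :]
        ns = np.sum(np.isfinite(s_block), axis=0)
        nr = np.sum(np.isfinite(r_block), axis=0)
        cov_s[gi] = ns
        cov_r[gi] = nr
        ok = (ns >= min_markers) & (nr >= min_markers)
        if not ok.any():
            continue
        with np.errstate(all="ignore"):
            sq = np.nanquantile(s_block, [0.5, 0.75], axis=0) if s_block.size else np.full((2, len(samples)), np.nan)
            rq = np.nanquantile(r_block, [0.5, 0.75], axis=0) if r_block.size else np.full((2, len(samples)), np.nan)
        comps["S_Q2"][gi, ok] = sq[0, ok]
        comps["S_Q3"][gi, ok] = sq[1, ok]
        comps["R_Q2"][gi, ok] = rq[0, ok]
        comps["R_Q3"][gi, ok] = rq[1, ok]
        d[gi, ok] = (sq[0, ok] - rq[0, ok]) + (sq[1, ok] - rq[1, ok])

    return DistanceMatrix(
        d=pd.DataFrame(d, index=drugs, columns=samples),
        components={k: pd.DataFrame(v, index=drugs, columns=samples) for k, v in comps.items()},
        coverage_sens=pd.DataFrame(cov_s, index=drugs, columns=samples),
        coverage_res=pd.DataFrame(cov_r, index=drugs, columns=samples),
    )


def fit_minmax(train: DistanceMatrix) -> dict[str, tuple[float, float]]:
    """Per-drug (min, max) of training D values for the 0-1 normalization.

    Drugs with fewer than two distinct finite training D values are excluded
    (they cannot be normalized, hence cannot be modeled).
    """
    params: dict[str, tuple[float, float]] = {}
    for drug in train.drug_ids:
        row = train.d.loc[drug].to_numpy(dtype=float)
        row = row[np.isfinite(row)]
        if row.size < 2 or np.ptp(row) == 0:
            continue
        params[drug] = (float(row.min()), float(row.max()))
    return params


def apply_minmax(dm: DistanceMatrix, norm_params: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Scale D to [0, 1] with stored training (min, max); new samples are clipped."""
    drugs = [d for d in dm.drug_ids if d in norm_params]
    out = pd.DataFrame(index=drugs, columns=dm.d.columns, dtype=float)
    for drug in drugs:
        lo, hi = norm_params[drug]
        out.loc[drug] = np.clip((dm.d.loc[drug] - lo) / (hi - lo), 0.0, 1.0)
    return DistanceMatrix(
        d=out,
        coverage_sens=None if dm.coverage_sens is None else dm.coverage_sens.loc[drugs],
        coverage_res=None if dm.coverage_res is None else dm.coverage_res.loc[drugs],
        norm_params=dict(norm_params),
        normalized=True,
    )


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.d.to_csv(path, sep="\t", index_label="drug_id")


def load_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix(d=df)
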