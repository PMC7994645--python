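"""Marker-set enrichment, delta enrichment, and drug-drug similarity scores.

For each drug and marker side, enrichment of a gene/phosphosite set is the
fold ratio [a/b] / [c/d] (a = markers in the set, b = marker count, c =
background features in the set, d = background size) with an upper-tail
hypergeometric p and BH adjustment. Delta enrichment (sensitivity-side ratio
minus resistance-side ratio) profiles a drug's mode of action; Pearson
correlation of delta-enrichment vectors between drugs, rescaled so the score
distribution has median 0 and sd 1, gives drug-drug similarity scores with
one-sample-t p values against that distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import benjamini_hochberg


@dataclass
class SimilarityMatrix:
    raw_r: pd.DataFrame
    scaled: pd.DataFrame
    p: pd.DataFrame


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT collection: one set per line (id, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for sid, members in sets.items():
            fh.write("\t".join([sid, description, *members]) + "\n")


def enrich_emdr(markers, gene_sets: dict[str, list[str]], background,
                min_set_size: int = 3) -> pd.DataFrame:
    """Over-representation of a marker set in each gene set.

    Gene sets are intersected with the background before counting; sets
    smaller than ``min_set_size`` after intersection are skipped. p values
    are upper-tail hypergeometric (P[X >= a]), BH-adjusted across sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    markers = set(markers)
    if not markers <= background:
        raise ValueError("markers must be a subset of the background")
    b = len(markers)
    d = len(background)
    rows = []
    for sid, members in gene_sets.items():
        in_bg = set(members) & background
        c = len(in_bg)
        if c < min_set_size:
            continue
        a = len(markers & in_bg)
        ratio = (a / b) / (c / d) if b else np.nan
        # P[X >= a] drawing b from d with c successes
        p = float(stats.hypergeom.sf(a - 1, d, c, b)) if b else np.nan
        rows.append({"set_id": sid, "a": a, "b": b, "c": c, "d": d, "ratio": ratio, "p": p})
    out = pd.DataFrame(rows, columns=["set_id", "a", "b", "c", "d", "ratio", "p"])
    if not out.empty:
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def delta_enrichment(enrich_sens: pd.DataFrame, enrich_res: pd.DataFrame) -> pd.Series:
    """Per set: sensitivity-side enrichment ratio minus resistance-side ratio.

    A side with no computed record for a set contributes ratio 0.
    """
    s = enrich_sens.set_index("set_id")["ratio"] if not enrich_sens.empty else pd.Series(dtype=float)
    r = enrich_res.set_index("set_id")["ratio"] if not enrich_res.empty else pd.Series(dtype=float)
    all_sets = s.index.union(r.index)
    return s.reindex(all_sets, fill_value=0.0) - r.reindex(all_sets, fill_value=0.0)


def enrichment_profile(catalog, gene_sets, background, min_set_size: int = 3) -> pd.DataFrame:
    """Delta-enrichment matrix (drugs x sets) over a whole catalog."""
    rows = {}
    for drug, entry in catalog.entries.items():
        es = enrich_emdr(set(entry.sensitivity) & set(background), gene_sets, background, min_set_size)
        er = enrich_emdr(set(entry.resistance) & set(background), gene_sets, background, min_set_size)
        rows[drug] = delta_enrichment(es, er)
    return pd.DataFrame(rows).T.sort_index()


def similarity_scores(delta_matrix: pd.DataFrame, min_overlap: int = 3) -> SimilarityMatrix:
    """Drug-drug similarity from pairwise Pearson over delta-enrichment vectors.

    Off-diagonal r values (each unordered pair once) are rescaled so their
    distribution has median 0 and sd 1 (self-correlations excluded); each
    pair's p is a one-sample t of the full score distribution against that
    pair's score. Drugs with constant delta vectors yield missing pairs.
    """
    if delta_matrix.shape[0] < 3 or delta_matrix.shape[1] < 3:
        raise ValueError("need >= 3 drugs and >= 3 sets")
    # pairwise-complete Pearson; constant vectors produce NaN columns/rows
    raw = delta_matrix.T.corr(method="pearson", min_periods=min_overlap)
    drugs = list(raw.index)
    iu = np.triu_indices(len(drugs), k=1)
    offdiag = raw.to_numpy()[iu]
    finite = offdiag[np.isfinite(offdiag)]
    if finite.size < 2:
        raise ValueError("too few finite pairwise correlations to scale")
    med = float(np.median(finite))
    sd = float(np.std(finite, ddof=1))
    if sd == 0:
        raise ValueError("degenerate similarity distribution (zero spread)")
    scaled = (raw - med) / sd
    np.fill_diagonal(scaled.values, np.nan)

    scaled_off = scaled.to_numpy()[iu]
    dist = scaled_off[np.isfinite(scaled_off)]
    pmat = pd.DataFrame(np.nan, index=drugs, columns=drugs, dtype=float)
    for i, j in zip(*iu):
        score = scaled.iat[i, j]
        if np.isfinite(score):
            p = float(stats.ttest_1samp(dist, popmean=score).pvalue)
            pmat.iat[i, j] = p
            pmat.iat[j, i] = p
    return SimilarityMatrix(raw_r=raw, scaled=scaled, p=pmat)
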