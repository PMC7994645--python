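"""Data containers, TSV readers/writers, and panel normalization rules.

The two core containers are :class:`OmicsMatrix` (abundance values,
features x samples, with a replicate -> cell line map) and
:class:`DrugResponseTable` (AAC drug responses, drugs x cell lines,
scaled to [0, 1]). AAC is the area above the dose-response curve:
0 means the drug had no effect, 1 means maximum cell killing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_LAYERS = ("phospho", "proteome", "rnaseq")


class PanelError(ValueError):
    """Raised on malformed or degenerate panel inputs."""


@dataclass
class OmicsMatrix:
    """Abundance matrix, features (rows) x samples (columns).

    Parameters
    ----------
    values
        Real-valued DataFrame; NaN marks a missing measurement. Values are
        never imputed here - downstream steps handle missingness explicitly.
    replicate_map
        sample_id -> cell_line_id. Identity map when samples are already
        cell-line level.
    layer
        One of ``phospho``, ``proteome``, ``rnaseq``.
    normalized
        True once features have been centered and scaled.
    zero_variance_features
        Features flagged as constant during normalization.
    """

    values: pd.DataFrame
    replicate_map: dict[str, str]
    layer: str = "phospho"
    normalized: bool = False
    zero_variance_features: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.layer not in VALID_LAYERS:
            raise PanelError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise PanelError(f"duplicate feature ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.replicate_map]
        if missing:
            raise PanelError(f"replicate_map does not cover samples: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_line_ids(self) -> list[str]:
        seen = {}
        for s in self.values.columns:
            seen.setdefault(self.replicate_map[s], None)
        return list(seen)

    def missingness(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def restrict_samples(self, samples) -> "OmicsMatrix":
        samples = [s for s in self.values.columns if s in set(samples)]
        return replace(
            self,
            values=self.values[samples],
            replicate_map={s: self.replicate_map[s] for s in samples},
        )


@dataclass
class DrugResponseTable:
    """AAC responses, drugs (rows) x cell lines (columns), NaN = not assayed."""

    aac: pd.DataFrame
    scaled: bool = False

    def __post_init__(self):
        if self.aac.index.has_duplicates:
            raise PanelError("duplicate drug ids in response table")
        vals = self.aac.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise PanelError("non-finite AAC values present")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.aac.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.aac.columns)

    def restrict_cell_lines(self, lines) -> "DrugResponseTable":
        lines = [c for c in self.aac.columns if c in set(lines)]
        return DrugResponseTable(self.aac[lines], scaled=self.scaled)


# ---------------------------------------------------------------------------
# readers / writers


def _read_numeric_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        cleaned = df[col].str.strip().replace("", np.nan)
        try:
            # float() round-trips the shortest repr bit-exactly
            out[col] = cleaned.astype(float)
        except ValueError:
            for row, cell in cleaned.items():
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise PanelError(
                        f"non-numeric cell at row {row!r}, column {col!r}: {cell!r}"
                    ) from None
            raise
    return out


def load_replicate_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise PanelError("replicate map needs two columns: sample_id, cell_line_id")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_omics_matrix(path, layer: str = "phospho", replicate_map=None) -> OmicsMatrix:
    """Read a features-x-samples abundance TSV.

    First column holds feature ids, header row holds sample ids; empty cells
    become missing values. ``replicate_map`` may be a path to a two-column
    TSV or a dict; when absent, each sample is its own cell line.
    """
    values = _read_numeric_tsv(path)
    if values.index.has_duplicates:
        dups = sorted(values.index[values.index.duplicated()].unique())
        raise PanelError(f"duplicate feature ids: {dups}")
    if replicate_map is None:
        rep = {s: s for s in values.columns}
    elif isinstance(replicate_map, dict):
        rep = dict(replicate_map)
    else:
        rep = load_replicate_map(replicate_map)
    return OmicsMatrix(values=values, replicate_map=rep, layer=layer)


def write_omics_matrix(m: OmicsMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id")


def load_drug_response(path) -> DrugResponseTable:
    """Read a drugs-x-cell-lines AAC TSV (first column = drug id)."""
    return DrugResponseTable(_read_numeric_tsv(path))


def write_drug_response(t: DrugResponseTable, path) -> None:
    t.aac.to_csv(path, sep="\t", index_label="drug_id")


# ---------------------------------------------------------------------------
# normalization and filtering


def scale_aac(raw: DrugResponseTable, axis: str = "cell_line") -> DrugResponseTable:
    """Min-max scale AAC to [0, 1].

    Default scales within each cell line across that line's observed drug
    responses, so 0 is that line's least- and 1 its most-effective drug;
    ``axis='drug'`` scales each drug across cell lines instead (sensitivity
    analysis for the ambiguous scaling direction).
    """
    if axis not in ("cell_line", "drug"):
        raise ValueError("axis must be 'cell_line' or 'drug'")
    df = raw.aac if axis == "cell_line" else raw.aac.T
    lo = df.min(axis=0)
    hi = df.max(axis=0)
    span = hi - lo
    degenerate = [c for c in df.columns if df[c].notna().sum() < 2 or span[c] == 0]
    if degenerate:
        kind = "cell line" if axis == "cell_line" else "drug"
        raise PanelError(f"degenerate AAC scaling ({kind}s with <2 distinct values): {degenerate}")
    scaled = (df - lo) / span
    if axis == "drug":
        scaled = scaled.T
    return DrugResponseTable(scaled, scaled=True)


def filter_drugs_by_iqr(table: DrugResponseTable, threshold: float = 0.15):
    """Keep drugs whose across-cell-line IQR (Q3 - Q1) strictly exceeds ``threshold``.

    Ensures a drug shows a sufficient range of sensitivity across the panel
    to support a sensitive-vs-resistant contrast. Returns the filtered table
    and a report dict with ``kept``, ``dropped`` and per-drug IQRs.
    """
    vals = table.aac.to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        q1 = np.nanquantile(vals, 0.25, axis=1)
        q3 = np.nanquantile(vals, 0.75, axis=1)
    iqr = q3 - q1
    keep = iqr > threshold
    kept = [d for d, k in zip(table.drug_ids, keep) if k]
    dropped = [d for d, k in zip(table.drug_ids, keep) if not k]
    report = {
        "kept": kept,
        "dropped": dropped,
        "iqr": dict(zip(table.drug_ids, iqr.tolist())),
        "threshold": threshold,
    }
    return DrugResponseTable(table.aac.loc[kept], scaled=table.scaled), report


def center_scale_features(
    m: OmicsMatrix,
    log2_transform: bool = False,
    pseudocount: float = 1.0,
    stats_from: str = "samples",
) -> OmicsMatrix:
    """Z-score each feature over its non-missing entries (sd with n-1).

    Constant (zero-variance) features are set to 0 and flagged. An optional
    preceding log2(x + pseudocount) transform is available for raw-intensity
    layers; off by default. With ``stats_from='cell_lines'`` the mean and sd
    are estimated on replicate-averaged (cell-line level) values and applied
    to every column, so replicate measurement noise does not inflate the
    feature sd; with the default 'samples' they come from the columns as
    given.
    """
    vals = m.values.to_numpy(dtype=float).copy()
    if log2_transform:
        vals = np.log2(vals + pseudocount)
    if stats_from == "cell_lines":
        stat_vals = average_replicates(replace(m, values=pd.DataFrame(
            vals, index=m.values.index, columns=m.values.columns))).values.to_numpy()
    elif stats_from == "samples":
        stat_vals = vals
    else:
        raise ValueError("stats_from must be 'samples' or 'cell_lines'")
    mean = np.nanmean(stat_vals, axis=1, keepdims=True)
    with np.errstate(all="ignore"):
        sd = np.nanstd(stat_vals, axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | ~np.isfinite(sd)
    centered = vals - mean
    out = np.where(flat, 0.0, centered / np.where(flat, 1.0, sd))
    out = np.where(np.isnan(vals), np.nan, out)
    flagged = [f for f, z in zip(m.feature_ids, flat.ravel()) if z]
    return replace(
        m,
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        normalized=True,
        zero_variance_features=flagged,
    )


def average_replicates(m: OmicsMatrix) -> OmicsMatrix:
    """Collapse replicate columns to one column per cell line (non-missing mean)."""
    groups: dict[str, list[str]] = {}
    for s in m.sample_ids:
        groups.setdefault(m.replicate_map[s], []).append(s)
    for line, samples in groups.items():
        if not samples:
            raise PanelError(f"cell line {line!r} has no samples")
    cols = {line: m.values[samples].mean(axis=1) for line, samples in groups.items()}
    avg = pd.DataFrame(cols, index=m.values.index)
    return replace(m, values=avg, replicate_map={line: line for line in avg.columns})
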