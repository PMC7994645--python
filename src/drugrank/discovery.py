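"""Discovery of empirical markers of drug response (EMDRs).

For each drug, cell lines are split at the median AAC into relatively
sensitive and resistant populations. Each population is resampled into ten
leave-one-fold-out subsets, every sensitive subset is paired with every
resistant subset (100 comparisons), pairs whose AAC values do not separate
(Welch t, p >= 0.05) are discarded, and an empirical-Bayes moderated t-test
contrasts feature abundances within each retained pair. A feature is a
sensitivity marker if its contrast coefficient is >= +0.8 (on the
centered/scaled abundance scale) with p < 0.05 in at least 80% of retained
pairs; resistance markers mirror this at <= -0.8. The per-comparison p is
raw by default: at panel sizes of tens of cell lines, per-comparison BH
adjustment across thousands of features leaves no recoverable markers even
for strong effects (``use_adjusted_p`` restores adjusted-p thresholding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special, stats

from ._utils import benjamini_hochberg, derive_seed
from .io import DrugResponseTable, OmicsMatrix


class DrugSkipped(Exception):
    """A drug cannot be processed (too few observations, no separable repeats...)."""

    def __init__(self, drug, reason):
        self.drug = drug
        self.reason = reason
        super().__init__(f"{drug}: {reason}")


@dataclass
class DiscoveryParams:
    """Thresholds for EMDR discovery.

    fold_threshold and p_threshold define a per-comparison marker call; the
    consistency fraction is the share of retained comparisons in which the
    call must recur. ``use_adjusted_p=True`` thresholds BH-adjusted instead
    of raw p values within each comparison. ``screen_test`` is the AAC
    separation screen between group pairs ('welch' or 'wilcoxon').
    """

    min_group_size: int = 6
    n_groups: int = 10
    screen_alpha: float = 0.05
    screen_test: str = "welch"
    fold_threshold: float = 0.8
    p_threshold: float = 0.05
    consistency: float = 0.8
    use_adjusted_p: bool = False
    min_retained: int = 10


@dataclass
class EMDREntry:
    """Markers and discovery statistics for one drug."""

    drug: str
    sensitivity: list[str]
    resistance: list[str]
    support: dict[str, dict]  # marker -> {"fraction": float, "mean_coef": float}
    n_retained: int
    low_support: bool = False

    def __post_init__(self):
        overlap = set(self.sensitivity) & set(self.resistance)
        if overlap:
            raise ValueError(f"markers on both sides for {self.drug}: {sorted(overlap)}")


@dataclass
class EMDRCatalog:
    entries: dict[str, EMDREntry] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    params: DiscoveryParams = field(default_factory=DiscoveryParams)
    seed: int | None = None

    @property
    def drug_ids(self):
        return list(self.entries)

    def to_json(self, path) -> None:
        payload = {
            "params": asdict(self.params),
            "seed": self.seed,
            "skipped": self.skipped,
            "drugs": {d: asdict(e) for d, e in self.entries.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EMDRCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        entries = {d: EMDREntry(**e) for d, e in payload["drugs"].items()}
        return cls(
            entries=entries,
            skipped=payload.get("skipped", {}),
            params=DiscoveryParams(**payload.get("params", {})),
            seed=payload.get("seed"),
        )


@dataclass
class ModeratedTestResult:
    """Per-feature moderated t statistics plus the shared prior (d0, s0_sq)."""

    table: pd.DataFrame  # coef, s2, df_residual, t, p_raw, p_adj
    d0: float
    s0_sq: float


# ---------------------------------------------------------------------------
# group construction


def split_sensitive_resistant(aac_row: pd.Series, min_group_size: int = 6):
    """Median split of one drug's responses into (sensitive, resistant) cell lines.

    Lines at exactly the median go to the sensitive group. Raises
    :class:`DrugSkipped` when there are too few observations or a degenerate
    split (all responses equal).
    """
    obs = aac_row.dropna()
    drug = aac_row.name if aac_row.name is not None else "<drug>"
    if len(obs) < 2 * min_group_size:
        raise DrugSkipped(drug, f"only {len(obs)} observed responses; need {2 * min_group_size}")
    med = float(np.median(obs.to_numpy()))
    sensitive = set(obs.index[obs >= med])
    resistant = set(obs.index[obs < med])
    if not sensitive or not resistant:
        raise DrugSkipped(drug, "degenerate median split (all responses equal)")
    return sensitive, resistant


def make_resample_groups(members, k: int = 10, seed: int = 0) -> list[list[str]]:
    """k leave-one-fold-out subsamples of ``members``.

    Members are shuffled (seeded) and partitioned into k folds with sizes
    differing by at most one; subset i is everything outside fold i, so each
    subset holds about (k-1)/k of the members.
    """
    members = sorted(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members to resample")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(members))
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        excluded = set(folds[i].tolist())
        out.append([members[j] for j in sorted(set(range(len(members))) - excluded)])
    return out


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0 if a[0] != b[0] else 1.0
    import warnings

    with warnings.catch_warnings():
        # near-constant subsets trigger harmless precision warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def screen_group_pairs(sens_groups, res_groups, aac_row: pd.Series,
                       alpha: float = 0.05, test: str = "welch"):
    """Retain (i, j) group pairs whose AAC values separate at p < alpha.

    Every sensitive subset is compared against every resistant subset
    (two-sided Welch t by default, Wilcoxon rank-sum optional), so only
    resamples that preserve the response contrast feed the marker test.
    """
    retained = []
    for i, sg in enumerate(sens_groups):
        a = aac_row[sg].to_numpy(dtype=float)
        for j, rg in enumerate(res_groups):
            b = aac_row[rg].to_numpy(dtype=float)
            if test == "welch":
                p = _welch_p(a, b)
            elif test == "wilcoxon":
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown screen test {test!r}")
            if p < alpha:
                retained.append((i, j))
    return retained


# ---------------------------------------------------------------------------
# moderated t-test (empirical-Bayes variance shrinkage)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-12:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray):
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log s2 using digamma/trigamma identities
    (Smyth-style closed form). Returns (d0, s0_sq); d0 = inf means all
    residual variances are shrunk fully to s0_sq.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances to fit the prior")
    s2u, dfu = s2[ok], df[ok]
    z = np.log(s2u)
    e = z - special.digamma(dfu / 2.0) + np.log(dfu / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, dfu / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_ttest(values: pd.DataFrame, group_labels: pd.Series,
                    prior: tuple[float, float] | None = None) -> ModeratedTestResult:
    """Two-group empirical-Bayes moderated t-test per feature.

    ``values`` is features x samples on the normalized abundance scale;
    ``group_labels`` maps each sample to 'sensitive' or 'resistant'. The
    contrast coefficient is mean(sensitive) - mean(resistant). Per-feature
    residual variances are shrunk toward a prior fitted across features;
    p values use a t distribution with d0 + df degrees of freedom, then
    BH adjustment. Features with fewer than two non-missing values in either
    group are reported as NaN rows. ``prior`` fixes (d0, s0_sq) instead of
    estimating them (d0 = 0 recovers the ordinary pooled t exactly).
    """
    if values.shape[0] < 2:
        raise ValueError("moderation needs at least 2 features")
    labels = group_labels.reindex(values.columns)
    sens = values.loc[:, (labels == "sensitive").to_numpy()].to_numpy(dtype=float)
    res = values.loc[:, (labels == "resistant").to_numpy()].to_numpy(dtype=float)
    if sens.shape[1] < 2 or res.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    n1 = np.sum(~np.isnan(sens), axis=1).astype(float)
    n2 = np.sum(~np.isnan(res), axis=1).astype(float)
    testable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(all="ignore"):
        m1 = np.nanmean(sens, axis=1)
        m2 = np.nanmean(res, axis=1)
        v1 = np.nanvar(sens, axis=1, ddof=1)
        v2 = np.nanvar(res, axis=1, ddof=1)
    coef = m1 - m2
    df = n1 + n2 - 2.0
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    coef[~testable] = np.nan
    s2[~testable] = np.nan
    df[~testable] = np.nan

    if prior is not None:
        d0, s0_sq = prior
    else:
        d0, s0_sq = fit_variance_prior(s2, np.where(testable, df, 0.0))
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        post_var = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(all="ignore"):
        se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
        t = coef / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t[~testable] = np.nan
    p[~testable] = np.nan
    p_adj = benjamini_hochberg(p)

    table = pd.DataFrame(
        {
            "coef": coef,
            "s2": s2,
            "df_residual": df,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
        },
        index=values.index,
    )
    return ModeratedTestResult(table=table, d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# per-drug marker identification


def identify_emdr(
    omics: OmicsMatrix,
    responses: DrugResponseTable,
    drug: str,
    params: DiscoveryParams | None = None,
    seed: int = 0,
) -> EMDREntry:
    """Resampled moderated-t discovery of one drug's sensitivity/resistance markers.

    Splitting, resampling and screening operate on cell lines; the moderated
    contrasts use every omics column (replicate) of the sampled lines, so a
    replicate-level matrix gains test power while a cell-line-averaged matrix
    works unchanged. Support is the fraction of retained pairs in which a
    feature passed the fold and p thresholds.
    """
    params = params or DiscoveryParams()
    if drug not in responses.aac.index:
        raise KeyError(f"drug {drug!r} not in response table")
    line_cols: dict[str, list[str]] = {}
    for sample in omics.sample_ids:
        line_cols.setdefault(omics.replicate_map[sample], []).append(sample)
    lines = [c for c in responses.aac.columns if c in line_cols]
    aac_row = responses.aac.loc[drug, lines]

    sensitive, resistant = split_sensitive_resistant(aac_row, params.min_group_size)
    sens_groups = make_resample_groups(sensitive, params.n_groups, derive_seed(seed, drug, "sens"))
    res_groups = make_resample_groups(resistant, params.n_groups, derive_seed(seed, drug, "res"))
    retained = screen_group_pairs(
        sens_groups, res_groups, aac_row, params.screen_alpha, params.screen_test
    )
    if not retained:
        raise DrugSkipped(drug, "no separable repeats")

    p_col = "p_adj" if params.use_adjusted_p else "p_raw"
    n_feat = len(omics.feature_ids)
    sens_hits = np.zeros(n_feat)
    res_hits = np.zeros(n_feat)
    coef_sum = np.zeros(n_feat)
    coef_n = np.zeros(n_feat)
    for i, j in retained:
        # contrasts use every measurement (replicate) of the sampled lines
        cols_s = [c for line in sens_groups[i] for c in line_cols[line]]
        cols_r = [c for line in res_groups[j] for c in line_cols[line]]
        labels = pd.Series(
            ["sensitive"] * len(cols_s) + ["resistant"] * len(cols_r),
            index=cols_s + cols_r,
        )
        result = moderated_ttest(omics.values[cols_s + cols_r], labels)
        coef = result.table["coef"].to_numpy()
        sig = result.table[p_col].to_numpy() < params.p_threshold
        ok = np.isfinite(coef)
        sens_hits += (ok & sig & (coef >= params.fold_threshold)).astype(float)
        res_hits += (ok & sig & (coef <= -params.fold_threshold)).astype(float)
        coef_sum += np.where(ok, coef, 0.0)
        coef_n += ok.astype(float)

    n_ret = len(retained)
    sens_frac = sens_hits / n_ret
    res_frac = res_hits / n_ret
    with np.errstate(invalid="ignore"):
        mean_coef = np.where(coef_n > 0, coef_sum / np.maximum(coef_n, 1), np.nan)

    feats = np.asarray(omics.feature_ids)
    sens_markers = feats[sens_frac >= params.consistency].tolist()
    res_markers = feats[res_frac >= params.consistency].tolist()
    support = {}
    for f, frac, mc in zip(
        list(sens_markers) + list(res_markers),
        np.concatenate([sens_frac[sens_frac >= params.consistency],
                        res_frac[res_frac >= params.consistency]]),
        np.concatenate([mean_coef[sens_frac >= params.consistency],
                        mean_coef[res_frac >= params.consistency]]),
    ):
        support[f] = {"fraction": float(frac), "mean_coef": float(mc)}

    return EMDREntry(
        drug=drug,
        sensitivity=sorted(sens_markers),
        resistance=sorted(res_markers),
        support=support,
        n_retained=n_ret,
        low_support=n_ret < params.min_retained,
    )


def build_catalog(
    omics: OmicsMatrix,
    responses: DrugResponseTable,
    params: DiscoveryParams | None = None,
    seed: int = 0,
    drugs=None,
) -> EMDRCatalog:
    """Run :func:`identify_emdr` over drugs, collecting skips instead of failing."""
    params = params or DiscoveryParams()
    catalog = EMDRCatalog(params=params, seed=seed)
    for drug in drugs if drugs is not None else responses.drug_ids:
        try:
            catalog.entries[drug] = identify_emdr(omics, responses, drug, params, seed)
        except DrugSkipped as exc:
            catalog.skipped[drug] = exc.reason
    return catalog
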