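"""Synthetic cell-line panels with known ground truth.

Emulates the statistical structure the pipeline assumes in real panels: a
latent per-(drug, cell line) sensitivity that IS the drug response (AAC),
planted abundance markers that rise linearly with sensitivity (sensitivity
markers) or fall with it (resistance markers), clusters of drugs with
correlated responses that share part of their marker sets, Gaussian
measurement noise, replicate structure, and missing values. Everything is
deterministic given the seed, so marker recovery, D fidelity and prediction
accuracy can be measured against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugResponseTable, OmicsMatrix


@dataclass
class PanelSpec:
    """Generator settings.

    effect_size is the planted marker slope in units of the measurement
    noise sd: a marker's mean abundance spans effect_size * noise_sd across
    the full sensitivity range. cluster_r2 is the fraction of latent
    sensitivity variance shared within a drug cluster (Gaussian copula, so
    the AAC marginal stays Uniform(0,1)); marker_share_fraction of each
    drug's markers are features shared by all drugs in its cluster. Shared
    features follow the cluster's mean latent, so their per-drug contrast is
    attenuated by the within-cluster response correlation; with the default
    share fraction of 0 every planted marker carries the full stated effect
    size for its drug.
    """

    n_cell_lines: int = 24
    n_replicates: int = 3
    n_features: int = 1000
    n_drugs: int = 24
    n_clusters: int = 6
    n_sens_markers: int = 20
    n_res_markers: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    cluster_r2: float = 0.6
    marker_share_fraction: float = 0.0
    seed: int = 17

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name in ("n_cell_lines", "n_replicates", "n_features", "n_drugs", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """True AAC, planted marker ids and cluster membership per drug."""

    aac: pd.DataFrame  # drugs x cell lines, the latent sensitivity
    sensitivity_markers: dict[str, list[str]]
    resistance_markers: dict[str, list[str]]
    clusters: dict[str, int]
    spec: PanelSpec = field(default_factory=PanelSpec)


def _marker_layout(spec: PanelSpec):
    """Assign feature ids to cluster-shared and drug-specific marker slots."""
    n_shared_s = int(round(spec.n_sens_markers * spec.marker_share_fraction))
    n_shared_r = int(round(spec.n_res_markers * spec.marker_share_fraction))
    n_own_s = spec.n_sens_markers - n_shared_s
    n_own_r = spec.n_res_markers - n_shared_r
    demand = spec.n_clusters * (n_shared_s + n_shared_r) + spec.n_drugs * (n_own_s + n_own_r)
    if demand > spec.n_features:
        raise ValueError(f"marker demand ({demand}) exceeds n_features ({spec.n_features})")
    return n_shared_s, n_shared_r, n_own_s, n_own_r


def generate_panel(spec: PanelSpec):
    """Build (OmicsMatrix, DrugResponseTable, GroundTruth) from a PanelSpec.

    Latent sensitivity s(d, c) = Phi(sqrt(r2) z_cluster + sqrt(1-r2) z_drug)
    with standard-normal factors, so s is Uniform(0,1) marginally and drugs
    within a cluster are correlated. AAC = s. A drug-specific sensitivity
    marker has mean abundance effect_size*noise_sd*(s - 0.5); a resistance
    marker the negative; a cluster-shared marker follows the mean latent
    sensitivity of the drugs sharing it. Per-replicate noise is
    N(0, noise_sd^2); entries are masked missing at missing_rate.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [f"CL{i:02d}" for i in range(spec.n_cell_lines)]
    drugs = [f"drug{i:02d}" for i in range(spec.n_drugs)]
    feats = [f"feat{i:04d}" for i in range(spec.n_features)]
    clusters = {d: i % spec.n_clusters for i, d in enumerate(drugs)}

    # latent sensitivities via Gaussian copula: uniform marginal, cluster-correlated
    z_cluster = rng.standard_normal((spec.n_clusters, spec.n_cell_lines))
    z_drug = rng.standard_normal((spec.n_drugs, spec.n_cell_lines))
    r = np.sqrt(spec.cluster_r2)
    z = np.vstack([r * z_cluster[clusters[d]] + np.sqrt(1 - spec.cluster_r2) * z_drug[i]
                   for i, d in enumerate(drugs)])
    s = stats.norm.cdf(z)  # drugs x lines, U(0,1) marginal

    n_shared_s, n_shared_r, n_own_s, n_own_r = _marker_layout(spec)
    next_feat = 0

    def take(n):
        nonlocal next_feat
        ids = list(range(next_feat, next_feat + n))
        next_feat += n
        return ids

    shared_s = {c: take(n_shared_s) for c in range(spec.n_clusters)}
    shared_r = {c: take(n_shared_r) for c in range(spec.n_clusters)}
    own_s = {d: take(n_own_s) for d in drugs}
    own_r = {d: take(n_own_r) for d in drugs}

    amp = spec.effect_size * spec.noise_sd
    signal = np.zeros((spec.n_features, spec.n_cell_lines))
    members = {c: [i for i, d in enumerate(drugs) if clusters[d] == c]
               for c in range(spec.n_clusters)}
    for c in range(spec.n_clusters):
        # a shared marker follows the mean sensitivity of the drugs sharing it
        drive = amp * (s[members[c]].mean(axis=0) - 0.5)
        signal[shared_s[c], :] += drive
        signal[shared_r[c], :] -= drive
    for i, d in enumerate(drugs):
        drive = amp * (s[i] - 0.5)
        signal[own_s[d], :] += drive
        signal[own_r[d], :] -= drive

    sample_ids, rep_map, cols = [], {}, []
    for line in lines:
        for rep in range(spec.n_replicates):
            sid = f"{line}_r{rep + 1}"
            sample_ids.append(sid)
            rep_map[sid] = line
            cols.append(signal[:, lines.index(line)])
    values = np.column_stack(cols) + rng.normal(0.0, spec.noise_sd, (spec.n_features, len(sample_ids)))
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    omics = OmicsMatrix(
        values=pd.DataFrame(values, index=feats, columns=sample_ids),
        replicate_map=rep_map,
        layer="phospho",
    )
    # generated AAC is already on the canonical effect scale (0 = no effect,
    # 1 = maximum kill); scale_aac exists to map raw assay tables onto it
    responses = DrugResponseTable(pd.DataFrame(s, index=drugs, columns=lines), scaled=True)
    truth = GroundTruth(
        aac=pd.DataFrame(s, index=drugs, columns=lines),
        sensitivity_markers={d: [feats[i] for i in shared_s[clusters[d]] + own_s[d]] for d in drugs},
        resistance_markers={d: [feats[i] for i in shared_r[clusters[d]] + own_r[d]] for d in drugs},
        clusters=clusters,
        spec=spec,
    )
    return omics, responses, truth


def reference_settings() -> PanelSpec:
    """The canonical panel used throughout the test suite and worked examples.

    24 cell lines x 3 replicates, 1000 features, 24 drugs in 6 clusters,
    20 sensitivity + 20 resistance markers per drug, effect size 2 noise-sd,
    noise sd 1, 5% missingness, seed 17.
    """
    return PanelSpec(
        n_cell_lines=24,
        n_replicates=3,
        n_features=1000,
        n_drugs=24,
        n_clusters=6,
        n_sens_markers=20,
        n_res_markers=20,
        effect_size=2.0,
        noise_sd=1.0,
        missing_rate=0.05,
        seed=17,
    )


def spec_to_dict(spec: PanelSpec) -> dict:
    return asdict(spec)


def marker_recovery(catalog, truth: GroundTruth, cluster_aware: bool = True) -> pd.DataFrame:
    """Per-drug precision and recall of discovered vs planted markers.

    Recall is always strict: the fraction of the drug's own planted markers
    that were discovered (direction-sensitive). Precision counts a discovered
    marker as correct if planted for the drug itself or — when
    ``cluster_aware`` (default) — for any drug in the same response cluster,
    since cluster-mates' markers co-vary with the drug's response by
    construction; strict precision (cluster_aware=False) charges those
    genuinely response-linked features as errors.
    """
    cluster_of = truth.clusters
    side_sets = {"sens": truth.sensitivity_markers, "res": truth.resistance_markers}
    rows = []
    for drug, entry in catalog.entries.items():
        if drug not in truth.aac.index:
            continue
        allowed_drugs = {drug}
        if cluster_aware:
            allowed_drugs |= {d for d, c in cluster_of.items() if c == cluster_of[drug]}
        ok_sens = set().union(*(side_sets["sens"][d] for d in allowed_drugs))
        ok_res = set().union(*(side_sets["res"][d] for d in allowed_drugs))
        found_s, found_r = set(entry.sensitivity), set(entry.resistance)
        tp = len(found_s & ok_sens) + len(found_r & ok_res)
        n_found = len(found_s) + len(found_r)
        own_s, own_r = set(side_sets["sens"][drug]), set(side_sets["res"][drug])
        tp_own = len(found_s & own_s) + len(found_r & own_r)
        rows.append({
            "drug": drug,
            "n_found": n_found,
            "precision": tp / n_found if n_found else np.nan,
            "recall": tp_own / (len(own_s) + len(own_r)),
        })
    return pd.DataFrame(rows, columns=["drug", "n_found", "precision", "recall"])
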