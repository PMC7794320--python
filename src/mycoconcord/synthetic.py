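"""Synthetic cohorts with the statistical structure of a fecal mycobiome study.

Real gut mycobiome profiles are sparse (each subject carries a small,
individual-specific subset of the community), heavy-tailed (a handful of
genera such as *Saccharomyces* and *Candida* dominate), and highly variable
between individuals.  This module generates cohorts with exactly that
structure, together with paired bacteriome / metabolome / diet blocks, so the
whole downstream pipeline — prevalence filtering, ordination, the
permutation-null SVM, and co-inertia — can be exercised and validated without
access to external data.

The generative model, per sample *i*:

1. draw a richness ``r_i`` (number of zOTUs carried) log-normally, with
   median 60 and an IQR near 46-75;
2. pick ``r_i`` zOTUs without replacement from a fixed popularity
   distribution: a "core" of common zOTUs (sized so that roughly 138 features
   survive a >10% prevalence filter at n=144) plus a long rare tail;
3. give each carried zOTU a log-normal abundance around its feature-specific
   baseline, add the sample's shared latent-factor contribution and, for case
   samples, any planted log-fold effects; soft-max to relative abundances;
4. multiply by a log-normal read depth (median 45,000) and round to counts.

Paired blocks are linear-Gaussian on the log scale: ``log X = baseline +
Z @ loadings.T + noise`` where ``Z`` holds the per-sample latent factors
shared between mycobiome, bacteriome and metabolome.  The diet block is
generated independently of ``Z``, so mycobiome-diet concordance is a true
null by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable

# ---------------------------------------------------------------------------
# Frozen shape constants (chosen once to match the target cohort shape).
# ---------------------------------------------------------------------------

#: log-sd of the per-sample richness distribution: ln(75/46) / (2 * 0.6745)
#: reproduces an IQR ratio of 75/46 around the median.
_RICHNESS_SIGMA = 0.362
#: Median per-sample mapped read depth and its log-sd.
_DEPTH_MEDIAN = 45_000
_DEPTH_SIGMA = 0.35
#: Size of the common "core" zOTU pool and the relative weight of the rare
#: tail; together these set how many features survive the prevalence filter.
_CORE_SIZE = 152
_CORE_WEIGHT_SIGMA = 0.9
_TAIL_WEIGHT_SCALE = 0.012
#: Spread of feature baseline log-abundances and boost for dominant taxa.
#: Dominant (high-abundance) taxa sit mid-core, away from the most prevalent
#: features, decoupling dominance from prevalence so that abundance effects
#: planted on the prevalence head are not confounded with compositional
#: spillover from the community's dominant members.
_BASE_SD = 1.2
_DOMINANT_BOOST = 2.5
_N_DOMINANT = 8
_DOMINANT_OFFSET = 40
#: sd of latent-factor loadings on the log-abundance scale.
_LATENT_SD = 0.8

_N_BACTERIA = 120
_N_METABOLITES = 100
_N_FOODS = 40

GENUS_POOL = (
    "Saccharomyces", "Candida", "Debaryomyces", "Penicillium", "Hanseniaspora",
    "Malassezia", "Cladosporium", "Agaricus", "Aspergillus", "Pichia",
    "Kluyveromyces", "Fusarium",
)
_PHYLA = {
    "Saccharomyces": "Ascomycota", "Candida": "Ascomycota",
    "Debaryomyces": "Ascomycota", "Penicillium": "Ascomycota",
    "Hanseniaspora": "Ascomycota", "Cladosporium": "Ascomycota",
    "Aspergillus": "Ascomycota", "Pichia": "Ascomycota",
    "Kluyveromyces": "Ascomycota", "Fusarium": "Ascomycota",
    "Malassezia": "Basidiomycota", "Agaricus": "Basidiomycota",
}

UP_IN_CASE = "up_in_case"
DOWN_IN_CASE = "down_in_case"


@dataclass(frozen=True)
class PlantedEffect:
    """A differential-abundance effect planted on one zOTU.

    ``log_fold`` is a natural-log fold change applied multiplicatively to the
    relative abundance of the feature in case (IBS) samples, before
    renormalisation.
    """

    feature: str
    direction: str
    log_fold: float

    def __post_init__(self) -> None:
        if self.direction not in (UP_IN_CASE, DOWN_IN_CASE):
            raise ValueError(f"direction must be {UP_IN_CASE!r} or {DOWN_IN_CASE!r}")
        if not np.isfinite(self.log_fold) or self.log_fold < 0:
            raise ValueError("log_fold must be finite and non-negative")

    @property
    def signed_log_fold(self) -> float:
        return self.log_fold if self.direction == UP_IN_CASE else -self.log_fold


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the shape of the target study: 144 samples (80 IBS /
    64 control), 1631 raw zOTUs of which roughly 138 survive a >10%
    prevalence filter, and per-sample richness with median 60.
    """

    n_ibs: int = 80
    n_control: int = 64
    n_zotus_raw: int = 1631
    target_prevalent: int = 138
    richness_median: int = 60
    effect_features: tuple[PlantedEffect, ...] = ()
    shared_latent_dim: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ibs + self.n_control < 4:
            raise ValueError("need at least 4 samples in total")
        if self.target_prevalent > self.n_zotus_raw:
            raise ValueError("target_prevalent cannot exceed n_zotus_raw")
        if len(self.effect_features) > self.n_zotus_raw:
            raise ValueError("more effect features than zOTUs")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.shared_latent_dim < 0:
            raise ValueError("shared_latent_dim must be non-negative")
        object.__setattr__(self, "effect_features", tuple(self.effect_features))


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: mycobiome plus paired omic blocks and ground truth."""

    mycobiome: FeatureTable
    taxonomy: dict[str, str]
    metadata: pd.DataFrame
    bacteriome: FeatureTable
    metabolome: FeatureTable
    diet: FeatureTable
    truth: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)


def feature_id(i: int) -> str:
    return f"zOTU{i + 1}"


def core_feature_ids(n: int = 5) -> list[str]:
    """IDs of the ``n`` most prevalent zOTUs (the head of the core pool).

    Core popularity weights are sorted descending, so ``zOTU1`` is always the
    most commonly carried feature — a convenient, well-powered place to plant
    effects.
    """
    return [feature_id(i) for i in range(n)]


def default_effect_features(
    n: int = 5, log_fold: float = 1.5, direction: str = UP_IN_CASE
) -> tuple[PlantedEffect, ...]:
    """Planted effects on the ``n`` most prevalent zOTUs, alternating direction
    starting from ``direction``."""
    other = DOWN_IN_CASE if direction == UP_IN_CASE else UP_IN_CASE
    return tuple(
        PlantedEffect(f, direction if i % 2 == 0 else other, log_fold)
        for i, f in enumerate(core_feature_ids(n))
    )


def _softmax_rows(log_a: np.ndarray) -> np.ndarray:
    m = log_a.max(axis=-1, keepdims=True)
    e = np.exp(log_a - m)
    return e / e.sum(axis=-1, keepdims=True)


def _make_taxonomy(feature_ids: list[str], rng: np.random.Generator) -> dict[str, str]:
    """UNITE-style lineage strings; dominant head features get the dominant
    genera, ~15% of features are unassigned below family rank."""
    taxonomy: dict[str, str] = {}
    dominant = range(_DOMINANT_OFFSET, _DOMINANT_OFFSET + _N_DOMINANT)
    for i, fid in enumerate(feature_ids):
        if i in dominant:
            genus = GENUS_POOL[i % 4]  # Saccharomyces/Candida/Debaryomyces/Penicillium
        else:
            genus = GENUS_POOL[rng.integers(len(GENUS_POOL))]
        phylum = _PHYLA[genus]
        if rng.random() < 0.15:
            lineage = f"k__Fungi;p__{phylum};c__;o__;f__;g__;s__"
        else:
            lineage = (
                f"k__Fungi;p__{phylum};c__{phylum}_class;o__{genus}ales;"
                f"f__{genus}aceae;g__{genus};s__{genus}_sp{i % 7 + 1}"
            )
        taxonomy[fid] = lineage
    return taxonomy


def _make_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_ibs + config.n_control
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    group = ["IBS"] * config.n_ibs + ["control"] * config.n_control
    subtype = []
    sehcat = []
    # IBS subtype proportions near 30:21:29, SeHCAT assayed in a subset.
    for g in group:
        if g == "IBS":
            subtype.append(rng.choice(["C", "D", "M"], p=[30 / 80, 21 / 80, 29 / 80]))
            if rng.random() < 45 / 80:
                sehcat.append(rng.choice(["normal", "BAM"], p=[21 / 45, 24 / 45]))
            else:
                sehcat.append("")
        else:
            subtype.append("")
            sehcat.append("")
    return pd.DataFrame(
        {"group": group, "ibs_subtype": subtype, "sehcat_category": sehcat},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; a pure function of ``config``.

    Returns
    -------
    SyntheticCohort
        Mycobiome counts, taxonomy, metadata, paired bacteriome (relative),
        metabolome (intensities) and diet (servings/week) blocks, plus a
        ``truth`` dict recording planted effects and latent-factor loadings.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ibs + config.n_control
    p = config.n_zotus_raw
    metadata = _make_metadata(config, rng)
    is_case = (metadata["group"] == "IBS").to_numpy()
    fids = [feature_id(i) for i in range(p)]

    effect_ids = {e.feature for e in config.effect_features}
    unknown = effect_ids.difference(fids)
    if unknown:
        raise ValueError(f"effect features not in the zOTU pool: {sorted(unknown)}")

    # Feature popularity: descending-sorted core weights + light rare tail.
    n_core = min(_CORE_SIZE, p)
    w = np.empty(p)
    w[:n_core] = np.sort(rng.lognormal(0.0, _CORE_WEIGHT_SIGMA, n_core))[::-1]
    w[n_core:] = rng.lognormal(0.0, 1.0, p - n_core) * _TAIL_WEIGHT_SCALE
    w /= w.sum()

    # Feature baseline log-abundances; a few dominant taxa get a boost.
    base = rng.normal(0.0, _BASE_SD, p)
    dom = slice(_DOMINANT_OFFSET, _DOMINANT_OFFSET + _N_DOMINANT)
    base[dom] += _DOMINANT_BOOST

    # Latent factors shared with the paired blocks (core features only).
    d = config.shared_latent_dim
    Z = rng.standard_normal((n, d)) if d else np.zeros((n, 0))
    L_myco = np.zeros((p, d))
    if d:
        L_myco[:n_core] = rng.normal(0.0, _LATENT_SD, (n_core, d))

    delta = np.zeros(p)
    for eff in config.effect_features:
        delta[fids.index(eff.feature)] = eff.signed_log_fold

    richness = np.round(
        rng.lognormal(np.log(config.richness_median), _RICHNESS_SIGMA, n)
    ).astype(int)
    richness = np.clip(richness, 5, p)

    counts = np.zeros((n, p), dtype=np.int64)
    for i in range(n):
        idx = rng.choice(p, size=richness[i], replace=False, p=w, shuffle=False)
        log_a = base[idx] + rng.normal(0.0, config.noise_sd, richness[i])
        if d:
            log_a = log_a + Z[i] @ L_myco[idx].T
        if is_case[i]:
            log_a = log_a + delta[idx]
        rel = _softmax_rows(log_a)
        depth = rng.lognormal(np.log(_DEPTH_MEDIAN), _DEPTH_SIGMA)
        counts[i, idx] = np.round(rel * depth).astype(np.int64)

    mycobiome = FeatureTable(
        pd.DataFrame(counts, index=metadata.index, columns=fids),
        units="counts",
        provenance=(f"synthetic_cohort(seed={config.seed})",),
    )

    # Paired blocks: linear-Gaussian in log space, sharing Z.
    L_bact = rng.normal(0.0, _LATENT_SD, (_N_BACTERIA, d)) if d else np.zeros((_N_BACTERIA, 0))
    log_b = (
        rng.normal(0.0, 1.5, _N_BACTERIA)
        + (Z @ L_bact.T if d else 0.0)
        + rng.normal(0.0, 1.0, (n, _N_BACTERIA))
    )
    bacteriome = FeatureTable(
        pd.DataFrame(
            _softmax_rows(log_b),
            index=metadata.index,
            columns=[f"bacterium{i + 1}" for i in range(_N_BACTERIA)],
        ),
        units="relative",
        provenance=("synthetic_bacteriome",),
    )

    L_met = rng.normal(0.0, _LATENT_SD, (_N_METABOLITES, d)) if d else np.zeros((_N_METABOLITES, 0))
    log_m = (
        rng.normal(5.0, 1.0, _N_METABOLITES)
        + (Z @ L_met.T if d else 0.0)
        + rng.normal(0.0, 1.0, (n, _N_METABOLITES))
    )
    metabolome = FeatureTable(
        pd.DataFrame(
            np.exp(log_m),
            index=metadata.index,
            columns=[f"metabolite{i + 1}" for i in range(_N_METABOLITES)],
        ),
        units="intensity",
        provenance=("synthetic_metabolome",),
    )

    # Diet: servings/week per food item, independent of the latent factors.
    lam = rng.gamma(2.0, 2.0, _N_FOODS)
    diet = FeatureTable(
        pd.DataFrame(
            rng.poisson(lam, (n, _N_FOODS)).astype(float),
            index=metadata.index,
            columns=[f"food{i + 1}" for i in range(_N_FOODS)],
        ),
        units="per_week",
        provenance=("synthetic_diet",),
    )

    taxonomy = _make_taxonomy(fids, rng)

    truth = {
        "effects": [
            {"feature": e.feature, "direction": e.direction, "log_fold": e.log_fold}
            for e in config.effect_features
        ],
        "shared_latent_dim": d,
        "latent_loadings": {
            "mycobiome_sd": _LATENT_SD if d else 0.0,
            "blocks_sharing_latent": ["mycobiome", "bacteriome", "metabolome"] if d else [],
            "independent_blocks": ["diet"],
        },
        "seed": config.seed,
    }
    return SyntheticCohort(
        mycobiome=mycobiome,
        taxonomy=taxonomy,
        metadata=metadata,
        bacteriome=bacteriome,
        metabolome=metabolome,
        diet=diet,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "mycobiome": ("mycobiome.tsv", "counts"),
    "bacteriome": ("bacteriome.tsv", "relative"),
    "metabolome": ("metabolome.tsv", "intensity"),
    "diet": ("diet.tsv", "per_week"),
}


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write all cohort tables as TSV plus the truth as JSON.

    Layout: feature tables with samples as rows (first column ``sample_id``),
    ``taxonomy.tsv`` mapping feature ID to lineage string, ``metadata.tsv``,
    and ``truth.json``.  Returns the mapping of artifact name to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        for name, (fname, _) in _TABLE_FILES.items():
            path = directory / fname
            table: FeatureTable = getattr(cohort, name)
            table.data.rename_axis("sample_id").to_csv(path, sep="\t")
            paths[name] = path
        tax_path = directory / "taxonomy.tsv"
        pd.Series(cohort.taxonomy, name="lineage").rename_axis("feature_id").to_csv(
            tax_path, sep="\t"
        )
        paths["taxonomy"] = tax_path
        meta_path = directory / "metadata.tsv"
        cohort.metadata.to_csv(meta_path, sep="\t")
        paths["metadata"] = meta_path
        truth_path = directory / "truth.json"
        truth_path.write_text(json.dumps(cohort.truth, indent=2))
        paths["truth"] = truth_path
    except OSError as exc:
        raise OSError(f"failed writing cohort to {directory}: {exc}") from exc
    return paths
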