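"""End-to-end orchestration: scan -> features -> labels -> model.

The central artifact is the *site table*: one row per deduplicated candidate
site carrying its coordinates, seed class, the full feature vector, the
IP+/IP- label, and (after prediction) the ensemble probability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import duplex, enrichment, features, model
from .io_formats import RunConfig
from .params import NNParameterTable, default_params

log = logging.getLogger(__name__)

#: covariates used when enrichment selection comes back empty (e.g. null
#: data); a deliberately generic, region-agnostic set
FALLBACK_COVARIATES = (
    "dg_total", "site_access", "au_up_30", "au_down_30",
    "site_location", "cons_site", "seed_type",
)

#: seed-specific columns never offered to a model fitted over all sites
SEED_ONLY = ("seed_access", "cons_seed", "cons_offseed")


def build_site_table(
    transcripts,
    mirnas,
    clip_regions=None,
    tracks=None,
    config: RunConfig | None = None,
    params: NNParameterTable | None = None,
) -> pd.DataFrame:
    """Scan every (miRNA, transcript) pair and assemble the site table."""
    config = config or RunConfig()
    params = params or default_params()
    track_map = {t.transcript_id: t for t in (tracks or [])}
    mirna_map = {m.id: m for m in mirnas}
    rows = []
    for transcript in transcripts:
        sites = []
        for mirna in mirnas:
            sites.extend(
                duplex.scan_candidate_sites(mirna, transcript, params, config)
            )
        sites = duplex.dedup_overlapping(sites)
        track = track_map.get(transcript.id)
        for site in sites:
            feats = features.assemble_features(
                site, transcript, mirna_map[site.mirna_id].seq,
                track, config, params,
            )
            row = {
                "transcript_id": site.transcript_id,
                "mirna_id": site.mirna_id,
                "start": site.start,
                "end": site.end,
                "region": site.region,
                "seed_type": site.seed_type.value,
                "discovery_mode": site.discovery_mode,
            }
            row.update(feats.as_row())
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and clip_regions is not None:
        df["ip_label"] = enrichment.label_sites(
            df, clip_regions, config.containment
        )
    log.info("site table: %d sites on %d transcripts", len(df), len(transcripts))
    return df


def build_dataset_table(dataset, config=None, params=None) -> pd.DataFrame:
    """Site table for a synthetic dataset object."""
    return build_site_table(
        dataset.transcripts, dataset.mirnas, dataset.clip_regions,
        dataset.tracks, config, params,
    )


def select_model_features(
    df: pd.DataFrame,
    config: RunConfig | None = None,
    site_class: str = "all",
    max_missing: float = 0.02,
) -> list[str]:
    """Enrichment-driven covariate selection for the logistic model.

    Features missing in more than ``max_missing`` of the rows are not
    offered (this drops seed-only columns automatically when seedless sites
    are present).  Falls back to a fixed generic list when nothing passes
    the enrichment criterion, so a model can always be fitted.
    """
    config = config or RunConfig()
    if config.features is not None:
        return list(config.features)
    pool = []
    numeric = features.feature_columns(config.flank_windows)
    for c in numeric + ["seed_type", "three_prime_pairing"]:
        if c not in df.columns:
            continue
        if site_class == "all" and c in SEED_ONLY:
            continue
        if c in enrichment.CATEGORICAL_FEATURES or (
            df[c].isna().mean() <= max_missing
        ):
            pool.append(c)
    table = enrichment.enrichment_table(
        df, enrichment.default_bin_specs(pool, config), config
    )
    chosen = enrichment.select_enriched(table, config.or_min, config.min_mass)
    if not chosen:
        chosen = [c for c in FALLBACK_COVARIATES if c in pool]
        log.info("no enriched features; using fallback covariates %s", chosen)
    return chosen


def run_cv(
    df: pd.DataFrame,
    config: RunConfig | None = None,
    covariates=None,
    seed: int | None = None,
) -> tuple[model.DesignSpec, model.EvalReport]:
    """Feature selection plus 10-fold cross-validation on one site table."""
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    covariates = covariates or select_model_features(df, config)
    spec = model.DesignSpec(list(covariates), "all")
    report = model.cross_validate_10fold(df, spec, seed, config)
    return spec, report


def train_full(
    df: pd.DataFrame,
    config: RunConfig | None = None,
    covariates=None,
    seed: int | None = None,
) -> model.LogisticEnsemble:
    """Fit the balanced ensemble on a full site table."""
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    covariates = covariates or select_model_features(df, config)
    spec = model.DesignSpec(list(covariates), "all")
    X, y, _ = model.build_design(df, spec, fit=True)
    return model.fit_balanced_ensemble(
        X[y == 1], X[y == 0], config.ensemble_size, seed, spec, config.ridge
    )


def predict_table(
    ensemble: model.LogisticEnsemble, df: pd.DataFrame
) -> np.ndarray:
    """Ensemble probability per site-table row (NaN where covariates miss)."""
    X, _, kept = model.build_design(df, ensemble.spec)
    probs = np.full(len(df), np.nan)
    probs[kept] = model.predict(ensemble, X)
    return probs


def match_planted(
    df: pd.DataFrame, truth: pd.DataFrame, slack: int = 2
) -> pd.Series:
    """For each truth row, whether a scanned site of the same miRNA covers it.

    A plant counts as recovered when a surviving site of the same miRNA on
    the same transcript covers its seed-complementary core (columns
    ``core_start``/``core_end`` when present, otherwise the full planted
    block) up to ``slack`` nt on each edge.
    """
    found = []
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in df.itertuples():
        by_key.setdefault((r.transcript_id, r.mirna_id), []).append(
            (r.start, r.end)
        )
    has_core = "core_start" in truth.columns
    for r in truth.itertuples():
        lo = r.core_start if has_core else r.start
        hi = r.core_end if has_core else r.end
        hits = by_key.get((r.transcript_id, r.mirna_id), ())
        ok = any(a <= lo + slack and b >= hi - slack for a, b in hits)
        found.append(ok)
    return pd.Series(found, index=truth.index, name="recovered")
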