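"""Per-site sequence and conservation features, and feature-vector assembly.

Feature conventions:

* ``site_location`` — fractional start position of the site within its own
  region (5'UTR, CDS or 3'UTR), normalized so 0 is a site flush with the
  region's 5' end and 1 a site flush with its 3' end.
* ``au_up_<w>`` / ``au_down_<w>`` — A/U fraction of the ``w``-nt block
  immediately 5' / 3' of the site (w in {5,10,15,20,25,30}); blocks
  truncated at transcript edges use the available nucleotides; an empty
  block is missing (NaN).
* ``cons_site`` / ``cons_seed`` / ``cons_offseed`` — mean conservation over
  the site, the seed-complementary block and the site minus that block; any
  unscored nucleotide in a block makes that block's score missing, and a
  missing ``cons_site`` flags the site for exclusion from
  conservation-using models.  Seed-block features exist only for seed-typed
  sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .duplex import CandidateSite, SeedType
from .io_formats import ConservationTrack, RunConfig, TranscriptRecord
from .params import NNParameterTable, default_params
from . import structure

#: fixed column order of the numeric feature block in site tables
def feature_columns(windows=(5, 10, 15, 20, 25, 30)) -> list[str]:
    cols = ["site_location"]
    cols += [f"au_up_{w}" for w in windows]
    cols += [f"au_down_{w}" for w in windows]
    cols += ["site_access", "seed_access"]
    cols += [f"up_access_{w}" for w in windows]
    cols += [f"down_access_{w}" for w in windows]
    cols += ["dg_hybrid", "dg_disruption", "dg_nucl", "dg_total"]
    cols += ["cons_site", "cons_seed", "cons_offseed"]
    return cols


@dataclass
class SiteFeatures:
    """The full covariate vector of one candidate site."""

    seed_type: SeedType
    has_3prime_pairing: bool
    region: str
    values: dict = field(default_factory=dict)
    cons_excluded: bool = False

    def as_row(self) -> dict:
        row = {
            "seed_type": self.seed_type.value,
            "three_prime_pairing": self.has_3prime_pairing,
            "region": self.region,
            "cons_excluded": self.cons_excluded,
        }
        row.update(self.values)
        return row


def au_content(
    transcript: TranscriptRecord, site: tuple[int, int], w: int, side: str
) -> float:
    """A/U fraction of the w-nt flank block 5' ("up") or 3' ("down") of a site."""
    start, end = site
    n = len(transcript.seq)
    if side == "up":
        a, b = max(0, start - w), start
    elif side == "down":
        a, b = end, min(n, end + w)
    else:
        raise ValueError(f"side must be 'up' or 'down', got {side!r}")
    if b <= a:
        return float("nan")
    block = transcript.seq[a:b]
    return (block.count("A") + block.count("U")) / len(block)


def site_location(
    site: tuple[int, int], transcript: TranscriptRecord, region: str | None = None
) -> float:
    """Fractional position of the site start within its region, in [0, 1]."""
    start, end = site
    region = region or transcript.region_of(start, end)
    r0, r1 = transcript.region_bounds(region)
    span = (r1 - r0) - (end - start)
    if span <= 0:
        return 0.5
    return float(np.clip((start - r0) / span, 0.0, 1.0))


def _block_mean(scores: np.ndarray, idx: np.ndarray) -> float:
    if idx.size == 0:
        return float("nan")
    vals = scores[idx]
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.mean())


def conservation_features(
    track: ConservationTrack | None,
    site: tuple[int, int],
    seed_block: tuple[int, int] | None,
) -> tuple[float, float, float]:
    """(cons_site, cons_seed, cons_offseed); NaN where unavailable."""
    nan = float("nan")
    if track is None:
        return nan, nan, nan
    start, end = site
    site_idx = np.arange(start, end)
    cons_site = _block_mean(track.scores, site_idx)
    if seed_block is None:
        return cons_site, nan, nan
    s0, s1 = seed_block
    seed_idx = np.arange(s0, s1)
    off_idx = site_idx[(site_idx < s0) | (site_idx >= s1)]
    return (
        cons_site,
        _block_mean(track.scores, seed_idx),
        _block_mean(track.scores, off_idx),
    )


def seed_block_of(site: CandidateSite) -> tuple[int, int] | None:
    """Target block opposite miRNA nt 2-8 (contiguous pairs only); None if seedless."""
    if site.seed_type is SeedType.SEEDLESS:
        return None
    pm = site.duplex.pair_map()
    targets = [pm[mi] for mi in range(1, 8) if mi in pm]
    if not targets:
        return None
    return min(targets), max(targets) + 1


def assemble_features(
    site: CandidateSite,
    transcript: TranscriptRecord,
    mirna_seq: str,
    track: ConservationTrack | None = None,
    config: RunConfig | None = None,
    params: NNParameterTable | None = None,
    ensemble: structure.EnsembleModel | None = None,
) -> SiteFeatures:
    """Compute the full feature vector of one candidate site.

    Folds the local window (if no ensemble is supplied), then evaluates the
    sequence, thermodynamic, accessibility and conservation features.
    Deterministic given its inputs.
    """
    config = config or RunConfig()
    params = params or default_params()
    interval = (site.start, site.end)
    try:
        if ensemble is None:
            ensemble = structure.fold_window(
                transcript, interval, config.fold_window, params
            )
        seed_block = seed_block_of(site)
        acc = structure.accessibility_profile(
            transcript, interval, ensemble, config.flank_windows, seed_block
        )
        dgd = structure.delta_g_disruption(
            transcript, interval, config.fold_window, params, ensemble=ensemble
        )
        dgn = structure.delta_g_nucl(
            site.duplex, ensemble, mirna_seq, transcript.seq,
            params, config.nucleation_length,
        )
        cons = conservation_features(track, interval, seed_block)
    except Exception as exc:
        raise RuntimeError(
            f"feature computation failed for site "
            f"{site.transcript_id}:[{site.start},{site.end}) x {site.mirna_id}: {exc}"
        ) from exc
    values = {"site_location": site_location(interval, transcript, site.region)}
    for w in config.flank_windows:
        values[f"au_up_{w}"] = au_content(transcript, interval, w, "up")
        values[f"au_down_{w}"] = au_content(transcript, interval, w, "down")
    values["site_access"] = acc.site_access
    values["seed_access"] = acc.seed_access
    for w in config.flank_windows:
        values[f"up_access_{w}"] = acc.upstream_access[w]
        values[f"down_access_{w}"] = acc.downstream_access[w]
    values["dg_hybrid"] = site.duplex.dg_hybrid
    values["dg_disruption"] = dgd
    values["dg_nucl"] = dgn
    values["dg_total"] = structure.delta_g_total(site.duplex.dg_hybrid, dgd)
    values["cons_site"], values["cons_seed"], values["cons_offseed"] = cons
    return SiteFeatures(
        seed_type=site.seed_type,
        has_3prime_pairing=site.has_3prime_pairing,
        region=site.region,
        values=values,
        cons_excluded=(track is not None and math.isnan(cons[0])),
    )
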