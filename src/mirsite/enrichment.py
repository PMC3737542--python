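"""IP+/IP- labeling against CLIP regions and binned odds-ratio enrichment.

A candidate site residing within an AGO-crosslinked region (tag/CCR) is IP+;
all remaining sites are IP-.  For every feature, the degree of enrichment of
a category or bin is the ratio of the odds of that category occurring in the
IP+ set to its odds in the IP- set, with odds P/(1-P) and P the within-set
frequency.  A ratio > 1 marks enrichment among bound sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ClipRegion, RunConfig

log = logging.getLogger(__name__)

CATEGORICAL_FEATURES = ("seed_type", "three_prime_pairing", "region")

#: feature families that exist at several window sizes; enrichment selection
#: picks one window per family
WINDOW_FAMILIES = ("au_up", "au_down", "up_access", "down_access")

#: conservation features: sites flagged cons_excluded are dropped from these
#: rows only
CONSERVATION_FEATURES = ("cons_site", "cons_seed", "cons_offseed")


@dataclass(frozen=True)
class BinSpec:
    """Binning of one feature for enrichment counting."""

    feature: str
    kind: str                  # "categorical" | "continuous"
    width: float = np.nan      # bin width for continuous features

    def __post_init__(self):
        if self.kind == "continuous" and not self.width > 0:
            raise ValueError(f"bin width for {self.feature} must be > 0")


@dataclass
class EnrichmentTable:
    """Per-feature, per-bin counts, frequencies and odds ratios."""

    table: pd.DataFrame        # feature, bin, lo, hi, counts, freqs, odds_ratio
    n_pos: int
    n_neg: int

    def rows(self, feature: str) -> pd.DataFrame:
        return self.table[self.table["feature"] == feature]

    def category_odds(self, feature: str) -> dict:
        """Category -> odds ratio, for OR-encoding of categorical covariates."""
        rows = self.rows(feature)
        return dict(zip(rows["bin"], rows["odds_ratio"]))


def default_bin_specs(columns, config: RunConfig | None = None) -> list[BinSpec]:
    """Binning defaults: 1 kcal/mol for energies, 0.1 for bounded scores."""
    config = config or RunConfig()
    specs = []
    for col in columns:
        if col in CATEGORICAL_FEATURES:
            specs.append(BinSpec(col, "categorical"))
        elif col.startswith("dg_"):
            specs.append(BinSpec(col, "continuous", config.energy_bin))
        else:
            specs.append(BinSpec(col, "continuous", config.prob_bin))
    return specs


def label_sites(sites, clip_regions: list[ClipRegion], containment: float = 1.0):
    """IP+/IP- labels for candidate sites against CLIP regions.

    A site is IP+ iff at least ``containment`` of its length (default: all
    of it) lies within a single region.  Accepts a list of CandidateSite or
    a DataFrame with transcript_id/start/end columns; returns a boolean
    array (True = IP+).
    """
    by_tid: dict[str, list[tuple[int, int]]] = {}
    for r in clip_regions:
        by_tid.setdefault(r.transcript_id, []).append((r.start, r.end))
    if isinstance(sites, pd.DataFrame):
        triples = zip(sites["transcript_id"], sites["start"], sites["end"])
    else:
        triples = ((s.transcript_id, s.start, s.end) for s in sites)
    labels = []
    for tid, start, end in triples:
        needed = containment * (end - start)
        hit = any(
            min(end, b) - max(start, a) >= needed - 1e-9
            for a, b in by_tid.get(tid, ())
        )
        labels.append(hit)
    return np.array(labels, dtype=bool)


def odds_ratio(
    count_pos: int, n_pos: int, count_neg: int, n_neg: int
) -> tuple[float, bool]:
    """Enrichment odds ratio of one bin, [p+/(1-p+)] / [p-/(1-p-)].

    Any zero cell in the 2x2 table triggers a +0.5 continuity correction on
    all four counts (Haldane-Anscombe); the second return value flags it.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("set sizes must be positive")
    if count_pos > n_pos or count_neg > n_neg:
        raise ValueError("bin count exceeds set size")
    a, b = count_pos, n_pos - count_pos
    c, d = count_neg, n_neg - count_neg
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d), corrected


def _bin_continuous(values: np.ndarray, width: float):
    idx = np.floor(values / width + 1e-12).astype(int)
    return idx


def enrichment_table(
    df: pd.DataFrame, bin_specs: list[BinSpec] | None = None,
    config: RunConfig | None = None,
) -> EnrichmentTable:
    """Binned odds ratios for every configured feature over IP+ vs IP- sites.

    ``df`` must carry an ``ip_label`` boolean column.  Sites with a missing
    feature value are excluded from that feature's rows only; sites flagged
    ``cons_excluded`` are additionally excluded from conservation rows.
    """
    if "ip_label" not in df.columns:
        raise ValueError("df must have an ip_label column")
    pos_mask = df["ip_label"].astype(bool).to_numpy()
    n_pos_all, n_neg_all = int(pos_mask.sum()), int((~pos_mask).sum())
    if n_pos_all == 0 or n_neg_all == 0:
        raise ValueError("both IP+ and IP- sites are required")
    if bin_specs is None:
        cols = [
            c for c in df.columns
            if c not in ("transcript_id", "mirna_id", "start", "end",
                         "discovery_mode", "ip_label", "cons_excluded",
                         "probability")
            and (c in CATEGORICAL_FEATURES or df[c].dtype.kind == "f")
        ]
        bin_specs = default_bin_specs(cols, config)
    records = []
    for spec in bin_specs:
        vals = df[spec.feature]
        keep = ~vals.isna().to_numpy()
        if spec.feature in CONSERVATION_FEATURES and "cons_excluded" in df:
            keep &= ~df["cons_excluded"].astype(bool).to_numpy()
        vp = vals.to_numpy()[keep & pos_mask]
        vn = vals.to_numpy()[keep & ~pos_mask]
        n_pos, n_neg = len(vp), len(vn)
        if n_pos == 0 or n_neg == 0:
            log.warning("feature %s has an empty label class; skipped", spec.feature)
            continue
        if spec.kind == "categorical":
            cats = sorted(set(vp) | set(vn), key=str)
            keys = [(str(c), np.nan, np.nan) for c in cats]
            cp = [int((vp == c).sum()) for c in cats]
            cn = [int((vn == c).sum()) for c in cats]
        else:
            bp = _bin_continuous(vp.astype(float), spec.width)
            bn = _bin_continuous(vn.astype(float), spec.width)
            bins = sorted(set(bp) | set(bn))
            keys = [
                (f"[{b * spec.width:g},{(b + 1) * spec.width:g})",
                 b * spec.width, (b + 1) * spec.width)
                for b in bins
            ]
            cp = [int((bp == b).sum()) for b in bins]
            cn = [int((bn == b).sum()) for b in bins]
        for (label, lo, hi), count_p, count_n in zip(keys, cp, cn):
            orv, corr = odds_ratio(count_p, n_pos, count_n, n_neg)
            records.append({
                "feature": spec.feature, "bin": label, "bin_lo": lo,
                "bin_hi": hi, "count_ip_pos": count_p, "count_ip_neg": count_n,
                "freq_ip_pos": count_p / n_pos, "freq_ip_neg": count_n / n_neg,
                "odds_ratio": orv, "corrected": corr,
            })
    return EnrichmentTable(pd.DataFrame(records), n_pos_all, n_neg_all)


def select_enriched(
    table: EnrichmentTable,
    or_min: float = 1.2,
    min_mass: float = 0.1,
) -> list[str]:
    """Features whose enriched bins carry enough IP+ mass.

    A feature is enriched when its bins/categories with odds ratio >=
    ``or_min`` jointly cover at least ``min_mass`` of the IP+ sites.  For
    windowed feature families (flank AU, flank accessibility) the window
    with the largest maximum-bin odds ratio among the enriched members is
    selected.
    """
    enriched: dict[str, float] = {}
    for feature, rows in table.table.groupby("feature", sort=False):
        hot = rows[rows["odds_ratio"] >= or_min]
        if hot["freq_ip_pos"].sum() >= min_mass:
            enriched[feature] = float(hot["odds_ratio"].max())
    chosen = []
    used = set()
    for fam in WINDOW_FAMILIES:
        members = {
            f: v for f, v in enriched.items()
            if f.startswith(fam + "_") and f[len(fam) + 1:].isdigit()
        }
        if members:
            best = max(members, key=lambda f: (members[f], f))
            chosen.append(best)
            used.update(members)
    for f in enriched:
        if f not in used:
            chosen.append(f)
    log.info("enriched features (or_min=%g, min_mass=%g): %s",
             or_min, min_mass, chosen)
    return chosen


def encode_categorical(
    table: EnrichmentTable, values, feature: str
) -> np.ndarray:
    """Replace categorical values by their training-set odds ratios.

    A category unseen during training encodes as 1.0 (neutral) with a
    warning.
    """
    mapping = table.category_odds(feature)
    out = np.empty(len(values), dtype=float)
    for k, v in enumerate(np.asarray(values, dtype=object)):
        key = str(v)
        if key in mapping:
            out[k] = mapping[key]
        else:
            log.warning("category %r of %s unseen in training; encoded as 1.0",
                        v, feature)
            out[k] = 1.0
    return out
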