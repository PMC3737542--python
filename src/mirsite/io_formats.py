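"""Input/output for every format the pipeline touches, plus run configuration.

All coordinates are 0-based half-open *transcript* coordinates throughout the
package.  DNA input is tolerated and silently converted to RNA (T->U); mixed
case is folded to upper case.  Missing values (conservation, truncated flank
blocks) are NaN in memory and ``"NA"`` on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGU")


def clean_seq(raw: str, record_id: str) -> str:
    seq = str(raw).upper().replace("T", "U")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_id!r}: invalid characters {sorted(bad)} in sequence"
        )
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    return seq


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA with its region boundaries.

    5'UTR = [0, utr5_end), CDS = [utr5_end, cds_end), 3'UTR = [cds_end, len).
    """

    id: str
    seq: str
    utr5_end: int = 0
    cds_end: int = 0

    def __post_init__(self):
        object.__setattr__(self, "seq", clean_seq(self.seq, self.id))
        if not (0 <= self.utr5_end <= self.cds_end <= len(self.seq)):
            raise ValueError(
                f"transcript {self.id!r}: region boundaries "
                f"({self.utr5_end}, {self.cds_end}) outside sequence of "
                f"length {len(self.seq)}"
            )

    def __len__(self):
        return len(self.seq)

    def region_bounds(self, region: str) -> tuple[int, int]:
        if region == "5UTR":
            return 0, self.utr5_end
        if region == "CDS":
            return self.utr5_end, self.cds_end
        if region == "3UTR":
            return self.cds_end, len(self.seq)
        raise ValueError(f"unknown region {region!r}")

    def region_of(self, start: int, end: int) -> str:
        """Region containing the midpoint of [start, end)."""
        mid = (start + end - 1) // 2
        if mid < self.utr5_end:
            return "5UTR"
        if mid < self.cds_end:
            return "CDS"
        return "3UTR"


@dataclass(frozen=True)
class MiRnaRecord:
    """A mature miRNA sequence, 5'->3', typically ~22 nt."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", clean_seq(self.seq, self.id))
        if len(self.seq) < 9:
            raise ValueError(
                f"miRNA {self.id!r}: length {len(self.seq)} < 9 (needs seed "
                "positions 1-8 plus at least one 3' nucleotide)"
            )

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class ClipRegion:
    """An AGO-crosslinked interval (tag or CCR) in transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    source_label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"CLIP region {self.transcript_id}:[{self.start},{self.end}) "
                "must satisfy 0 <= start < end"
            )


@dataclass(frozen=True)
class ConservationTrack:
    """Per-nucleotide conservation scores in [0,1]; NaN marks missing."""

    transcript_id: str
    scores: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.scores, dtype=float)
        present = ~np.isnan(arr)
        if present.any() and ((arr[present] < 0) | (arr[present] > 1)).any():
            raise ValueError(
                f"conservation track {self.transcript_id!r}: scores outside [0,1]"
            )
        object.__setattr__(self, "scores", arr)


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run."""

    dg_threshold: float = -15.0       # kcal/mol, threshold-mode scan
    seed_spans: tuple = ("2-7", "2-8", "3-8")
    flank_windows: tuple = (5, 10, 15, 20, 25, 30)
    max_site_span: int = 40           # nt, target window for one duplex
    fold_window: int = 200            # nt, local folding window
    nucleation_length: int = 4        # nt, helix block for dG_nucl
    energy_bin: float = 1.0           # kcal/mol, enrichment bin width
    prob_bin: float = 0.1             # bin width for probabilities/scores
    or_min: float = 1.2               # enrichment call: minimum odds ratio
    min_mass: float = 0.1             # enrichment call: IP+ mass in OR>=or_min bins
    containment: float = 1.0          # fraction of site inside a CLIP region
    q_threshold: float = 0.5          # logistic classification threshold
    ensemble_size: int = 10
    n_folds: int = 10
    ridge: float = 1e-6
    seed: int = 0
    features: tuple | None = None     # explicit covariate list; None = select

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"config field {f.name} must be finite")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed_spans", "flank_windows", "features"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for key in ("seed_spans", "flank_windows", "features"):
            if data[key] is not None:
                data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def override(self, **kwargs) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# readers


def read_fasta(path, kind: str = "transcript"):
    """Read a FASTA file into transcript or miRNA records.

    T is converted to U; ids must be unique.  ``kind`` selects the record
    type ("transcript" or "mirna"); transcript region boundaries default to
    an all-3'UTR layout until :func:`apply_regions` joins a region table.
    """
    seen = set()
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if kind == "mirna":
            out.append(MiRnaRecord(rec.id, str(rec.seq)))
        else:
            out.append(TranscriptRecord(rec.id, str(rec.seq)))
    log.info("read %d %s records from %s", len(out), kind, path)
    return out


def read_region_table(path) -> dict[str, tuple[int, int]]:
    """Read the transcript region table (TSV: transcript_id, utr5_end, cds_end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "utr5_end", "cds_end"}
    if not required <= set(df.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    return {
        str(r.transcript_id): (int(r.utr5_end), int(r.cds_end))
        for r in df.itertuples()
    }


def apply_regions(transcripts, table) -> list[TranscriptRecord]:
    """Attach region boundaries to transcripts, validating against lengths."""
    out = []
    for t in transcripts:
        if t.id in table:
            u5, cd = table[t.id]
            out.append(TranscriptRecord(t.id, t.seq, u5, cd))
        else:
            out.append(t)
    return out


def read_clip_regions(path) -> list[ClipRegion]:
    """Read BED-like CLIP intervals (transcript_id, start, end[, label])."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("CLIP region file %s is empty", path)
        return []
    regions = []
    for row in df.itertuples(index=False):
        label = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else ""
        regions.append(ClipRegion(str(row[0]), int(row[1]), int(row[2]), label))
    regions.sort(key=lambda r: (r.transcript_id, r.start, r.end))
    return regions


def read_conservation(path, lengths: dict[str, int] | None = None):
    """Read per-transcript conservation (TSV: transcript_id, position, score).

    Positions absent from the file become NaN.  ``lengths`` (transcript id ->
    sequence length) sizes each track; without it the track extends to the
    largest scored position.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "position", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"conservation table must have columns {sorted(required)}")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        bad = df[(df["score"] < 0) | (df["score"] > 1)].iloc[0]
        raise ValueError(
            f"conservation score {bad['score']} outside [0,1] for "
            f"{bad['transcript_id']}:{int(bad['position'])}"
        )
    tracks = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        tid = str(tid)
        n = (lengths or {}).get(tid, int(grp["position"].max()) + 1)
        scores = np.full(n, np.nan)
        pos = grp["position"].to_numpy(dtype=int)
        if (pos >= n).any():
            raise ValueError(f"conservation position beyond transcript {tid!r}")
        scores[pos] = grp["score"].to_numpy(dtype=float)
        tracks.append(ConservationTrack(tid, scores))
    return tracks


# ---------------------------------------------------------------------------
# site tables

#: fixed, versioned column order of the site table
SITE_KEY_COLUMNS = [
    "transcript_id", "mirna_id", "start", "end", "region", "seed_type",
    "discovery_mode",
]


def write_site_table(df: pd.DataFrame, path, probabilities=None) -> None:
    """Write the per-site feature table as TSV (NaN encoded as "NA").

    Floats are written with 12 significant digits so that a read-back is
    identical to 1e-9.
    """
    df = df.copy()
    if probabilities is not None:
        if len(probabilities) != len(df):
            raise ValueError(
                f"{len(probabilities)} probabilities for {len(df)} sites"
            )
        df["probability"] = np.asarray(probabilities, dtype=float)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
    log.info("wrote %d sites to %s", len(df), path)


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
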