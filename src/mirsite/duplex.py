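"""Candidate miRNA binding sites by intermolecular duplex energy minimization.

Two discovery modes mirror the two ways the hybrid search is run:

* ``threshold`` — the minimum-free-energy duplex anywhere on the transcript,
  kept when ``dG_hybrid`` is at or below a stability threshold (default
  -15 kcal/mol).  This captures seedless sites, including rare centered
  sites, that a seed-match search would miss.
* ``seed-forced`` — base-pairing forced for the seed region (miRNA nt 2-7,
  2-8 or 3-8) with no energy threshold, capturing every offset-6mer, 6mer,
  7mer-A1, 7mer-m8 and 8mer seed site even when pairing beyond the seed is
  weak.

Overlapping redundant sites are resolved by the canonical seed hierarchy
(8mer > 7mer-m8 > 7mer-A1 > 6mer > offset-6mer > seedless), ties broken by
the more stable hybrid (lower dG_hybrid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _kernels
from .io_formats import MiRnaRecord, RunConfig, TranscriptRecord
from .params import NNParameterTable, WC_PARTNER, default_params, encode

log = logging.getLogger(__name__)


class SeedType(str, Enum):
    """Canonical seed-match classes, ordered from most to least preferred."""

    EIGHT_MER = "8mer"
    SEVEN_MER_M8 = "7mer-m8"
    SEVEN_MER_A1 = "7mer-A1"
    SIX_MER = "6mer"
    OFFSET_SIX_MER = "offset-6mer"
    SEEDLESS = "seedless"

    @property
    def rank(self) -> int:
        """0 is the most preferred class."""
        return _SEED_RANK[self]


_SEED_RANK = {st: i for i, st in enumerate(SeedType)}

#: forced seed spans as 0-based half-open miRNA index ranges
SEED_SPANS = {"2-7": (1, 7), "2-8": (1, 8), "3-8": (2, 8)}


@dataclass(frozen=True)
class HybridDuplex:
    """An intermolecular miRNA:target duplex.

    ``pairs`` maps miRNA positions (0-based, 5'->3') to transcript positions,
    monotone decreasing in the target (the strands are antiparallel).
    """

    mirna_id: str
    transcript_id: str
    target_start: int
    target_end: int
    pairs: tuple  # ((mi, tj), ...) sorted by mi ascending
    dg_hybrid: float

    def pair_map(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass(frozen=True)
class CandidateSite:
    duplex: HybridDuplex
    seed_type: SeedType
    region: str
    has_3prime_pairing: bool
    discovery_mode: str  # "threshold" | "seed-forced"

    @property
    def start(self) -> int:
        return self.duplex.target_start

    @property
    def end(self) -> int:
        return self.duplex.target_end

    @property
    def mirna_id(self) -> str:
        return self.duplex.mirna_id

    @property
    def transcript_id(self) -> str:
        return self.duplex.transcript_id


def _traceback(pred, t_len, i, j):
    pairs = []
    while i >= 0:
        pairs.append((i, j))
        packed = pred[i, j]
        if packed < 0:
            break
        i, j = divmod(packed, t_len)
    pairs.reverse()
    return tuple(pairs)


def _fill(mir_codes, tgt_codes, params, forced_j=None, span=(0, 0)):
    if forced_j is None:
        forced_j = np.full(len(mir_codes), -1, dtype=np.int64)
    return _kernels.duplex_fill(
        mir_codes.astype(np.int64), tgt_codes.astype(np.int64),
        params.stack, params.pairable, params.duplex_init,
        params.bulge_per_nt, params.internal_per_nt, params.max_loop,
        forced_j, span[0], span[1],
    )


def _best_cell(B, min_i=0):
    sub = B[min_i:]
    idx = np.argmin(sub)
    i, j = divmod(idx, B.shape[1])
    return int(i) + min_i, int(j), float(sub.flat[idx])


def duplex_energy(
    mirna_seq: str,
    target_seq: str,
    forced_seed_span: tuple[int, int] | None = None,
    params: NNParameterTable | None = None,
    mirna_id: str = "",
    transcript_id: str = "",
    target_offset: int = 0,
) -> HybridDuplex | None:
    """Minimum-free-energy monotone duplex of a miRNA against a target window.

    Energy is the sum of nearest-neighbor stacks, linear bulge/internal-loop
    penalties and the duplex initiation term.  With ``forced_seed_span`` (a
    0-based half-open miRNA index range) every position in the span must be
    Watson-Crick paired to consecutive target positions; if no placement is
    feasible the result is ``None`` (NO_DUPLEX), as it is when no duplex of
    negative free energy exists.
    """
    params = params or default_params()
    mir = encode(mirna_seq)
    tgt = encode(target_seq)
    m, t = len(mir), len(tgt)
    if forced_seed_span is None:
        B, pred = _fill(mir, tgt, params)
        i, j, dg = _best_cell(B)
        if dg >= 0:
            return None
        pairs = _traceback(pred, t, i, j)
    else:
        lo, hi = forced_seed_span
        if not (0 <= lo < hi <= m):
            raise ValueError(f"forced span {forced_seed_span} outside miRNA")
        block = [WC_PARTNER[int(b)] for b in mir[lo:hi]]
        needle = np.array(block[::-1], dtype=np.int64)  # target 5'->3'
        L = hi - lo
        best = None
        for q in range(t - L + 1):
            if not np.array_equal(tgt[q:q + L], needle):
                continue
            forced_j = np.full(m, -1, dtype=np.int64)
            for k in range(L):
                forced_j[lo + k] = q + L - 1 - k
            B, pred = _fill(mir, tgt, params, forced_j, (lo, hi))
            i, j, dg = _best_cell(B, min_i=hi - 1)
            if dg >= _kernels.INF:
                continue
            if best is None or dg < best[0]:
                best = (dg, _traceback(pred, t, i, j))
        if best is None:
            return None
        dg, pairs = best
    tj = [p[1] for p in pairs]
    return HybridDuplex(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        target_start=min(tj) + target_offset,
        target_end=max(tj) + 1 + target_offset,
        pairs=tuple((mi, j + target_offset) for mi, j in pairs),
        dg_hybrid=dg,
    )


# ---------------------------------------------------------------------------
# seed taxonomy


def _contiguous_wc(pair_map, mirna_seq, target_seq, lo, hi, target_offset=0):
    """True iff miRNA positions [lo, hi) are WC-paired to consecutive targets."""
    if lo not in pair_map:
        return False
    base_j = pair_map[lo]
    for mi in range(lo, hi):
        j = pair_map.get(mi)
        if j is None or j != base_j - (mi - lo):
            return False
        a = mirna_seq[mi]
        b = target_seq[j - target_offset]
        if WC_PARTNER[_B[a]] != _B[b]:
            return False
    return True


_B = {"A": 0, "C": 1, "G": 2, "U": 3}


def _is_wc_paired(pair_map, mirna_seq, target_seq, mi, target_offset=0):
    j = pair_map.get(mi)
    if j is None:
        return False
    return WC_PARTNER[_B[mirna_seq[mi]]] == _B[target_seq[j - target_offset]]


def classify_seed(
    duplex: HybridDuplex,
    mirna_seq: str,
    target_seq: str,
    target_offset: int = 0,
) -> SeedType:
    """Assign the canonical seed class of a duplex.

    8mer: contiguous WC pairing of miRNA nt 2-8 with an A opposite nt 1;
    7mer-m8: WC 2-8 without the A; 7mer-A1: WC 2-7, A opposite nt 1, nt 8
    unpaired or non-WC; 6mer: WC 2-7 only; offset-6mer: WC 3-8 only.  A G:U
    pair anywhere in the claimed span disqualifies that span.  The A-opposite-
    nt-1 test reads the target nucleotide itself, regardless of whether nt 1
    is paired.
    """
    pm = duplex.pair_map()
    wc28 = _contiguous_wc(pm, mirna_seq, target_seq, 1, 8, target_offset)
    wc27 = _contiguous_wc(pm, mirna_seq, target_seq, 1, 7, target_offset)
    wc38 = _contiguous_wc(pm, mirna_seq, target_seq, 2, 8, target_offset)
    # the target nucleotide opposite miRNA nt 1 sits one base 3' (in target
    # coordinates) of the partner of nt 2
    a1 = False
    if 1 in pm:
        j1 = pm[1] + 1 - target_offset
        if 0 <= j1 < len(target_seq):
            a1 = target_seq[j1] == "A"
    if wc28:
        return SeedType.EIGHT_MER if a1 else SeedType.SEVEN_MER_M8
    if wc27:
        if a1 and not _is_wc_paired(pm, mirna_seq, target_seq, 7, target_offset):
            return SeedType.SEVEN_MER_A1
        return SeedType.SIX_MER
    if wc38:
        return SeedType.OFFSET_SIX_MER
    return SeedType.SEEDLESS


def three_prime_pairing(
    duplex: HybridDuplex, mirna_seq: str, target_seq: str, target_offset: int = 0
) -> bool:
    """True iff miRNA nt 12-17 are contiguously WC-paired to the target."""
    if len(mirna_seq) < 17:
        log.warning(
            "miRNA %s shorter than 17 nt: no 3' supplementary pairing",
            duplex.mirna_id,
        )
        return False
    return _contiguous_wc(
        duplex.pair_map(), mirna_seq, target_seq, 11, 17, target_offset
    )


# ---------------------------------------------------------------------------
# scanning


def _annotate(duplex, mirna, transcript, mode) -> CandidateSite:
    return CandidateSite(
        duplex=duplex,
        seed_type=classify_seed(duplex, mirna.seq, transcript.seq),
        region=transcript.region_of(duplex.target_start, duplex.target_end),
        has_3prime_pairing=three_prime_pairing(duplex, mirna.seq, transcript.seq),
        discovery_mode=mode,
    )


def scan_candidate_sites(
    mirna: MiRnaRecord,
    transcript: TranscriptRecord,
    params: NNParameterTable | None = None,
    config: RunConfig | None = None,
) -> list[CandidateSite]:
    """All candidate sites of one miRNA on one transcript (both modes).

    Threshold mode runs one duplex DP across the whole transcript and emits
    every non-overlapping local optimum with dG_hybrid at or below the
    threshold.  Seed-forced mode anchors a constrained duplex at every exact
    seed-complement match for each configured span.  The union may contain
    overlapping redundant sites; resolve with :func:`dedup_overlapping`.
    """
    params = params or default_params()
    config = config or RunConfig()
    mir = encode(mirna.seq)
    tgt = encode(transcript.seq)
    m, t = len(mir), len(tgt)
    sites: list[CandidateSite] = []

    # --- mode 1: energy threshold, no seed constraint
    B, pred = _fill(mir, tgt, params)
    start_best = B.min(axis=0)            # per target start position
    start_arg = B.argmin(axis=0)
    order = np.argsort(start_best, kind="stable")
    occupied = np.zeros(t, dtype=bool)
    for j in order:
        dg = start_best[j]
        if dg > config.dg_threshold:
            break
        i = int(start_arg[j])
        pairs = _traceback(pred, t, i, int(j))
        lo = min(p[1] for p in pairs)
        hi = max(p[1] for p in pairs) + 1
        if occupied[lo:hi].any():
            continue
        occupied[lo:hi] = True
        duplex = HybridDuplex(
            mirna.id, transcript.id, lo, hi, tuple(pairs), float(dg)
        )
        sites.append(_annotate(duplex, mirna, transcript, "threshold"))

    # --- mode 2: forced seed pairing, no energy threshold
    seen_anchors = set()
    for span_name in config.seed_spans:
        lo, hi = SEED_SPANS[span_name]
        L = hi - lo
        needle = "".join(
            "ACGU"[WC_PARTNER[int(b)]] for b in mir[lo:hi]
        )[::-1]
        q = transcript.seq.find(needle)
        while q >= 0:
            key = (q, q + L, lo, hi)
            if key not in seen_anchors:
                seen_anchors.add(key)
                wl = max(0, q - (m - hi) - params.max_loop // 2)
                wr = min(t, q + L + lo + params.max_loop // 2 + 1)
                duplex = duplex_energy(
                    mirna.seq, transcript.seq[wl:wr],
                    forced_seed_span=(lo, hi), params=params,
                    mirna_id=mirna.id, transcript_id=transcript.id,
                    target_offset=wl,
                )
                if duplex is not None:
                    sites.append(_annotate(duplex, mirna, transcript, "seed-forced"))
            q = transcript.seq.find(needle, q + 1)
    return sites


def dedup_overlapping(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Resolve redundant overlapping sites by the seed hierarchy.

    Within each (miRNA, transcript) pair, sites sharing at least one
    nucleotide form a cluster (transitively); exactly one site per cluster
    survives: the highest-ranked seed class, ties broken by lower dG_hybrid.
    Idempotent and independent of input order.
    """
    by_pair: dict[tuple[str, str], list[CandidateSite]] = {}
    for s in sites:
        by_pair.setdefault((s.mirna_id, s.transcript_id), []).append(s)
    out: list[CandidateSite] = []
    for key in sorted(by_pair):
        group = sorted(
            by_pair[key],
            key=lambda s: (s.start, s.end, s.seed_type.rank, s.duplex.dg_hybrid),
        )
        cluster: list[CandidateSite] = []
        cluster_end = -1
        for s in group:
            if cluster and s.start >= cluster_end:
                out.append(_cluster_best(cluster))
                cluster = []
            cluster.append(s)
            cluster_end = max(cluster_end, s.end)
        if cluster:
            out.append(_cluster_best(cluster))
    out.sort(key=lambda s: (s.transcript_id, s.mirna_id, s.start, s.end))
    return out


def _cluster_best(cluster: list[CandidateSite]) -> CandidateSite:
    return min(
        cluster,
        key=lambda s: (s.seed_type.rank, s.duplex.dg_hybrid, s.start, s.end),
    )
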