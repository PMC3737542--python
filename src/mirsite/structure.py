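"""Target secondary-structure ensemble: accessibility and opening energetics.

The target is folded locally (default 200-nt window centered on the site)
under a simplified stacking ensemble model: admissible structures are
non-crossing sets of WC/GU pairs with a minimum hairpin loop of 3 nt; each
pair carries a constant loop/entropy surcharge and adjacent pairs gain the
nearest-neighbor stacking energy from the shared parameter table.  The
partition function, base-pair probabilities and single-strandedness profile
are computed exactly for this model by inside/outside recursions — the exact
expectation of what a Boltzmann structure-sampling approach estimates, with
zero sampling noise.

Two-step hybridization energetics:

* ``dG_disruption >= 0`` — ensemble free-energy cost of forcing the site
  single-stranded (constrained minus unconstrained ensemble free energy);
* ``dG_total = dG_hybrid + dG_disruption`` — the net energy change of
  hybridization, the headline accessibility-aware energy feature;
* ``dG_nucl`` — nucleation potential: the best short (default 4-pair)
  contiguously stacked block of the duplex, charged with the cost of opening
  its target nucleotides (-RT ln of their mean single-strandedness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .duplex import HybridDuplex
from .params import NNParameterTable, default_params, encode

#: ensemble free energy scaling constant; exp(+1.7/RT) per nucleotide keeps
#: the scaled partition function in double range for windows up to ~300 nt
_SIGMA_E = 1.7


@dataclass(frozen=True)
class EnsembleModel:
    """Boltzmann ensemble of one folded window.

    ``p[i, j]`` (window coordinates, i < j) is the probability that i pairs
    j; ``s[i] = 1 - sum_j p(i, j)`` the single-strandedness; ``e_ens`` the
    ensemble free energy -RT ln Z <= 0.
    """

    seq: str
    offset: int            # window start in transcript coordinates
    p: np.ndarray
    s: np.ndarray
    e_ens: float

    def __len__(self):
        return len(self.seq)

    @property
    def window(self) -> tuple[int, int]:
        return self.offset, self.offset + len(self.seq)

    def s_at(self, start: int, end: int) -> np.ndarray:
        """Single-strandedness over a transcript-coordinate interval."""
        a, b = start - self.offset, end - self.offset
        if a < 0 or b > len(self.seq):
            raise ValueError(
                f"block [{start},{end}) outside fold window {self.window}"
            )
        return self.s[a:b]


@dataclass(frozen=True)
class AccessibilityProfile:
    site_access: float
    seed_access: float                 # NaN for seedless sites
    upstream_access: dict
    downstream_access: dict


@dataclass(frozen=True)
class EnergyFeatures:
    dg_hybrid: float
    dg_disruption: float
    dg_nucl: float                     # NaN = NO_NUCLEATION
    dg_total: float


def _scaled_inside(codes, params, banned=None):
    n = len(codes)
    if banned is None:
        banned = np.zeros(n, dtype=np.bool_)
    inv_sigma = math.exp(-_SIGMA_E / params.rt)
    wpair = math.exp(-params.pair_penalty / params.rt)
    q, qb = _kernels.pf_inside(
        codes.astype(np.int64), params.stack_weights(), wpair,
        params.pairable, params.min_hairpin, inv_sigma, banned,
    )
    return q, qb, inv_sigma, wpair


def ensemble_free_energy(q, n, params) -> float:
    """-RT ln Z from the scaled inside matrix (<= 0; 0 iff no structure)."""
    z_scaled = q[0, n - 1]
    return -params.rt * (math.log(z_scaled) + n * (_SIGMA_E / params.rt))


def fold_sequence(
    seq: str,
    params: NNParameterTable | None = None,
    banned: np.ndarray | None = None,
    offset: int = 0,
) -> EnsembleModel:
    """Fold one window exactly; ``banned`` positions are held single-stranded."""
    params = params or default_params()
    n = len(seq)
    if n < 4:
        return EnsembleModel(seq, offset, np.zeros((n, n)), np.ones(n), 0.0)
    codes = encode(seq)
    if banned is None:
        banned = np.zeros(n, dtype=np.bool_)
    q, qb, inv_sigma, wpair = _scaled_inside(codes, params, banned)
    qc = _kernels.pf_outside(
        codes.astype(np.int64), q, qb, params.stack_weights(), wpair,
        params.pairable, params.min_hairpin, inv_sigma,
    )
    p = _kernels.pair_probabilities(q, qb, qc)
    s = 1.0 - (p.sum(axis=1) + p.sum(axis=0))
    s = np.clip(s, 0.0, 1.0)
    e = ensemble_free_energy(q, n, params)
    return EnsembleModel(seq, offset, p, s, min(e, 0.0))


def sample_structures(
    seq: str,
    n_samples: int,
    seed: int = 0,
    params: NNParameterTable | None = None,
) -> list[tuple[tuple[int, int], ...]]:
    """Draw structures from the Boltzmann ensemble (seeded, exact weights).

    Stochastic traceback over the inside matrices: each returned structure
    (a sorted tuple of pairs) appears with probability proportional to its
    Boltzmann weight.  Provided for fidelity experiments against the exact
    partition-function quantities; the pipeline itself never samples.
    """
    params = params or default_params()
    n = len(seq)
    if n < 4:
        return [tuple() for _ in range(n_samples)]
    codes = encode(seq)
    q, qb, inv_sigma, wpair = _scaled_inside(codes, params)
    ws_tab = params.stack_weights()
    wp = wpair * inv_sigma * inv_sigma
    rng = np.random.default_rng(seed)

    def qv(i, j):
        return 1.0 if i > j else q[i, j]

    def trace_interval(i, j, pairs):
        while i <= j:
            tot = q[i, j] if i < j else inv_sigma
            u = rng.random() * tot
            u -= qv(i, j - 1) * inv_sigma
            if u < 0 or i == j:
                j -= 1
                continue
            for k in range(i, j - params.min_hairpin):
                if qb[k, j] <= 0:
                    continue
                u -= qv(i, k - 1) * qb[k, j]
                if u < 0:
                    trace_pair(k, j, pairs)
                    j = k - 1
                    break
            else:  # pragma: no cover - numerical safety
                j -= 1

    def trace_pair(i, j, pairs):
        pairs.append((i, j))
        inner_q = qv(i + 1, j - 1)
        stacked = 0.0
        if (j - i - 3 >= params.min_hairpin
                and params.pairable[codes[i + 1], codes[j - 1]]):
            ws = ws_tab[4 * codes[i] + codes[j], 4 * codes[i + 1] + codes[j - 1]]
            stacked = (ws - 1.0) * qb[i + 1, j - 1]
        u = rng.random() * (inner_q + stacked)
        if u < inner_q:
            trace_interval(i + 1, j - 1, pairs)
        else:
            trace_pair(i + 1, j - 1, pairs)

    out = []
    for _ in range(n_samples):
        pairs: list[tuple[int, int]] = []
        trace_interval(0, n - 1, pairs)
        out.append(tuple(sorted(pairs)))
    return out


def window_for_site(
    transcript_len: int, start: int, end: int, window_size: int
) -> tuple[int, int]:
    """A window of at most ``window_size`` nt centered on [start, end)."""
    if window_size < end - start:
        raise ValueError("fold window smaller than the site")
    mid = (start + end) // 2
    a = mid - window_size // 2
    a = max(0, min(a, transcript_len - window_size))
    a = max(a, 0)
    b = min(transcript_len, a + window_size)
    return a, b


def fold_window(
    transcript,
    center_interval: tuple[int, int],
    window_size: int = 200,
    params: NNParameterTable | None = None,
) -> EnsembleModel:
    """Fold a local window of a transcript centered on a site interval."""
    seq = transcript.seq if hasattr(transcript, "seq") else str(transcript)
    a, b = window_for_site(len(seq), *center_interval, window_size)
    return fold_sequence(seq[a:b], params, offset=a)


def block_accessibility(ensemble: EnsembleModel, start: int, end: int) -> float:
    """Mean single-strandedness over a transcript-coordinate block."""
    if end <= start:
        raise ValueError("empty accessibility block")
    return float(ensemble.s_at(start, end).mean())


def accessibility_profile(
    transcript,
    site_interval: tuple[int, int],
    ensemble: EnsembleModel,
    windows=(5, 10, 15, 20, 25, 30),
    seed_block: tuple[int, int] | None = None,
) -> AccessibilityProfile:
    """Site, seed and flank accessibilities.

    Flank blocks are truncated at transcript/window edges; a block truncated
    to zero length yields NaN.
    """
    n = len(transcript.seq) if hasattr(transcript, "seq") else len(transcript)
    start, end = site_interval
    wa, wb = ensemble.window
    site = block_accessibility(ensemble, start, end)
    seed = (
        block_accessibility(ensemble, *seed_block)
        if seed_block is not None
        else float("nan")
    )
    up, down = {}, {}
    for w in windows:
        a = max(start - w, 0, wa)
        up[w] = block_accessibility(ensemble, a, start) if a < start else float("nan")
        b = min(end + w, n, wb)
        down[w] = block_accessibility(ensemble, end, b) if b > end else float("nan")
    return AccessibilityProfile(site, seed, up, down)


def delta_g_disruption(
    transcript,
    site_interval: tuple[int, int],
    window_size: int = 200,
    params: NNParameterTable | None = None,
    ensemble: EnsembleModel | None = None,
) -> float:
    """Free-energy cost of opening target structure over the site (>= 0).

    Computed as the constrained (site forced single-stranded) minus the
    unconstrained ensemble free energy of the same window.  An existing
    ``ensemble`` for the same window supplies the unconstrained half.
    """
    params = params or default_params()
    seq = transcript.seq if hasattr(transcript, "seq") else str(transcript)
    start, end = site_interval
    if ensemble is not None:
        a, b = ensemble.window
        window_seq = ensemble.seq
        e_free = ensemble.e_ens
    else:
        a, b = window_for_site(len(seq), start, end, window_size)
        window_seq = seq[a:b]
        e_free = None
    n = len(window_seq)
    if n < 4:
        return 0.0
    codes = encode(window_seq)
    if e_free is None:
        q, _, _, _ = _scaled_inside(codes, params)
        e_free = ensemble_free_energy(q, n, params)
    banned = np.zeros(n, dtype=np.bool_)
    banned[max(start - a, 0):min(end - a, n)] = True
    qc_, _, _, _ = _scaled_inside(codes, params, banned)
    e_constrained = ensemble_free_energy(qc_, n, params)
    return max(e_constrained - e_free, 0.0)


def delta_g_nucl(
    duplex: HybridDuplex,
    ensemble: EnsembleModel,
    mirna_seq: str,
    target_seq: str,
    params: NNParameterTable | None = None,
    block_len: int = 4,
) -> float:
    """Nucleation potential of a duplex (kcal/mol); NaN = NO_NUCLEATION.

    Minimum over every ``block_len``-pair contiguously stacked block of the
    duplex of: block helix energy (initiation + stacks) plus the opening
    cost -RT ln(mean single-strandedness of the block's target nucleotides).
    Blocks exist only where ``block_len`` consecutive miRNA positions pair
    consecutive target positions; if none exists, or the best block is
    unfavorable (> 0), there is no nucleation site.
    """
    params = params or default_params()
    pairs = list(duplex.pairs)
    runs: list[list[tuple[int, int]]] = []
    run: list[tuple[int, int]] = []
    for k, (mi, tj) in enumerate(pairs):
        if run and (mi == run[-1][0] + 1 and tj == run[-1][1] - 1):
            run.append((mi, tj))
        else:
            if len(run) >= block_len:
                runs.append(run)
            run = [(mi, tj)]
    if len(run) >= block_len:
        runs.append(run)
    if not runs:
        return float("nan")
    mir = encode(mirna_seq)
    tgt = encode(target_seq)
    best = math.inf
    wa, wb = ensemble.window
    for run in runs:
        for k in range(len(run) - block_len + 1):
            block = run[k:k + block_len]
            helix = params.duplex_init
            for (mi1, tj1), (mi2, tj2) in zip(block, block[1:]):
                helix += params.stack[
                    4 * mir[mi1] + tgt[tj1], 4 * mir[mi2] + tgt[tj2]
                ]
            t_lo = min(t for _, t in block)
            t_hi = max(t for _, t in block) + 1
            if t_lo < wa or t_hi > wb:
                continue
            sbar = float(ensemble.s_at(t_lo, t_hi).mean())
            sbar = max(sbar, 1e-300)
            cand = helix - params.rt * math.log(sbar)
            if cand < best:
                best = cand
    if not math.isfinite(best) or best > 0:
        return float("nan")
    return best


def delta_g_total(dg_hybrid: float, dg_disruption: float) -> float:
    """Total hybridization energy: dG_hybrid + dG_disruption."""
    return dg_hybrid + dg_disruption
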