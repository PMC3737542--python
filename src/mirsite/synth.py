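"""Seeded synthetic CLIP-style datasets with planted miRNA binding sites.

The generator emulates the statistical structure the pipeline is built to
detect: transcripts carry exact seed-type complements of synthetic miRNAs;
half of the plants ("wrapped") are covered by an AGO-crosslink region (CCR,
~50 nt, as in CLIP protocols) and sit in favorable contexts — AU-elevated,
unstructured, conservation-elevated — while the other half are decoys
placed outside CCRs in contexts degraded by the configured effect sizes
(structure clamps over the site and upstream flank, AU depletion, background
conservation).  With all effect sizes zero the wrapped and decoy
neighborhoods are exchangeable, so every downstream statistic is null.

All randomness flows through one seeded generator; the same config and seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import ClipRegion, ConservationTrack, MiRnaRecord, TranscriptRecord
from .params import BASES, WC_PARTNER

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class PlantedSiteSpec:
    """One planted site: where it was written and what it should look like."""

    mirna_id: str
    transcript_id: str
    start: int          # planted complement block, transcript coordinates
    end: int
    seed_type: str
    wrapped: bool       # covered by a CLIP region (expected IP+)
    three_prime: bool


@dataclass
class SynthConfig:
    """Generator knobs; the defaults are the package's study conditions."""

    n_transcripts: int = 100
    n_mirnas: int = 10
    mirna_length: int = 22
    utr5_len: int = 60
    cds_len: int = 1000
    utr3_len: int = 2580
    len_jitter: float = 0.1            # fractional region-length jitter
    wrapped_per_transcript: int = 20
    decoy_per_transcript: int = 20
    background_per_transcript: int = 0  # neutral-context, unwrapped plants
    scrub_accidental_seeds: bool = True
    scrub_dg_threshold: float = -14.0  # also scrub background duplexes below this
    seed_type_mix: dict = field(default_factory=lambda: {
        "8mer": 0.30, "7mer-m8": 0.25, "7mer-A1": 0.20,
        "6mer": 0.15, "offset-6mer": 0.10,
    })
    three_prime_fraction: float = 0.5
    # effect sizes between IP+ (wrapped) and IP- (decoy) neighborhoods
    dg_total_shift: float = -3.0       # kcal/mol (negative favors IP+)
    access_shift: float = 0.3
    au_shift: float = 0.2
    cons_shift: float = 0.3
    flank_width: int = 30              # AU-modulated flank on each side
    ccr_width_mean: float = 50.0
    ccr_width_sd: float = 5.0
    ccr_jitter: int = 8
    cons_background_mean: float = 0.4
    cons_concentration: float = 5.0
    gc_bias: float = 0.0               # added GC fraction of background
    seed: int = 0

    def __post_init__(self):
        if self.wrapped_per_transcript < 0 or self.decoy_per_transcript < 0:
            raise ValueError("site counts must be >= 0")
        total = sum(self.seed_type_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("seed_type_mix must sum to 1")
        for name in ("access_shift", "au_shift", "cons_shift"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "SynthConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass
class SynthDataset:
    transcripts: list
    mirnas: list
    clip_regions: list
    tracks: list
    truth: pd.DataFrame
    config: SynthConfig

    def track_map(self) -> dict:
        return {t.transcript_id: t for t in self.tracks}

    def write(self, outdir) -> dict:
        """Write the dataset in the exact formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "transcripts": "transcripts.fa", "mirnas": "mirnas.fa",
            "regions": "regions.tsv", "clip": "clip.tsv",
            "conservation": "conservation.tsv", "truth": "truth.tsv",
        }.items()}
        with open(paths["transcripts"], "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.id}\n{t.seq}\n")
        with open(paths["mirnas"], "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.id}\n{m.seq}\n")
        pd.DataFrame(
            [(t.id, t.utr5_end, t.cds_end) for t in self.transcripts],
            columns=["transcript_id", "utr5_end", "cds_end"],
        ).to_csv(paths["regions"], sep="\t", index=False)
        with open(paths["clip"], "w") as fh:
            for r in self.clip_regions:
                fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.source_label}\n")
        rows = []
        for tr in self.tracks:
            for pos, score in enumerate(tr.scores):
                if not np.isnan(score):
                    rows.append((tr.transcript_id, pos, score))
        pd.DataFrame(rows, columns=["transcript_id", "position", "score"]).to_csv(
            paths["conservation"], sep="\t", index=False, float_format="%.6f"
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_seq(rng, n: int, p_au: float = 0.5) -> np.ndarray:
    """Random base string (index-coded) with a given total A+U probability."""
    pa = p_au / 2
    pg = (1 - p_au) / 2
    return rng.choice(4, size=n, p=[pa, pg, pg, pa])  # A, C, G, U


def _mutate_away(rng, partner_code: int) -> str:
    """A base that neither WC- nor GU-pairs the given miRNA base."""
    bad = {WC_PARTNER[partner_code]}
    if partner_code == 2:      # G also pairs U
        bad.add(3)
    if partner_code == 3:      # U also pairs G
        bad.add(2)
    choices = [b for b in range(4) if b not in bad]
    return BASES[choices[int(rng.integers(len(choices)))]]


def _site_block(rng, mirna_seq: str, seed_type: str, three_prime: bool) -> str:
    """Target-sense complement block implementing one seed class.

    The block is the reverse complement of miRNA nt 1..L (L = 17 with 3'
    supplementary pairing, otherwise 10), then mutated at the positions that
    define the class: the nucleotide opposite nt 1 (A anchor or not) and,
    for classes without an nt-8 match, a non-pairing base opposite nt 8 (or
    nt 2 for the offset 6mer).
    """
    L = 17 if three_prime else 10
    block = list(revcomp(mirna_seq[:L]))
    mir = ["ACGU".index(b) for b in mirna_seq]

    def set_opposite(nt: int, base: str):
        block[L - nt] = base

    def break_opposite(nt: int):
        set_opposite(nt, _mutate_away(rng, mir[nt - 1]))

    if seed_type in ("8mer", "7mer-A1"):
        set_opposite(1, "A")
    else:
        # anything but A opposite nt 1 (keep it non-pairing for cleanliness)
        alt = [b for b in "CG" if b != _COMP[mirna_seq[0]]]
        set_opposite(1, alt[0] if alt else "C")
    if seed_type in ("7mer-A1", "6mer"):
        break_opposite(8)
    if seed_type == "offset-6mer":
        break_opposite(2)
    return "".join(block)


def _cross_duplex_clean(block, own_id, mirnas, dg_threshold, params) -> bool:
    """True iff no *other* miRNA forms a duplex below threshold with block."""
    from . import duplex as duplex_mod
    from .params import encode

    tgt = encode(block)
    for m in mirnas:
        if m.id == own_id:
            continue
        B, _ = duplex_mod._fill(encode(m.seq), tgt, params)
        if B.min() <= dg_threshold:
            return False
    return True


def _scrub_needles(seq_list, protected, needles) -> bool:
    """Complement-swap one free position of every unprotected needle match."""
    changed = False
    seq = "".join(seq_list)
    for needle in needles:
        start = seq.find(needle)
        while start >= 0:
            span = range(start, start + len(needle))
            free = [q for q in span if not protected[q]]
            if free:
                q = free[len(free) // 2]
                seq_list[q] = _COMP[seq_list[q]]
                changed = True
            start = seq.find(needle, start + 1)
    return changed


def _unpairable_base(mir_base: str) -> str:
    """A target base that neither WC- nor GU-pairs the given miRNA base."""
    bad = {_COMP[mir_base]}
    if mir_base == "G":
        bad.add("U")
    if mir_base == "U":
        bad.add("G")
    return next(b for b in "ACGU" if b not in bad)


def _scrub_duplexes(seq_list, protected, owner, mirnas, dg_threshold, params,
                    aggressive=False) -> bool:
    """Break accidental stable background duplexes of the panel miRNAs.

    A site whose span touches sequence owned by a plant of the *same*
    miRNA is that plant's own duplex and is left intact.  Any other stable
    site has two unprotected paired target positions complement-swapped,
    which severs those pairs while preserving A/U content; block screening
    at plant time guarantees the protected remainder is too weak to stay
    above threshold on its own.  In ``aggressive`` mode (later passes, for
    low-complexity tracts where swaps just reshuffle complementarity) the
    chosen positions are instead set to a base that cannot pair their
    miRNA partner at all.
    """
    from . import duplex as duplex_mod
    from .params import encode

    changed = False
    tgt = encode("".join(seq_list))
    for mix, mirna in enumerate(mirnas):
        mir = encode(mirna.seq)
        B, pred = duplex_mod._fill(mir, tgt, params)
        start_best = B.min(axis=0)
        start_arg = B.argmin(axis=0)
        for j in np.flatnonzero(start_best <= dg_threshold):
            pairs = duplex_mod._traceback(pred, len(tgt), int(start_arg[j]), int(j))
            tjs = sorted(t for _, t in pairs)
            if (owner[tjs[0]:tjs[-1] + 1] == mix).any():
                continue                     # the plant's own duplex
            free = [(mi, tj) for mi, tj in pairs if not protected[tj]]
            if not free:
                continue
            for mi, q in {free[len(free) // 3], free[2 * len(free) // 3]}:
                if aggressive:
                    seq_list[q] = _unpairable_base(mirna.seq[mi])
                else:
                    seq_list[q] = _COMP[seq_list[q]]
            changed = True
    return changed


def _scrub_matches(seq_list, protected, owner, needles, mirnas=None,
                   dg_threshold=None, params=None, max_passes=10) -> None:
    """Remove accidental binding signal from background sequence.

    Iterates needle scrubbing (exact seed-complement matches) and, when a
    parameter table is given, duplex scrubbing (stable threshold-mode
    hits), until a pass changes nothing.  Planted blocks and clamps are
    protected and never mutated.
    """
    for p in range(max_passes):
        changed = _scrub_needles(seq_list, protected, needles)
        if params is not None:
            changed |= _scrub_duplexes(
                seq_list, protected, owner, mirnas, dg_threshold, params,
                aggressive=(p >= 3),
            )
        if not changed:
            break


def generate_dataset(config: SynthConfig, seed: int | None = None) -> SynthDataset:
    """Generate transcripts, miRNAs, CLIP regions, conservation and truth.

    Wrapped plants get AU-elevated flanks and elevated conservation and are
    covered by a CCR; decoys get AU-depleted flanks, a stem clamp over the
    site sized by the ΔG_total shift, a stem clamp over the upstream flank
    sized by the accessibility shift, and background conservation.
    Background plants (``background_per_transcript``) sit in unmodified
    context and are never wrapped.

    Accidental seed-complement matches in the remaining background sequence
    are mutated out (complement swaps, preserving A/U content) so that the
    truth table is exhaustive: with all effect shifts zero, the IP+ and IP-
    neighborhoods are exchangeable by construction.
    """
    from .params import default_params

    cfg = config
    params_tbl = default_params()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mirnas = []
    for k in range(cfg.n_mirnas):
        seq = "".join(BASES[b] for b in _random_seq(rng, cfg.mirna_length))
        mirnas.append(MiRnaRecord(f"mir{k:03d}", seq))

    site_clamp = 0
    if cfg.dg_total_shift != 0:
        site_clamp = int(np.clip(round(abs(cfg.dg_total_shift)) + 3, 4, 10))
    flank_clamp = 0
    if cfg.access_shift != 0:
        flank_clamp = int(np.clip(round(abs(cfg.access_shift) * 20), 4, 10))

    p_au_bg = np.clip(0.5 - cfg.gc_bias, 0.05, 0.95)
    p_au_pos = float(np.clip(p_au_bg + cfg.au_shift / 2, 0.05, 0.95))
    p_au_neg = float(np.clip(p_au_bg - cfg.au_shift / 2, 0.05, 0.95))

    conc = cfg.cons_concentration
    m_bg = cfg.cons_background_mean
    m_site = float(np.clip(m_bg + 0.8 * cfg.cons_shift, 0.02, 0.95))
    m_seed = float(np.clip(m_bg + 1.2 * cfg.cons_shift, 0.02, 0.97))

    transcripts, clip_regions, tracks, truth_rows = [], [], [], []
    seed_types = list(cfg.seed_type_mix)
    seed_probs = np.array([cfg.seed_type_mix[t] for t in seed_types])
    n_plants = (
        cfg.wrapped_per_transcript + cfg.decoy_per_transcript
        + cfg.background_per_transcript
    )
    spans = ((1, 7), (1, 8), (2, 8))
    needles = sorted({
        revcomp(m.seq[lo:hi]) for m in mirnas for lo, hi in spans
    })
    needles_of = {
        m.id: {revcomp(m.seq[lo:hi]) for lo, hi in spans} for m in mirnas
    }

    for tix in range(cfg.n_transcripts):
        tid = f"tx{tix:04d}"
        lens = []
        for base_len in (cfg.utr5_len, cfg.cds_len, cfg.utr3_len):
            jit = 1.0 + cfg.len_jitter * (2 * rng.random() - 1)
            lens.append(max(10, int(round(base_len * jit))))
        utr5_end = lens[0]
        cds_end = lens[0] + lens[1]
        total = sum(lens)
        seq = _random_seq(rng, total, p_au_bg)
        seq_list = list("".join(BASES[b] for b in seq))
        cons = rng.beta(m_bg * conc, (1 - m_bg) * conc, size=total)

        # each plant owns a slot wide enough that its flank rewrites and
        # clamps (~77 nt of footprint) cannot touch a neighboring plant
        lo = utr5_end + 5
        hi = total - 55
        slot = (hi - lo) / max(n_plants, 1)
        if slot < 79:
            raise ValueError(
                f"transcript {tid} too short for {n_plants} planted sites"
            )
        categories = (
            ["wrapped"] * cfg.wrapped_per_transcript
            + ["decoy"] * cfg.decoy_per_transcript
            + ["background"] * cfg.background_per_transcript
        )
        rng.shuffle(categories)
        protected = np.zeros(total, dtype=bool)
        owner = np.full(total, -1, dtype=np.int32)   # miRNA index per plant

        for k in range(n_plants):
            category = categories[k]
            wrapped = category == "wrapped"
            st = seed_types[int(rng.choice(len(seed_types), p=seed_probs))]
            three_p = bool(rng.random() < cfg.three_prime_fraction)
            # pick a miRNA whose block neither contains another miRNA's
            # seed complement nor forms a stable cross-duplex with one:
            # such signal sits inside the protected block where the
            # background scrub cannot reach, and would leak unintended
            # sites into the IP- universe
            first = int(rng.integers(cfg.n_mirnas))
            for probe in range(cfg.n_mirnas):
                mirna = mirnas[(first + probe) % cfg.n_mirnas]
                block = _site_block(rng, mirna.seq, st, three_p)
                foreign = set(needles) - needles_of[mirna.id]
                if any(n in block for n in foreign):
                    continue
                if _cross_duplex_clean(
                    block, mirna.id, mirnas, cfg.scrub_dg_threshold, params_tbl
                ):
                    break
            L = len(block)
            s = int(lo + k * slot + rng.integers(0, max(1, int(slot) - 78)))
            # AU-modulated flanks, then the site block itself
            if category == "wrapped":
                p_au = p_au_pos
            elif category == "decoy":
                p_au = p_au_neg
            else:
                p_au = float(p_au_bg)
            fl = cfg.flank_width
            for a, b in ((max(0, s - fl), s), (s + L, min(total, s + L + fl))):
                if b > a:
                    flank = _random_seq(rng, b - a, p_au)
                    seq_list[a:b] = [BASES[x] for x in flank]
            seq_list[s:s + L] = list(block)
            protected[s:s + L] = True
            mirna_index = mirnas.index(mirna)
            owner[s:s + L] = mirna_index
            if category == "decoy":
                if site_clamp:
                    stem = revcomp("".join(seq_list[s:s + site_clamp]))
                    a = s + L + 4
                    seq_list[a:a + site_clamp] = list(stem)
                    protected[a:a + site_clamp] = True
                    owner[a:a + site_clamp] = mirna_index
                if flank_clamp:
                    a = s - flank_clamp            # immediate upstream flank
                    b = a - flank_clamp - 4        # its partner, further 5'
                    if b >= 0:
                        stem = revcomp("".join(seq_list[a:s]))
                        seq_list[b:b + flank_clamp] = list(stem)
                        protected[b:b + flank_clamp] = True
                        protected[a:s] = True
                        owner[b:b + flank_clamp] = mirna_index
                        owner[a:s] = mirna_index
            elif category == "wrapped":
                cons[s:s + L] = rng.beta(
                    m_site * conc, (1 - m_site) * conc, size=L
                )
                sb0, sb1 = s + L - 8, s + L - 1    # block opposite nt 2-8
                cons[sb0:sb1] = rng.beta(
                    m_seed * conc, (1 - m_seed) * conc, size=sb1 - sb0
                )
                width = int(np.clip(
                    round(rng.normal(cfg.ccr_width_mean, cfg.ccr_width_sd)),
                    48, 80,
                ))
                mid = s + L // 2
                jitter = int(rng.integers(-cfg.ccr_jitter, cfg.ccr_jitter + 1))
                a = max(0, mid - width // 2 + jitter)
                b = min(total, a + width)
                clip_regions.append(ClipRegion(tid, a, b, "synthetic"))
            # the seed-complementary core: the target block the duplex is
            # guaranteed to pair for this class (opposite nt 2-8, 2-7 or 3-8)
            if st in ("8mer", "7mer-m8"):
                core = (s + L - 8, s + L - 1)
            elif st == "offset-6mer":
                core = (s + L - 8, s + L - 2)
            else:                                  # 7mer-A1, 6mer
                core = (s + L - 7, s + L - 1)
            truth_rows.append({
                "transcript_id": tid, "mirna_id": mirna.id,
                "start": s, "end": s + L,
                "core_start": core[0], "core_end": core[1],
                "seed_type": st, "wrapped": wrapped, "three_prime": three_p,
                "category": category,
            })
        if cfg.scrub_accidental_seeds:
            _scrub_matches(
                seq_list, protected, owner, needles, mirnas,
                cfg.scrub_dg_threshold, params_tbl,
            )
        transcripts.append(
            TranscriptRecord(tid, "".join(seq_list), utr5_end, cds_end)
        )
        tracks.append(ConservationTrack(tid, np.clip(cons, 0.0, 1.0)))

    truth = pd.DataFrame(truth_rows)
    clip_regions.sort(key=lambda r: (r.transcript_id, r.start, r.end))
    return SynthDataset(transcripts, mirnas, clip_regions, tracks, truth, cfg)


def generate_feature_table(
    n_pos: int,
    n_neg: int,
    coefficients,
    interaction_coeffs: dict | None = None,
    seed: int = 0,
    alpha: float = 0.0,
) -> pd.DataFrame:
    """Feature table with a known logistic law, for parameter recovery.

    Covariates x1..xk are standard normal; the outcome is Bernoulli with
    log-odds alpha + sum beta_i x_i + sum gamma_ij x_i x_j.  Rows are drawn
    until each class holds its requested count, then truncated, so the
    returned table is balanced exactly as asked (case-control sampling:
    slopes are unaffected; the intercept is shifted when n_pos/n_neg differs
    from the model's marginal odds).
    """
    beta = np.asarray(coefficients, dtype=float)
    k = len(beta)
    gamma = interaction_coeffs or {}
    rng = np.random.default_rng(seed)
    pos_rows, neg_rows = [], []
    while len(pos_rows) < n_pos or len(neg_rows) < n_neg:
        batch = max(1024, 2 * (n_pos + n_neg))
        X = rng.standard_normal((batch, k))
        eta = alpha + X @ beta
        for (i, j), g in gamma.items():
            eta = eta + g * X[:, i] * X[:, j]
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        for row, label in zip(X, y):
            if label and len(pos_rows) < n_pos:
                pos_rows.append(row)
            elif not label and len(neg_rows) < n_neg:
                neg_rows.append(row)
    X = np.vstack([np.array(pos_rows), np.array(neg_rows)])
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(k)])
    df["ip_label"] = np.r_[np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)]
    return df
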