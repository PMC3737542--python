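"""Nearest-neighbor energy parameters shared by the duplex and folding models.

A single plain-text table (``data/nn_params.tsv``) holds the stacking free
energies for all Watson-Crick and G:U wobble dinucleotide steps, the duplex
initiation term, linear loop penalties and the folding constants.  Both the
intermolecular duplex dynamic program and the intramolecular partition
function read this table, so there is exactly one parameter source for every
energy in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: nucleotide codes used by all numeric kernels
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

A, C, G, U = 0, 1, 2, 3

#: Watson-Crick complement partner (index-coded)
WC_PARTNER = {A: U, U: A, C: G, G: C}

#: every admissible pair (WC + GU wobble), as (base, partner) index tuples
CANONICAL_PAIRS = {(A, U), (U, A), (C, G), (G, C), (G, U), (U, G)}


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as an int8 array (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - caller validates
        raise ValueError(f"invalid RNA base {exc.args[0]!r} in sequence") from exc


def is_wc(x: int, y: int) -> bool:
    return WC_PARTNER[x] == y


def can_pair(x: int, y: int) -> bool:
    return (x, y) in CANONICAL_PAIRS


@dataclass(frozen=True)
class NNParameterTable:
    """Bundled Turner-style nearest-neighbor parameter set.

    Attributes
    ----------
    stack : (16, 16) float array
        ``stack[4*x + y, 4*w + z]`` is the stacking free energy (kcal/mol)
        of the step 5'-x w-3' / 3'-y z-5'; +inf where either pair is not
        admissible.
    duplex_init : float
        Intermolecular duplex initiation penalty (>= 0).
    bulge_per_nt, internal_per_nt : float
        Linear per-nucleotide penalties for one-sided bulges and two-sided
        internal loops in the duplex model (> 0).
    max_loop : int
        Maximum unpaired stretch per side between consecutive duplex pairs.
    pair_penalty : float
        Per-base-pair loop/entropy surcharge of the folding model (> 0).
    min_hairpin : int
        Minimum number of unpaired nucleotides closed by a hairpin pair.
    rt : float
        Gas constant times temperature, kcal/mol at 310.15 K.
    """

    stack: np.ndarray
    duplex_init: float
    bulge_per_nt: float
    internal_per_nt: float
    max_loop: int
    pair_penalty: float
    min_hairpin: int
    rt: float
    pairable: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.duplex_init < 0:
            raise ValueError("duplex initiation term must be >= 0")
        for name in ("bulge_per_nt", "internal_per_nt", "pair_penalty"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        pairable = np.zeros((4, 4), dtype=np.bool_)
        for x, y in CANONICAL_PAIRS:
            pairable[x, y] = True
        # every admissible step must have a finite entry
        for x, y in CANONICAL_PAIRS:
            for w, z in CANONICAL_PAIRS:
                if not np.isfinite(self.stack[4 * x + y, 4 * w + z]):
                    raise ValueError(
                        f"missing stack entry for {BASES[x]}{BASES[y]}/{BASES[w]}{BASES[z]}"
                    )
        object.__setattr__(self, "pairable", pairable)

    def stack_weights(self) -> np.ndarray:
        """Boltzmann weights exp(-dG/RT) of the stack table (0 where absent)."""
        w = np.zeros_like(self.stack)
        finite = np.isfinite(self.stack)
        w[finite] = np.exp(-self.stack[finite] / self.rt)
        return w


def _parse(text: str) -> NNParameterTable:
    stack = np.full((16, 16), np.inf)
    scalars: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, *rest = line.split("\t")
        if kind == "stack":
            p1, p2, dg = rest
            x, y = BASE_INDEX[p1[0]], BASE_INDEX[p1[1]]
            w, z = BASE_INDEX[p2[0]], BASE_INDEX[p2[1]]
            stack[4 * x + y, 4 * w + z] = float(dg)
        elif kind == "scalar":
            scalars[rest[0]] = float(rest[1])
        else:
            raise ValueError(f"unknown parameter line: {line!r}")
    return NNParameterTable(
        stack=stack,
        duplex_init=scalars["duplex_init"],
        bulge_per_nt=scalars["bulge_per_nt"],
        internal_per_nt=scalars["internal_per_nt"],
        max_loop=int(scalars["max_loop"]),
        pair_penalty=scalars["pair_penalty"],
        min_hairpin=int(scalars["min_hairpin"]),
        rt=scalars["rt"],
    )


_DEFAULT: NNParameterTable | None = None


def default_params() -> NNParameterTable:
    """The bundled parameter table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = (
            resources.files("mirsite").joinpath("data/nn_params.tsv").read_text()
        )
        _DEFAULT = _parse(text)
    return _DEFAULT


def load_params(path) -> NNParameterTable:
    """Load a parameter table from a plain-text file (same format as bundled)."""
    with open(path) as fh:
        return _parse(fh.read())
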