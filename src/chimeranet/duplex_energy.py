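"""Intermolecular miRNA:target-site hybridization energy.

Computes the minimum free energy (MFE, kcal/mol) of the best duplex a
miRNA can form with a candidate site, under a transparent nearest-neighbor
model: stacked canonical pairs (Watson-Crick plus, by default, G-U wobble)
contribute tabulated stacking free energies; bulges and internal loops
contribute size-dependent penalties; a single duplex-initiation term is
charged once.  Intramolecular pairs, multiloops, dangling ends and coaxial
stacking are outside the model.

The duplex MFE gates candidate target sites during transcript scanning:
only sites hybridizing at or below a threshold (default -20 kcal/mol) are
passed to the classifier.

The parameter table ships as versioned plain text
(``data/nn_duplex_params_v1.tsv``).  Absolute energies from this simplified
model differ from full hybridization programs; the threshold is exposed
wherever the filter is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .sequence_io import SequenceRecord  # noqa: F401  (re-exported context type)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

_PARAM_FILE = "nn_duplex_params_v1.tsv"


@dataclass
class NNParameterSet:
    """Nearest-neighbor duplex parameters.

    ``stack_energies`` maps (5'-side pair, 3'-side pair) to dG37, each pair
    written as top-strand base + bottom-strand base of the antiparallel
    stack.  Loop penalties are indexed by total unpaired bases.
    """

    stack_energies: dict[tuple[str, str], float]
    bulge_penalties: dict[int, float]
    internal_penalties: dict[int, float]
    duplex_init: float
    max_loop: int = 8
    allow_wobble: bool = True
    version: str = "v1"

    def __post_init__(self):
        for stack, dg in self.stack_energies.items():
            if dg > 0:
                raise ValidationError(f"stack {stack} has positive energy {dg}")
        if any(v < 0 for v in self.bulge_penalties.values()) or any(
            v < 0 for v in self.internal_penalties.values()
        ):
            raise ValidationError("loop penalties must be non-negative")

    def pairable(self, x: str, y: str) -> bool:
        return (x, y) in _WC or (self.allow_wobble and (x, y) in _WOBBLE)

    def loop_penalty(self, gx: int, gy: int) -> float:
        """Cost of gx unpaired top-strand and gy unpaired bottom-strand
        bases between two consecutive pairs (not both zero)."""
        if gx > 0 and gy > 0:
            return self.internal_penalties[gx + gy]
        return self.bulge_penalties[gx + gy]


def load_parameters(path: str | Path | None = None, *, allow_wobble: bool = True) -> NNParameterSet:
    """Load the shipped (or a user-supplied) plain-text parameter table."""
    if path is None:
        text = (
            resources.files("chimeranet").joinpath("data", _PARAM_FILE).read_text()
        )
        version = _PARAM_FILE.rsplit("_", 1)[-1].split(".")[0]
    else:
        text = Path(path).read_text()
        version = Path(path).stem
    stacks: dict[tuple[str, str], float] = {}
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    init = None
    max_loop = 8
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            p1, p2 = key.split(",")
            stacks[(p1, p2)] = float(value)
        elif kind == "bulge":
            bulge[int(key)] = float(value)
        elif kind == "internal":
            internal[int(key)] = float(value)
        elif kind == "init":
            init = float(value)
        elif kind == "max_loop":
            max_loop = int(value)
    if init is None or not stacks:
        raise ValidationError("parameter table incomplete")
    return NNParameterSet(
        stacks, bulge, internal, init, max_loop=max_loop,
        allow_wobble=allow_wobble, version=version,
    )


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_parameters() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_parameters()
    return _DEFAULT_PARAMS


@dataclass
class DuplexResult:
    """Best intermolecular structure of a miRNA:site hybrid.

    ``pairs`` lists (miRNA index, site index) base pairs, 0-based on each
    strand's own 5'->3' orientation.  ``pairing`` is a two-line dot-bracket
    rendering joined by '&'.  ``mfe`` is 0 with no pairs when no structure
    has negative free energy.
    """

    mfe: float
    pairs: list[tuple[int, int]]
    mirna_span: tuple[int, int]  # half-open index range of paired miRNA bases
    site_span: tuple[int, int]

    @property
    def pairing(self) -> str:
        if not self.pairs:
            return "&"
        n_a = max(i for i, _ in self.pairs) + 1
        n_b = max(j for _, j in self.pairs) + 1
        line_a = ["."] * n_a
        line_b = ["."] * n_b
        for i, j in self.pairs:
            line_a[i] = "("
            line_b[j] = ")"
        return "".join(line_a) + "&" + "".join(line_b)


def duplex_mfe(
    mirna_seq: str,
    site_seq: str,
    params: NNParameterSet | None = None,
) -> DuplexResult:
    """Minimum free energy over all intermolecular duplex structures.

    Dynamic program over pairs (i on the miRNA, j on the site, antiparallel),
    extending a duplex by a stack or by a bulge/internal loop of at most
    ``params.max_loop`` unpaired bases per side.
    """
    if params is None:
        params = default_parameters()
    if len(mirna_seq) < 2 or len(site_seq) < 2:
        raise ValidationError("duplex_mfe needs sequences of length >= 2")
    a = mirna_seq
    c = site_seq[::-1]  # reverse so pairing indices increase on both strands
    n, m = len(a), len(c)

    base_idx = {"A": 0, "U": 1, "G": 2, "C": 3}
    ai = np.array([base_idx[b] for b in a])
    ci = np.array([base_idx[b] for b in c])

    # pairability mask P[i, j] and 4x4 pair lookup
    pair_ok = np.zeros((4, 4), dtype=bool)
    for x, y in _WC | (_WOBBLE if params.allow_wobble else set()):
        pair_ok[base_idx[x], base_idx[y]] = True
    P = pair_ok[ai[:, None], ci[None, :]]

    # stack energy for adjacent pairs (i-1, j-1), (i, j); +inf where undefined
    letters = "AUGC"
    stack44 = np.full((4, 4, 4, 4), np.inf)
    for (p1, p2), dg in params.stack_energies.items():
        stack44[base_idx[p1[0]], base_idx[p1[1]], base_idx[p2[0]], base_idx[p2[1]]] = dg
    S = np.full((n, m), np.inf)
    S[1:, 1:] = stack44[ai[:-1, None], ci[None, :-1], ai[1:, None], ci[None, 1:]]

    G = params.max_loop
    INF = np.inf
    D = np.full((n, m), INF)
    back = np.full((n, m, 2), -1, dtype=np.int64)  # predecessor pair, -1 = start

    loop_cost = np.full((G + 1, G + 1), INF)
    for gx in range(G + 1):
        for gy in range(G + 1):
            if gx == 0 and gy == 0:
                continue
            try:
                loop_cost[gx, gy] = params.loop_penalty(gx, gy)
            except KeyError:
                pass  # size not tabulated -> disallowed

    for i in range(n):
        row_ok = P[i]
        if not row_ok.any():
            continue
        best = np.full(m, params.duplex_init)
        prev_i = np.full(m, -1, dtype=np.int64)
        prev_j = np.full(m, -1, dtype=np.int64)
        if i >= 1:
            # stack extension from (i-1, j-1)
            cand = np.full(m, INF)
            cand[1:] = D[i - 1, :-1] + S[i, 1:]
            upd = cand < best
            best[upd] = cand[upd]
            prev_i[upd] = i - 1
            prev_j[upd] = np.arange(m)[upd] - 1
            # loop extensions from (i-1-gx, j-1-gy)
            for gx in range(G + 1):
                ip = i - 1 - gx
                if ip < 0:
                    break
                for gy in range(G + 1):
                    if gx == 0 and gy == 0:
                        continue
                    cost = loop_cost[gx, gy]
                    if not np.isfinite(cost):
                        continue
                    off = 1 + gy
                    cand = np.full(m, INF)
                    cand[off:] = D[ip, :-off] + cost
                    upd = cand < best
                    if upd.any():
                        best[upd] = cand[upd]
                        prev_i[upd] = ip
                        prev_j[upd] = np.arange(m)[upd] - off
        D[i] = np.where(row_ok, best, INF)
        back[i, :, 0] = np.where(row_ok, prev_i, -1)
        back[i, :, 1] = np.where(row_ok, prev_j, -1)

    if not np.isfinite(D).any() or D.min() >= 0:
        return DuplexResult(0.0, [], (0, 0), (0, 0))

    flat = int(np.argmin(D))
    bi, bj = divmod(flat, m)
    mfe = float(D[bi, bj])
    pairs_rev: list[tuple[int, int]] = []
    i, j = bi, bj
    while i >= 0:
        pairs_rev.append((i, j))
        i, j = int(back[i, j, 0]), int(back[i, j, 1])
    pairs = [(i, m - 1 - j) for i, j in reversed(pairs_rev)]  # back to site 5'->3'
    a_idx = [i for i, _ in pairs]
    b_idx = [j for _, j in pairs]
    return DuplexResult(
        round(mfe, 10),
        pairs,
        (min(a_idx), max(a_idx) + 1),
        (min(b_idx), max(b_idx) + 1),
    )


def filter_candidates(
    candidates: list, threshold: float = -20.0
) -> list:
    """Keep candidates whose duplex MFE is at or below ``threshold``.

    ``candidates`` is a sequence of objects carrying an ``mfe`` attribute,
    or (item, DuplexResult) tuples; input order is preserved.
    """
    if not np.isfinite(threshold) and threshold < 0:
        raise ValidationError("threshold must be finite or +inf")
    kept = []
    for cand in candidates:
        mfe = cand[1].mfe if isinstance(cand, tuple) else cand.mfe
        if mfe <= threshold:
            kept.append(cand)
    return kept
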