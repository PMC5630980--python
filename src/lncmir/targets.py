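"""miRNA target prediction under two filter profiles and their consensus.

Both profiles run on the module's own complementarity machinery (the
score scale is miRanda-like, the energy model a simplified
nearest-neighbor duplex model); the published thresholds are applied on
top:

* profile A — hybridization energy of the best site <= -25 kcal/mol;
* profile B — alignment score >= 140 AND energy <= -25 kcal/mol on the
  best-scoring site.

A miRNA-target pair is accepted ("consensus") only when reported by both
profiles; site coordinates need not agree, pair identity suffices.

The alignment model scores antiparallel complementarity: Watson-Crick
match +5, G:U wobble +2, mismatch -3, gap open -9, gap extend -4, with
all substitution scores multiplied by 4 at miRNA seed positions 2-8
(1-based, from the 5' end). The duplex energy model sums nearest-neighbor
stacking terms over consecutive pairs with a size-dependent penalty for
interior loops and bulges; it is <= 0 by construction and 0 when nothing
pairs.

A plant-style scanner (for cross-species screening against plant coding
sequences) scores a penalty expectation instead: mismatch 1.0, G:U 0.5,
indel 2.0, doubled within miRNA positions 2-13; a site is a hit when the
expectation is at or below the cutoff (default 3.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MIRNA_MIN, MIRNA_MAX = 18, 26

MATCH = 5.0
WOBBLE = 2.0
MISMATCH = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_START, SEED_END = 2, 8  # 1-based miRNA positions, inclusive
SEED_WEIGHT = 4.0

ENERGY_MAX_DEFAULT = -25.0
SCORE_MIN_DEFAULT = 140.0
PLANT_EXPECTATION_MAX = 3.0
PLANT_SEED_START, PLANT_SEED_END = 2, 13

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair categories: 0 none, 1 AU/UA, 2 CG/GC, 3 GU/UG
_PAIR_CAT = np.zeros((5, 5), dtype=np.int8)
for _a, _b, _c in (("A", "T", 1), ("C", "G", 2), ("G", "T", 3)):
    _PAIR_CAT[_CODE[_a], _CODE[_b]] = _c
    _PAIR_CAT[_CODE[_b], _CODE[_a]] = _c

# nearest-neighbor stacking energy (kcal/mol) by the categories of the two
# stacked pairs; simplified from standard RNA duplex parameter scales
_STACK_STRENGTH = {1: 1.1, 2: 2.0, 3: 0.5}
_STACK = np.zeros((4, 4), dtype=float)
for _p in (1, 2, 3):
    for _q in (1, 2, 3):
        _STACK[_p, _q] = -0.85 * (_STACK_STRENGTH[_p] + _STACK_STRENGTH[_q])

_LOOP_BASE = 3.0  # kcal/mol penalty opening an interior loop / bulge
_LOOP_PER_NT = 0.9
_MAX_LOOP = 6  # per-side unpaired bound inside a duplex


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in _dna(seq)), dtype=np.int8)


@dataclass(frozen=True)
class DuplexHit:
    mirna_id: str
    target_id: str
    target_class: str
    site_start: int  # 0-based half-open on the target
    site_end: int
    score: float
    energy: float
    profile: str  # A / B / both


@dataclass(frozen=True)
class ConsensusPair:
    mirna_id: str
    target_id: str
    target_class: str


# ---------------------------------------------------------------------------
# alignment score (profile-B style)
# ---------------------------------------------------------------------------

def _position_weights(n: int) -> np.ndarray:
    w = np.ones(n)
    w[SEED_START - 1 : SEED_END] = SEED_WEIGHT
    return w


def duplex_align(mirna: str, target_window: str) -> tuple[float, tuple[int, int]]:
    """Best local complementarity alignment of a miRNA against a target.

    Returns (score, (site_start, site_end)) with the site on the target in
    forward coordinates. The miRNA is aligned antiparallel to the target;
    ties resolve to the 5'-most site on the target. An empty overlap (no
    complementary positions) scores 0 with an empty site.
    """
    a = _encode(mirna)
    n = len(a)
    if not MIRNA_MIN <= n <= MIRNA_MAX:
        raise ValueError(f"miRNA length {n} outside [{MIRNA_MIN}, {MIRNA_MAX}]")
    t = _dna(target_window)
    m = len(t)
    if m < 6:
        raise ValueError("target window shorter than 6 nt")
    c = _encode(t[::-1])  # reversed target: consecutive indices stack
    weights = _position_weights(n)

    cat = _PAIR_CAT[a[:, None], c[None, :]]
    sub = np.where(cat == 2, MATCH, np.where(cat == 1, MATCH, np.where(cat == 3, WOBBLE, MISMATCH)))
    sub = sub * weights[:, None]

    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in target (miRNA advances)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in miRNA (target advances)
    for i in range(1, n + 1):
        E[i] = np.maximum(H[i - 1] + GAP_OPEN, E[i - 1] + GAP_EXTEND)
        row = H[i - 1, :-1] + sub[i - 1]
        # F needs a left-to-right scan; do it with a loop over j
        for j in range(1, m + 1):
            F[i, j] = max(H[i, j - 1] + GAP_OPEN, F[i, j - 1] + GAP_EXTEND)
            H[i, j] = max(0.0, row[j - 1], E[i, j], F[i, j])
    best = float(H.max())
    if best <= 0:
        return 0.0, (0, 0)
    # 5'-most site on the target = largest index in the reversed coordinate
    ii, jj = np.unravel_index(np.argmax(H[::-1, ::-1]), H.shape)
    i_end, j_end = n - ii, m - jj
    # walk back to the alignment start
    i, j = i_end, j_end
    state = "H"
    while i > 0 and j > 0 and H[i, j] > 0:
        if state == "H":
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                i, j = i - 1, j - 1
                continue
            break
        if state == "E":
            state = "H" if E[i, j] == H[i - 1, j] + GAP_OPEN else "E"
            i -= 1
            continue
        if state == "F":
            state = "H" if F[i, j] == H[i, j - 1] + GAP_OPEN else "F"
            j -= 1
            continue
    # reversed-coordinate span [j, j_end) -> forward target span
    start, end = m - j_end, m - j
    return best, (start, end)


# ---------------------------------------------------------------------------
# duplex energy (profile-A style)
# ---------------------------------------------------------------------------

def _energy_dp(a: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """E[i, j] = best duplex energy whose last pair is (a[i], c[j])."""
    n, m = len(a), len(c)
    cat = _PAIR_CAT[a[:, None], c[None, :]].astype(np.int64)
    E = np.full((n, m), np.inf)
    E[cat > 0] = 0.0  # a duplex may start at any pair
    for i in range(1, n):
        row_ok = cat[i] > 0
        if not row_ok.any():
            continue
        best = np.full(m, np.inf)
        for di in range(1, min(_MAX_LOOP + 2, i + 1)):
            prev = E[i - di]
            for dj in range(1, _MAX_LOOP + 2):
                cand = np.full(m, np.inf)
                if di == 1 and dj == 1:
                    # stack the previous pair (i-1, j-1) under the current one
                    cost = _STACK[cat[i - 1, :-1], cat[i, 1:]]
                    cand[1:] = prev[:-1] + cost
                elif di - 1 + dj - 1 <= _MAX_LOOP:
                    pen = _LOOP_BASE + _LOOP_PER_NT * (di - 1 + dj - 1)
                    cand[dj:] = prev[:-dj] + pen
                else:
                    continue
                best = np.minimum(best, cand)
        E[i] = np.where(row_ok, np.minimum(E[i], best), np.inf)
    return E, cat


def _duplex_best(mirna: str, target: str) -> tuple[float, tuple[int, int]]:
    """Minimum duplex energy and its site span on the target."""
    a = _encode(mirna)
    c = _encode(_dna(target)[::-1])
    if len(a) == 0 or len(c) == 0:
        raise ValueError("sequences must be nonempty")
    E, cat = _energy_dp(a, c)
    if not np.isfinite(E).any():
        return 0.0, (0, 0)
    best = float(E.min())
    if best >= 0:
        # an isolated pair has zero stacking energy: no meaningful duplex
        return 0.0, (0, 0)
    m = len(c)
    # 5'-most on target = largest reversed index; prefer it deterministically
    flat = np.where(np.isfinite(E), E, np.inf)[:, ::-1]
    i_last, jr = np.unravel_index(np.argmin(flat), flat.shape)
    j_last = m - 1 - jr
    # walk back through the DP to find the first pair of the duplex
    i, j = int(i_last), int(j_last)
    while True:
        e = E[i, j]
        if e == 0.0:
            break
        moved = False
        for di in range(1, min(_MAX_LOOP + 2, i + 1)):
            for dj in range(1, min(_MAX_LOOP + 2, j + 1)):
                if di == 1 and dj == 1:
                    cost = _STACK[cat[i - 1, j - 1], cat[i, j]]
                elif di - 1 + dj - 1 <= _MAX_LOOP:
                    cost = _LOOP_BASE + _LOOP_PER_NT * (di - 1 + dj - 1)
                else:
                    continue
                if np.isfinite(E[i - di, j - dj]) and np.isclose(
                    E[i - di, j - dj] + cost, e
                ):
                    i, j = i - di, j - dj
                    moved = True
                    break
            if moved:
                break
        if not moved:
            break
    j_first = j
    start, end = m - 1 - int(j_last), m - j_first
    return best, (start, end)


def duplex_energy(mirna: str, site_sequence: str) -> float:
    """Hybridization energy (kcal/mol, <= 0) of the best intermolecular
    duplex between a miRNA and a candidate site; 0 when nothing pairs."""
    return _duplex_best(mirna, site_sequence)[0]


# ---------------------------------------------------------------------------
# profile scans and consensus
# ---------------------------------------------------------------------------

def passes_profile_a(energy: float, mfe_max: float = ENERGY_MAX_DEFAULT) -> bool:
    return energy <= mfe_max


def passes_profile_b(
    score: float,
    energy: float,
    score_min: float = SCORE_MIN_DEFAULT,
    energy_max: float = ENERGY_MAX_DEFAULT,
) -> bool:
    return score >= score_min and energy <= energy_max


def scan_profile_a(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    target_class: str = "mRNA",
    mfe_max: float = ENERGY_MAX_DEFAULT,
) -> list[DuplexHit]:
    """Energy-gated hits: best-site duplex energy <= mfe_max."""
    if not targets:
        raise ValueError("empty target set")
    hits = []
    for mid, mseq in sorted(mirnas.items()):
        for tid, tseq in sorted(targets.items()):
            energy, site = _duplex_best(mseq, tseq)
            if passes_profile_a(energy, mfe_max):
                hits.append(
                    DuplexHit(mid, tid, target_class, site[0], site[1],
                              score=float("nan"), energy=energy, profile="A")
                )
    return hits


def scan_profile_b(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    target_class: str = "mRNA",
    score_min: float = SCORE_MIN_DEFAULT,
    energy_max: float = ENERGY_MAX_DEFAULT,
) -> list[DuplexHit]:
    """Score- and energy-gated hits; both gates apply to the best-scoring site."""
    if not targets:
        raise ValueError("empty target set")
    hits = []
    for mid, mseq in sorted(mirnas.items()):
        for tid, tseq in sorted(targets.items()):
            score, site = duplex_align(mseq, tseq)
            if score <= 0:
                continue
            energy = duplex_energy(mseq, tseq[site[0]:site[1]])
            if passes_profile_b(score, energy, score_min, energy_max):
                hits.append(
                    DuplexHit(mid, tid, target_class, site[0], site[1],
                              score=score, energy=energy, profile="B")
                )
    return hits


def consensus(hits_a: Iterable[DuplexHit], hits_b: Iterable[DuplexHit]) -> list[ConsensusPair]:
    """Pair-level intersection of two hit lists (deduplicated, sorted)."""
    def pairs(hits: Iterable[DuplexHit]) -> dict[tuple[str, str], str]:
        return {(h.mirna_id, h.target_id): h.target_class for h in hits}

    pa, pb = pairs(hits_a), pairs(hits_b)
    both = sorted(set(pa) & set(pb))
    return [ConsensusPair(m, t, pa[(m, t)]) for m, t in both]


# ---------------------------------------------------------------------------
# plant-mode (cross-species) scan
# ---------------------------------------------------------------------------

def _plant_dp(mirna: str, sequence: str) -> tuple[float, int]:
    """(best expectation, reversed-coordinate end index of the best site).

    Global in the miRNA (every miRNA base is matched, mismatched or
    charged as an indel), local in the target.
    """
    a = _encode(mirna)
    n = len(a)
    c = _encode(_dna(sequence)[::-1])
    m = len(c)
    scale = np.ones(n)
    scale[PLANT_SEED_START - 1 : PLANT_SEED_END] = 2.0
    cat = _PAIR_CAT[a[:, None], c[None, :]]
    sub = np.where(cat == 3, 0.5, np.where(cat > 0, 0.0, 1.0)) * scale[:, None]
    D = np.zeros((n + 1, m + 1))
    D[1:, 0] = np.cumsum(2.0 * scale)  # unmatched miRNA bases are indels
    for i in range(1, n + 1):
        indel = 2.0 * scale[i - 1]
        prev, cur = D[i - 1], D[i]
        cur[1:] = np.minimum(prev[:-1] + sub[i - 1], prev[1:] + indel)
        cur[0] = prev[0] + indel
        for j in range(1, m + 1):  # target-side indels need a serial pass
            if cur[j - 1] + indel < cur[j]:
                cur[j] = cur[j - 1] + indel
    j_best = int(np.argmin(D[n]))
    return float(D[n, j_best]), j_best


def plant_expectation(mirna: str, site_sequence: str) -> float:
    """Penalty expectation of a miRNA against one candidate plant site.

    Mismatch 1.0, G:U 0.5, indel 2.0, all doubled within miRNA positions
    2-13 (5' end, 1-based); 0 for a perfect complement.
    """
    return _plant_dp(mirna, site_sequence)[0]


def plant_mode_scan(
    mirnas: Mapping[str, str],
    plant_cds: Mapping[str, str],
    expectation_max: float = PLANT_EXPECTATION_MAX,
) -> list[DuplexHit]:
    """Plant-style complementarity screen over coding sequences.

    A target is a hit when its best site's expectation is at or below the
    cutoff; the reported site span is the aligned region of the best site.
    """
    hits = []
    for mid, mseq in sorted(mirnas.items()):
        n = len(mseq)
        for tid, tseq in sorted(plant_cds.items()):
            best, j_end = _plant_dp(mseq, tseq)
            if best <= expectation_max:
                m = len(tseq)
                start = max(0, m - j_end)
                hits.append(
                    DuplexHit(mid, tid, "plant-mRNA", start,
                              min(start + n, m),
                              score=best, energy=0.0, profile="plant")
                )
    return hits


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

HITS_COLUMNS = [
    "mirna", "target", "class", "site_start", "site_end", "score", "energy", "profile",
]


def hits_to_frame(hits: Sequence[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": h.mirna_id, "target": h.target_id, "class": h.target_class,
                "site_start": h.site_start, "site_end": h.site_end,
                "score": h.score, "energy": h.energy, "profile": h.profile,
            }
            for h in hits
        ],
        columns=HITS_COLUMNS,
    )


def frame_to_hits(df: pd.DataFrame) -> list[DuplexHit]:
    return [
        DuplexHit(
            str(row["mirna"]), str(row["target"]), str(row["class"]),
            int(row["site_start"]), int(row["site_end"]),
            float(row["score"]), float(row["energy"]), str(row["profile"]),
        )
        for _, row in df.iterrows()
    ]


def consensus_to_frame(pairs: Sequence[ConsensusPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna": p.mirna_id, "target": p.target_id, "class": p.target_class} for p in pairs],
        columns=["mirna", "target", "class"],
    )
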