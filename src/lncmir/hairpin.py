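"""Homology-guided miRNA discovery with hairpin-structure validation.

Candidate mature miRNAs are found by scanning transcripts (both strands)
for occurrences of reference matures within a Hamming distance of 1.
Each hit is extended into a ladder of precursor windows, folded, and the
resulting stem-loop is validated against four criteria:

  c1  at most 4 unpaired positions within the mature and 6 within the
      star span (bulges count per unpaired position);
  c2  the first and last base of both mature and star are paired
      (Dicer-like cut sites sit at the duplex ends);
  c3  no multi-loop between mature and star: exactly one hairpin loop
      lies between the two arms;
  c4  neither mature nor star reaches the head of the hairpin (the
      terminal loop plus its closing pair).

MFE, AMFE (= MFE/length*100) and MFEI (= AMFE/GC%) are computed on every
precursor; thresholds on them are reported but not enforced by default.

Folding is an engine interface. The bundled default is a deterministic
maximum-weighted-pairing folder (AU/GU weight 1, GC weight 2, minimum
loop 3, traceback preferring 5'-most pairs); a thermodynamic engine
(ViennaRNA) can be selected when its Python bindings are installed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import expression

MATURE_MIN, MATURE_MAX = 21, 23
REFERENCE_MIN, REFERENCE_MAX = 18, 26
STAR_OVERHANG = 2  # nt of 3' overhang carried by the reported star sequence

SENSE, ANTISENSE = "sense", "antisense"

MAX_MATURE_MISMATCH = 4
MAX_STAR_MISMATCH = 6

CRITERION_VIOLATIONS = {
    "c1": "mismatch_budget",
    "c2": "cut_site",
    "c3": "multiloop",
    "c4": "loop_overlap",
}

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair weights for the bundled folder: AU=1, GC=2, GU=1 (wobble)
_PAIR_W = np.zeros((5, 5), dtype=np.int32)
for _a, _b, _w in (("A", "T", 1), ("C", "G", 2), ("G", "T", 1)):
    _PAIR_W[_CODE[_a], _CODE[_b]] = _w
    _PAIR_W[_CODE[_b], _CODE[_a]] = _w

_MIN_LOOP = 3


def revcomp(seq: str) -> str:
    out = seq.upper().translate(_COMPLEMENT)[::-1]
    return out


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in _dna(seq)), dtype=np.int8)


def parse_mirbase_name(header: str) -> tuple[str, str]:
    """(name, family) from a miRBase-style mature name.

    'cci-miR-281-2-5p' -> family 'miR-281'; 'dme-bantam-3p' -> 'bantam'.
    The leading species code and trailing arm/variant suffixes are dropped.
    """
    name = header.split()[0]
    body = re.sub(r"^[a-z]{3,4}-", "", name)
    body = re.sub(r"-(5p|3p)$", "", body)  # arm suffix is not family
    m = re.match(r"([A-Za-z]+-?\d*)", body)
    family = m.group(1).rstrip("-") if m else body
    return name, family


# ---------------------------------------------------------------------------
# mature scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureHit:
    transcript_id: str
    strand: str  # sense / antisense
    start: int  # 0-based, forward transcript coordinates
    mature: str  # reference mature sequence (DNA alphabet)
    ref_name: str
    family: str
    mismatches: int


def scan_mature(
    transcripts: Mapping[str, str],
    reference_matures: Mapping[str, str],
    max_mismatch: int = 1,
) -> list[MatureHit]:
    """All Hamming-distance <= max_mismatch occurrences on both strands.

    An antisense hit is an occurrence of the reverse complement of the
    reference mature on the transcript's forward strand. U and T are
    treated as equivalent.
    """
    if not reference_matures:
        raise ValueError("empty reference mature set")
    refs: list[tuple[str, str, str]] = []
    for ref_name, seq in reference_matures.items():
        seq = _dna(seq)
        if not REFERENCE_MIN <= len(seq) <= REFERENCE_MAX:
            raise ValueError(
                f"reference mature {ref_name!r} length {len(seq)} outside "
                f"[{REFERENCE_MIN}, {REFERENCE_MAX}]"
            )
        name, family = parse_mirbase_name(ref_name)
        refs.append((name, family, seq))

    hits: list[MatureHit] = []
    for tid, tseq in transcripts.items():
        enc = _encode(tseq)
        views: dict[int, np.ndarray] = {}
        for name, family, seq in refs:
            L = len(seq)
            if L > len(enc):
                continue
            if L not in views:
                views[L] = np.lib.stride_tricks.sliding_window_view(enc, L)
            win = views[L]
            for strand, pattern in ((SENSE, seq), (ANTISENSE, revcomp(seq))):
                mm = (win != _encode(pattern)[None, :]).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    hits.append(
                        MatureHit(
                            transcript_id=tid,
                            strand=strand,
                            start=int(pos),
                            mature=seq,
                            ref_name=name,
                            family=family,
                            mismatches=int(mm[pos]),
                        )
                    )
    hits.sort(key=lambda h: (h.ref_name, h.transcript_id, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# precursor windows
# ---------------------------------------------------------------------------

DEFAULT_FLANKS = tuple(range(10, 111, 10))


@dataclass
class HairpinCandidate:
    transcript_id: str
    strand: str
    window_start: int  # forward transcript coordinates
    window_end: int
    sequence: str  # precursor on the hit strand, 5'->3'
    mature_offset: int  # 0-based offset of the mature within `sequence`
    mature_len: int
    structure: str | None = None
    mfe: float | None = None

    @property
    def mature_span(self) -> tuple[int, int]:
        return self.mature_offset, self.mature_offset + self.mature_len


def extract_precursors(
    hit: MatureHit,
    transcript_seq: str,
    flanks: Sequence[int] = DEFAULT_FLANKS,
    min_extra: int = 15,
) -> list[HairpinCandidate]:
    """Nested precursor windows extending the mature on both sides.

    Windows are clipped at the transcript ends (never rejected for
    clipping) and must retain at least `min_extra` nt beyond the mature.
    For antisense hits the window is reverse-complemented so the candidate
    sequence always carries the mature on its own strand.
    """
    tseq = _dna(transcript_seq)
    n = len(tseq)
    mlen = len(hit.mature)
    if not (0 <= hit.start and hit.start + mlen <= n):
        raise ValueError("mature hit outside transcript bounds")
    out: list[HairpinCandidate] = []
    seen: set[tuple[int, int]] = set()
    for f in flanks:
        ws = max(0, hit.start - f)
        we = min(n, hit.start + mlen + f)
        if (ws, we) in seen:
            continue
        seen.add((ws, we))
        if we - ws < mlen + min_extra:
            continue
        window = tseq[ws:we]
        if hit.strand == SENSE:
            seq, offset = window, hit.start - ws
        else:
            seq, offset = revcomp(window), we - (hit.start + mlen)
        out.append(
            HairpinCandidate(
                transcript_id=hit.transcript_id,
                strand=hit.strand,
                window_start=ws,
                window_end=we,
                sequence=seq,
                mature_offset=offset,
                mature_len=mlen,
            )
        )
    return out


# ---------------------------------------------------------------------------
# folding engines
# ---------------------------------------------------------------------------

def _fill_pairing(codes: np.ndarray, pair_w: np.ndarray) -> np.ndarray:
    """Maximum-weighted-pairing DP table (Nussinov-style)."""
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            w = pair_w[codes[i], codes[j]]
            if w > 0 and M[i + 1, j - 1] + w > best:
                best = M[i + 1, j - 1] + w
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M


try:  # numba shaves the O(n^3) fill down to milliseconds when present
    from numba import njit

    _fill_pairing_fast = njit(cache=False)(_fill_pairing)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _fill_pairing_fast = _fill_pairing


def _traceback(codes: np.ndarray, M: np.ndarray, pair_w: np.ndarray) -> list[int]:
    """Deterministic traceback preferring pairing (i, j), then 5'-most moves."""
    n = codes.shape[0]
    pt = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_LOOP:
            continue
        w = pair_w[codes[i], codes[j]]
        if w > 0 and M[i, j] == M[i + 1, j - 1] + w:
            pt[i], pt[j] = j, i
            stack.append((i + 1, j - 1))
            continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if M[i, k] + M[k + 1, j] == M[i, j]:
                stack.append((k + 1, j))
                stack.append((i, k))
                break
    return pt


def pair_table(structure: str) -> list[int]:
    """Dot-bracket -> partner index per position (-1 for unpaired)."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def fold(sequence: str, engine: str = "builtin") -> tuple[str, float]:
    """Fold a sequence into (dot-bracket, MFE <= 0).

    engine='builtin' uses the bundled deterministic maximum-pairing folder
    (its "energy" is the negated pairing weight); engine='vienna' calls the
    ViennaRNA thermodynamic model when its Python bindings are available.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    if engine == "vienna":
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("ViennaRNA Python bindings not installed") from exc
        structure, mfe = RNA.fold(_dna(sequence).replace("T", "U"))
        return structure, float(mfe)
    if engine != "builtin":
        raise ValueError(f"unknown folding engine {engine!r}")
    codes = _encode(sequence)
    if len(codes) < 2:
        return "." * len(codes), 0.0
    M = _fill_pairing_fast(codes, _PAIR_W)
    pt = _traceback(codes, M, _PAIR_W)
    structure = "".join(
        "(" if (p := pt[i]) > i else ")" if 0 <= p < i else "." for i in range(len(pt))
    )
    return structure, -float(M[0, len(codes) - 1])


def fold_candidate(candidate: HairpinCandidate, engine: str = "builtin") -> HairpinCandidate:
    structure, mfe = fold(candidate.sequence, engine=engine)
    return replace(candidate, structure=structure, mfe=mfe)


# ---------------------------------------------------------------------------
# star inference and evaluation
# ---------------------------------------------------------------------------

@dataclass
class StarSpan:
    core: tuple[int, int]  # duplex-facing span (no overhang)
    reported: tuple[int, int]  # core plus the 2-nt 3' overhang, clipped


def infer_star(pt: Sequence[int], mature_span: tuple[int, int], n: int) -> StarSpan | None:
    """Star span from the positions pairing with the mature.

    The core span mirrors the full mature span through the median pairing
    diagonal (so bulge-shifted duplexes stay aligned); the reported span
    appends the conventional 2-nt 3' overhang. Returns None when the
    mature is entirely unpaired or pairs into itself.
    """
    ms, me = mature_span
    partners = [pt[i] for i in range(ms, me) if pt[i] >= 0 and not ms <= pt[i] < me]
    if not partners:
        return None
    diag = [i + pt[i] for i in range(ms, me) if pt[i] >= 0 and not ms <= pt[i] < me]
    d = int(round(float(np.median(diag))))
    lo, hi = d - (me - 1), d - ms + 1
    lo, hi = max(0, lo), min(n, hi)
    if hi <= lo:
        return None
    if not (hi <= ms or lo >= me):
        # star overlapping the mature: no separable duplex
        return None
    reported = (lo, min(hi + STAR_OVERHANG, n))
    return StarSpan(core=(lo, hi), reported=reported)


@dataclass
class HairpinEvaluation:
    c1_mismatch_budget: bool
    c2_cut_sites: bool
    c3_no_multiloop: bool
    c4_not_in_loop: bool
    mature_mismatches: int
    star_mismatches: int
    mfe: float
    amfe: float
    mfei: float
    gc: float
    star: StarSpan | None
    verdict: bool

    @property
    def failed_criteria(self) -> list[str]:
        return [
            name
            for name, ok in zip(
                ("c1", "c2", "c3", "c4"),
                (
                    self.c1_mismatch_budget,
                    self.c2_cut_sites,
                    self.c3_no_multiloop,
                    self.c4_not_in_loop,
                ),
            )
            if not ok
        ]


def mfei(mfe: float, length_nt: int, gc_percent: float) -> tuple[float, float]:
    """AMFE = MFE/length*100; MFEI = AMFE/GC%."""
    if length_nt <= 0:
        raise ValueError("length must be positive")
    if gc_percent <= 0 or gc_percent > 100:
        raise ValueError("GC percent must be in (0, 100]")
    amfe = mfe / length_nt * 100.0
    return amfe, amfe / gc_percent


def _hairpin_loops(pt: Sequence[int]) -> list[tuple[int, int]]:
    """Closing pairs (i, j) of hairpin loops: no paired position inside."""
    loops = []
    for i, j in ((i, pt[i]) for i in range(len(pt)) if pt[i] > i):
        if all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def evaluate_hairpin(
    candidate: HairpinCandidate,
    cut_site_width: int = 1,
    mfei_max: float | None = None,
    gc_window: tuple[float, float] | None = None,
) -> HairpinEvaluation:
    """Validate a folded precursor window against the four criteria.

    MFEI/GC gates are report-only unless `mfei_max` / `gc_window` are set.
    """
    if candidate.structure is None or candidate.mfe is None:
        raise ValueError("candidate must be folded before evaluation")
    seq = candidate.sequence
    pt = pair_table(candidate.structure)
    if len(pt) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    n = len(seq)
    ms, me = candidate.mature_span
    gc = 100.0 * sum(seq.count(b) for b in "GC") / n
    amfe, mfei_val = mfei(candidate.mfe, n, gc) if gc > 0 else (0.0, 0.0)

    star = infer_star(pt, (ms, me), n)
    if star is None:
        return HairpinEvaluation(
            False, False, False, False, me - ms, 0, candidate.mfe, amfe, mfei_val,
            gc, None, False,
        )
    slo, shi = star.core

    def in_star(p: int) -> bool:
        return slo <= p < shi

    def in_mature(p: int) -> bool:
        return ms <= p < me

    mature_mm = sum(1 for i in range(ms, me) if not (pt[i] >= 0 and in_star(pt[i])))
    star_mm = sum(1 for j in range(slo, shi) if not (pt[j] >= 0 and in_mature(pt[j])))
    c1 = mature_mm <= MAX_MATURE_MISMATCH and star_mm <= MAX_STAR_MISMATCH

    w = cut_site_width
    mature_ends = list(range(ms, min(ms + w, me))) + list(range(max(me - w, ms), me))
    star_ends = list(range(slo, min(slo + w, shi))) + list(range(max(shi - w, slo), shi))
    c2 = all(pt[i] >= 0 and in_star(pt[i]) for i in mature_ends) and all(
        pt[j] >= 0 and in_mature(pt[j]) for j in star_ends
    )

    env_lo, env_hi = min(ms, slo), max(me, shi)
    loops = [(i, j) for i, j in _hairpin_loops(pt) if i >= env_lo and j < env_hi]
    c3 = len(loops) == 1

    # head region = terminal loop including its closing pair
    c4 = True
    for i, j in loops:
        if not (j < ms or i >= me) or not (j < slo or i >= shi):
            c4 = False

    verdict = c1 and c2 and c3 and c4
    if mfei_max is not None:
        verdict = verdict and mfei_val <= mfei_max
    if gc_window is not None:
        verdict = verdict and gc_window[0] <= gc <= gc_window[1]
    return HairpinEvaluation(
        c1, c2, c3, c4, mature_mm, star_mm, candidate.mfe, amfe, mfei_val, gc,
        star, verdict,
    )


# ---------------------------------------------------------------------------
# discovery pipeline
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryConfig:
    max_mismatch: int = 1
    flanks: Sequence[int] = DEFAULT_FLANKS
    cut_site_width: int = 1
    mfei_max: float | None = None
    gc_window: tuple[float, float] | None = None
    engine: str = "builtin"


@dataclass
class DiscoveryResult:
    table: pd.DataFrame  # one row per (mature, transcript, strand) hit
    accepted_matures: set[str] = field(default_factory=set)
    attribution: dict[str, frozenset] = field(default_factory=dict)


def evaluate_hit(
    hit: MatureHit,
    transcript_seq: str,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> tuple[bool, HairpinCandidate | None, HairpinEvaluation | None]:
    """Extract/fold/evaluate all windows for one hit; pick the best window.

    Among passing windows: lowest MFEI, ties to the shortest precursor,
    then the 5'-most window. A hit with no passing window reports its most
    nearly passing window (fewest failed criteria, same tie-breaks).
    """
    candidates = extract_precursors(hit, transcript_seq, flanks=config.flanks)
    scored = []
    for cand in candidates:
        cand = fold_candidate(cand, engine=config.engine)
        ev = evaluate_hairpin(
            cand,
            cut_site_width=config.cut_site_width,
            mfei_max=config.mfei_max,
            gc_window=config.gc_window,
        )
        scored.append((cand, ev))
    if not scored:
        return False, None, None
    scored.sort(
        key=lambda ce: (
            len(ce[1].failed_criteria),
            not ce[1].verdict,
            ce[1].mfei,
            len(ce[0].sequence),
            ce[0].window_start,
        )
    )
    best_cand, best_ev = scored[0]
    return best_ev.verdict, best_cand, best_ev


def discover(
    transcripts: Mapping[str, str],
    reference_matures: Mapping[str, str],
    config: DiscoveryConfig = DiscoveryConfig(),
    fpkm: pd.DataFrame | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> DiscoveryResult:
    """scan -> extract -> fold -> evaluate over a transcript set.

    A mature is reported as discovered when at least one of its hits has a
    passing precursor window. When an FPKM matrix and sample groups are
    given, each accepted mature is attributed to the sample groups in
    which any of its precursor transcripts is actively expressed.
    """
    hits = scan_mature(transcripts, reference_matures, config.max_mismatch)
    rows = []
    accepted: set[str] = set()
    precursors: dict[str, set[str]] = {}
    for hit in hits:
        ok, cand, ev = evaluate_hit(hit, transcripts[hit.transcript_id], config)
        if cand is None or ev is None:
            continue
        if ok:
            accepted.add(hit.ref_name)
            precursors.setdefault(hit.ref_name, set()).add(hit.transcript_id)
        rows.append(
            {
                "mature": hit.ref_name,
                "family": hit.family,
                "transcript_id": hit.transcript_id,
                "strand": hit.strand,
                "mature_start": hit.start,
                "scan_mismatches": hit.mismatches,
                "precursor_start": cand.window_start,
                "precursor_end": cand.window_end,
                "precursor_len": len(cand.sequence),
                "mature_mismatches": ev.mature_mismatches,
                "star_mismatches": ev.star_mismatches,
                "mfe": ev.mfe,
                "amfe": ev.amfe,
                "mfei": ev.mfei,
                "gc": ev.gc,
                "c1": ev.c1_mismatch_budget,
                "c2": ev.c2_cut_sites,
                "c3": ev.c3_no_multiloop,
                "c4": ev.c4_not_in_loop,
                "accepted": ok,
                "failed_criteria": ",".join(ev.failed_criteria),
            }
        )
    table = pd.DataFrame(rows)
    attribution: dict[str, frozenset] = {}
    if fpkm is not None and groups is not None and accepted:
        _, patterns = expression.sample_specific_sets(fpkm, groups)
        for mature in accepted:
            pat: set[str] = set()
            for tid in precursors.get(mature, ()):  # union over precursors
                pat |= patterns.get(tid, frozenset())
            attribution[mature] = frozenset(pat)
    return DiscoveryResult(table=table, accepted_matures=accepted, attribution=attribution)


def precursor_fasta(result: DiscoveryResult, transcripts: Mapping[str, str]) -> dict[str, str]:
    """Pre-miRNA sequences of accepted hits, keyed mature@transcript:span."""
    out = {}
    if result.table.empty:
        return out
    for row in result.table[result.table["accepted"]].itertuples(index=False):
        window = _dna(transcripts[row.transcript_id])[row.precursor_start : row.precursor_end]
        if row.strand == ANTISENSE:
            window = revcomp(window)
        key = f"{row.mature}@{row.transcript_id}:{row.precursor_start}-{row.precursor_end}({row.strand})"
        out[key] = window
    return out
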