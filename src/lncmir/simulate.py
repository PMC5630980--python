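"""Synthetic transcriptomes with planted ground truth.

Everything downstream of read assembly is emulated here so the whole
pipeline is testable without any download: a multi-isoform transcriptome
(Trinity-style `cNN_gG_iK` ids, all transcripts > 200 bp), planted ORFs
and annotation evidence consistent with an assigned transcript class,
planted pre-miRNA hairpins that satisfy — or violate exactly one of — the
four validation criteria, and an eight-sample negative-binomial count
matrix with known differential-expression structure between a larva group
and adult groups.

Class labels and DE status are assigned (exact counts), never sampled, so
requested proportions are matched exactly. A fixed seed makes every
output byte-identical across runs.

Hairpin planting builds an inverted repeat (mature + spacer + loop +
reverse-complemented spacer and mature) rather than searching random
sequence, then verifies the design against the discovery evaluator and
retries with fresh random choices until the designed outcome holds — a
planted violation must fail exactly its designed criterion and nothing
else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify, expression, hairpin, report

VIOLATIONS = ("none", "mismatch_budget", "cut_site", "multiloop", "loop_overlap")

DEFAULT_GROUPS = {
    "larva": ("s1", "s2"),
    "male": ("s3", "s4"),
    "female": ("s5", "s6"),
    "other": ("s7", "s8"),
}
ADULT_GROUPS = ("male", "female", "other")

DEFAULT_CLASS_FRACTIONS = {
    "mRNA": 0.30,
    "lncRNA": 0.50,
    "unknown": 0.15,
    "contaminant": 0.05,
}

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# the six mixed criterion patterns (orf, coding, homology) -> class unknown
_UNKNOWN_PATTERNS = [
    (True, False, False), (False, True, False), (False, False, True),
    (True, True, False), (True, False, True), (False, True, True),
]


@dataclass
class SimConfig:
    n_genes: int = 200
    isoforms_per_gene: tuple = ("geometric", 0.6, 6)  # or ("fixed", k)
    length_dist: tuple = ("lognormal", 6.6, 0.6, 201, 8000)  # mu, sigma, min, max
    gc_target: float = 0.41
    n_samples: int = 8
    groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {g: list(s) for g, s in DEFAULT_GROUPS.items()}
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    de_fraction: float = 0.10
    true_log2fc: float = 3.0
    dispersion: float = 0.05  # NB overdispersion (BCV ~ 0.22)
    depth_mean: float = 100.0  # mean baseline expected count per transcript
    silenced_fraction: float = 0.05
    n_planted_hairpins: int = 10
    planted_violations: Sequence[str] | None = None  # defaults to all "none"
    antisense_fraction: float = 0.4
    n_planted_orfs: int | None = None  # defaults to the mRNA-class count
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("de_fraction", "gc_target", "silenced_fraction", "antisense_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        kind = self.length_dist[0]
        if kind == "fixed" and self.length_dist[1] <= 200:
            raise ValueError("length distribution must only admit lengths > 200 bp")
        if kind == "uniform" and self.length_dist[1] <= 200:
            raise ValueError("length distribution must only admit lengths > 200 bp")
        if kind == "lognormal" and self.length_dist[3] <= 200:
            raise ValueError("length distribution must only admit lengths > 200 bp")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.planted_violations is not None:
            if len(self.planted_violations) != self.n_planted_hairpins:
                raise ValueError("one violation label per planted hairpin required")
            bad = set(self.planted_violations) - set(VIOLATIONS)
            if bad:
                raise ValueError(f"unknown violation labels: {sorted(bad)}")
        listed = [s for ss in self.groups.values() for s in ss]
        if len(listed) != self.n_samples:
            raise ValueError("groups must cover exactly n_samples samples")


@dataclass
class HairpinLocus:
    transcript_id: str
    strand: str  # sense / antisense
    mature_name: str
    mature_start: int  # forward transcript coordinates
    mature_end: int
    violation: str


@dataclass
class GroundTruth:
    classes: dict[str, str] = field(default_factory=dict)
    criterion_patterns: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)
    de_direction: dict[str, str] = field(default_factory=dict)  # up_in_larva / up_in_adult
    silenced: set[str] = field(default_factory=set)
    hairpins: list[HairpinLocus] = field(default_factory=list)
    orf_lengths: dict[str, int] = field(default_factory=dict)  # planted, aa

    def to_json(self) -> str:
        obj = {
            "classes": self.classes,
            "criterion_patterns": {k: list(v) for k, v in self.criterion_patterns.items()},
            "de_direction": self.de_direction,
            "silenced": sorted(self.silenced),
            "hairpins": [asdict(h) for h in self.hairpins],
            "orf_lengths": self.orf_lengths,
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            classes=obj["classes"],
            criterion_patterns={
                k: tuple(v) for k, v in obj["criterion_patterns"].items()
            },
            de_direction=obj["de_direction"],
            silenced=set(obj["silenced"]),
            hairpins=[HairpinLocus(**h) for h in obj["hairpins"]],
            orf_lengths={k: int(v) for k, v in obj["orf_lengths"].items()},
        )


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _draw_length(rng: np.random.Generator, dist: tuple, floor: int = 201) -> int:
    kind = dist[0]
    if kind == "fixed":
        return int(dist[1])
    if kind == "uniform":
        lo, hi = int(dist[1]), int(dist[2])
        return int(rng.integers(max(lo, floor), hi + 1))
    if kind == "lognormal":
        mu, sigma, lo, hi = dist[1], dist[2], int(dist[3]), int(dist[4])
        lo = max(lo, floor)
        for _ in range(1000):
            val = int(rng.lognormal(mu, sigma))
            if lo <= val <= hi:
                return val
        return lo
    raise ValueError(f"unknown length distribution {kind!r}")


def _draw_isoform_count(rng: np.random.Generator, dist: tuple) -> int:
    if dist[0] == "fixed":
        return int(dist[1])
    if dist[0] == "geometric":
        p, cap = float(dist[1]), int(dist[2])
        return int(min(rng.geometric(p), cap))
    raise ValueError(f"unknown isoform distribution {dist[0]!r}")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        codon = "".join(_BASES[rng.integers(0, 4, size=3)])
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _plant_orf(seq: str, aa: int, rng: np.random.Generator) -> str:
    """Overwrite a random slice with an ATG + (aa-1) sense codons + stop."""
    orf = "ATG" + _random_codons(rng, aa - 1) + "TAA"
    if len(orf) > len(seq):
        raise ValueError("transcript too short for the requested ORF")
    pos = int(rng.integers(0, len(seq) - len(orf) + 1))
    return seq[:pos] + orf + seq[pos + len(orf):]


def _break_long_orfs(seq: str, max_aa: int = classify.ORF_MIN_AA) -> str:
    """Insert in-frame stops until no ORF longer than `max_aa` remains."""
    for _ in range(200):
        orf = classify.find_longest_orf(seq)
        if orf.length_aa <= max_aa:
            return seq
        mid_codon = orf.length_aa // 2
        if orf.strand == "+":
            pos = orf.start + 3 * mid_codon
            seq = seq[:pos] + "TAA" + seq[pos + 3:]
        else:
            pos = orf.end - 3 * (mid_codon + 1)
            seq = seq[:pos] + "TTA" + seq[pos + 3:]  # revcomp of TAA
    raise RuntimeError("could not break ORFs")  # pragma: no cover


# ---------------------------------------------------------------------------
# hairpin planting
# ---------------------------------------------------------------------------

def _choose_unpairable(mature: str, pos: int, rng: np.random.Generator) -> str:
    """A base for the star that cannot pair with mature[pos-1..pos+1]."""
    partners = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}
    context = set(mature[max(0, pos - 1): pos + 2])
    safe = [b for b in "ACGT" if not (partners[b] & context)]
    pool = safe if safe else [mature[pos]]  # self-identical base never pairs itself
    return pool[int(rng.integers(0, len(pool)))]


def _build_construct(mature: str, violation: str, rng: np.random.Generator) -> tuple[str, int]:
    """(construct sequence, mature offset within construct)."""
    spacer = _random_seq(rng, 5, 0.5)
    loop = "A" * int(rng.integers(6, 10))
    star = hairpin.revcomp(mature)
    if violation == "none":
        return mature + spacer + loop + hairpin.revcomp(spacer) + star, 0
    if violation == "loop_overlap":
        # no spacer duplex: the mature's last pair closes the terminal loop
        return mature + loop + star, 0
    if violation == "cut_site":
        star = star[:-1] + _choose_unpairable(mature, 0, rng)
        return mature + spacer + loop + hairpin.revcomp(spacer) + star, 0
    if violation == "mismatch_budget":
        interior = list(range(3, len(mature) - 3))
        rng.shuffle(interior)
        chosen: list[int] = []
        for p in interior:
            if all(abs(p - q) >= 2 for q in chosen):
                chosen.append(p)
            if len(chosen) == 5:
                break
        s = list(star)
        for p in chosen:
            s[len(star) - 1 - p] = _choose_unpairable(mature, p, rng)
        return mature + spacer + loop + hairpin.revcomp(spacer) + "".join(s), 0
    if violation == "multiloop":
        # two branch stems between the arms -> a genuine multi-loop
        def branch() -> str:
            b = _random_seq(rng, 7, 0.6)
            return b + "A" * 4 + hairpin.revcomp(b)
        inner = "AAA" + branch() + "AAA" + branch() + "AAA"
        return mature + spacer + inner + hairpin.revcomp(spacer) + star, 0
    raise ValueError(f"unknown violation label {violation!r}")


def plant_hairpin(
    transcript: str,
    mature: str,
    violation: str = "none",
    seed: int = 0,
    mature_name: str = "planted",
    antisense: bool = False,
    insert_at: int | None = None,
    max_tries: int = 30,
    config: hairpin.DiscoveryConfig | None = None,
) -> tuple[str, HairpinLocus]:
    """Insert a pre-miRNA construct into a transcript and verify the design.

    The construct replaces a same-length slice of the transcript (so the
    transcript length is unchanged). After insertion the planted locus is
    evaluated with the discovery machinery: a `violation='none'` construct
    must pass all four criteria in at least one precursor window; any other
    label must be rejected with exactly that criterion failing in the best
    window. The build is retried with fresh random choices until the
    designed outcome holds.
    """
    if not hairpin.MATURE_MIN <= len(mature) <= hairpin.MATURE_MAX:
        raise ValueError(f"mature length {len(mature)} outside [21, 23]")
    if violation not in VIOLATIONS:
        raise ValueError(f"unknown violation label {violation!r}")
    mature = mature.upper().replace("U", "T")
    rng = np.random.default_rng(seed)
    cfg = config or hairpin.DiscoveryConfig()
    last_err = "no attempt"
    for _ in range(max_tries):
        construct, moff = _build_construct(mature, violation, rng)
        if len(transcript) < len(construct) + 10:
            raise ValueError("transcript too short to host a hairpin window")
        if insert_at is None:
            pos = int(rng.integers(5, len(transcript) - len(construct) - 5))
        else:
            pos = insert_at
        piece = hairpin.revcomp(construct) if antisense else construct
        seq = transcript[:pos] + piece + transcript[pos + len(piece):]
        if antisense:
            m_start = pos + len(construct) - moff - len(mature)
            strand = hairpin.ANTISENSE
        else:
            m_start = pos + moff
            strand = hairpin.SENSE
        # verify the whole discovery outcome on this transcript: the scan
        # also picks up the star arm as an opposite-strand hit, and a
        # violation must be rejected through every such path
        scan_hits = hairpin.scan_mature(
            {"_planted": seq}, {mature_name: mature}, cfg.max_mismatch
        )
        outcomes = [hairpin.evaluate_hit(h, seq, cfg) for h in scan_hits]
        outcomes = [(ok, ev) for ok, _, ev in outcomes if ev is not None]
        if not outcomes:
            last_err = "mature not rediscovered after insertion"
            continue
        if violation == "none":
            designed = any(ok for ok, _ in outcomes)
            last_err = "no window passed for a violation-free construct"
        else:
            crit = next(
                k for k, v in hairpin.CRITERION_VIOLATIONS.items() if v == violation
            )
            fails = [set(ev.failed_criteria) for _, ev in outcomes]
            designed = (
                not any(ok for ok, _ in outcomes)
                and all(crit in f for f in fails)
                and any(f == {crit} for f in fails)
            )
            last_err = f"wanted only {{{crit}}} across hits, got {fails}"
        if designed:
            locus = HairpinLocus(
                transcript_id="", strand=strand, mature_name=mature_name,
                mature_start=m_start, mature_end=m_start + len(mature),
                violation=violation,
            )
            return seq, locus
    raise RuntimeError(
        f"could not plant a {violation!r} hairpin in {max_tries} tries ({last_err})"
    )


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _assign_exact(n: int, fractions: Mapping[str, float], rng: np.random.Generator) -> list[str]:
    """Largest-remainder assignment of exactly n labels, then shuffled."""
    labels = sorted(fractions)
    raw = {lbl: n * fractions[lbl] for lbl in labels}
    counts = {lbl: int(raw[lbl]) for lbl in labels}
    short = n - sum(counts.values())
    for lbl in sorted(labels, key=lambda l: raw[l] - counts[l], reverse=True)[:short]:
        counts[lbl] += 1
    out = [lbl for lbl in labels for _ in range(counts[lbl])]
    rng.shuffle(out)
    return out


def generate_transcriptome(config: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Generate the transcript FASTA content plus its ground truth.

    Transcript ids follow the `cNN_gG_iK` convention; classes and mixed
    criterion patterns are assigned exactly; mRNA-class transcripts carry a
    planted ORF > 100 aa while every other class has its open reading
    frames broken below the criterion; hairpins are planted last and
    verified (see `plant_hairpin`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # gene/isoform layout
    ids: list[str] = []
    gene_of: dict[str, int] = {}
    for g in range(config.n_genes):
        k = _draw_isoform_count(rng, config.isoforms_per_gene)
        for i in range(k):
            tid = f"c{g + 1}_g1_i{i + 1}"
            ids.append(tid)
            gene_of[tid] = g

    labels = _assign_exact(len(ids), config.class_fractions, rng)
    if config.n_planted_orfs is not None:
        # override the number of ORF-carrying (mRNA-class) transcripts
        want = config.n_planted_orfs
        have = labels.count("mRNA")
        if want > len(ids):
            raise ValueError("n_planted_orfs exceeds the transcript count")
        donors = [i for i, l in enumerate(labels) if l != "mRNA"]
        takers = [i for i, l in enumerate(labels) if l == "mRNA"]
        rng.shuffle(donors), rng.shuffle(takers)
        while have < want:
            labels[donors.pop()] = "mRNA"
            have += 1
        while have > want:
            labels[takers.pop()] = "lncRNA"
            have -= 1

    unknown_cycle = 0
    sequences: dict[str, str] = {}
    gene_base: dict[int, str] = {}
    for tid, cls in zip(ids, labels):
        truth.classes[tid] = cls
        needs_orf = cls == "mRNA"
        if cls == "unknown":
            pattern = _UNKNOWN_PATTERNS[unknown_cycle % len(_UNKNOWN_PATTERNS)]
            unknown_cycle += 1
            truth.criterion_patterns[tid] = pattern
            needs_orf = pattern[0]
        elif cls == "mRNA":
            truth.criterion_patterns[tid] = (True, True, True)
        else:
            truth.criterion_patterns[tid] = (False, False, False)

        floor = 350 if needs_orf else 201
        length = max(_draw_length(rng, config.length_dist), floor)
        g = gene_of[tid]
        if g not in gene_base:
            gene_base[g] = _random_seq(rng, max(length, 250), config.gc_target)
        base = gene_base[g]
        if length <= len(base):
            seq = base[:length]
        else:  # isoform longer than the gene base: extend with fresh sequence
            seq = base + _random_seq(rng, length - len(base), config.gc_target)
            gene_base[g] = seq
        if needs_orf:
            max_aa = (length - 6) // 3 - 2
            aa = int(rng.integers(110, min(400, max_aa) + 1))
            seq = _plant_orf(seq, aa, rng)
            truth.orf_lengths[tid] = aa
        else:
            seq = _break_long_orfs(seq)
        sequences[tid] = seq

    _plant_all_hairpins(config, rng, sequences, truth)
    return sequences, truth


def _plant_all_hairpins(
    config: SimConfig,
    rng: np.random.Generator,
    sequences: dict[str, str],
    truth: GroundTruth,
) -> dict[str, str]:
    """Plant the configured hairpins; returns the reference mature set."""
    violations = (
        list(config.planted_violations)
        if config.planted_violations is not None
        else ["none"] * config.n_planted_hairpins
    )
    matures = make_reference_matures(len(violations), seed=int(rng.integers(2**31)))
    hosts = [t for t, s in sequences.items() if len(s) >= 250]
    if violations and not hosts:
        raise ValueError("no transcripts long enough to host hairpins")
    used: dict[str, list[tuple[int, int]]] = {}
    names = sorted(matures)
    for idx, violation in enumerate(violations):
        name = names[idx]
        antisense = bool(rng.random() < config.antisense_fraction)
        for attempt in range(50):
            tid = hosts[int(rng.integers(0, len(hosts)))]
            seq = sequences[tid]
            pos = int(rng.integers(5, len(seq) - 130))
            span = (pos - 130, pos + 260)
            if any(a < span[1] and span[0] < b for a, b in used.get(tid, [])):
                continue
            try:
                newseq, locus = plant_hairpin(
                    seq, matures[name], violation,
                    seed=int(rng.integers(2**31)), mature_name=name,
                    antisense=antisense, insert_at=pos,
                )
            except (RuntimeError, ValueError):
                continue
            # insertion must not flip the host's ORF criterion either way
            wants_orf = truth.criterion_patterns[tid][0]
            host_orf = classify.find_longest_orf(newseq).length_aa
            if wants_orf != (host_orf > classify.ORF_MIN_AA):
                continue
            sequences[tid] = newseq
            locus.transcript_id = tid
            truth.hairpins.append(locus)
            used.setdefault(tid, []).append(span)
            break
        else:
            raise RuntimeError(f"failed to place hairpin {idx} ({violation})")
    return matures


def make_reference_matures(n: int, seed: int = 0, prefix: str = "syn-miR") -> dict[str, str]:
    """n distinct synthetic reference matures, 21-23 nt, miRBase-ish names."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    while len(out) < n:
        length = int(rng.integers(hairpin.MATURE_MIN, hairpin.MATURE_MAX + 1))
        seq = _random_seq(rng, length, 0.5)
        name = f"{prefix}-{len(out) + 1}"
        if seq not in out.values():
            out[name] = seq
    return out


def planted_matures(truth: GroundTruth, sequences: Mapping[str, str]) -> dict[str, str]:
    """Recover the reference mature set from planted loci (for discovery runs)."""
    out: dict[str, str] = {}
    for locus in truth.hairpins:
        seq = sequences[locus.transcript_id][locus.mature_start:locus.mature_end]
        if locus.strand == hairpin.ANTISENSE:
            seq = hairpin.revcomp(seq)
        out[locus.mature_name] = seq
    return out


# ---------------------------------------------------------------------------
# counts and evidence
# ---------------------------------------------------------------------------

def generate_counts(
    config: SimConfig,
    transcripts: Mapping[str, str],
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Negative-binomial counts + FPKM with planted DE and silenced sets.

    DE transcripts differ between the larva group and all adult groups by a
    factor of 2^true_log2fc (direction alternating); a `silenced_fraction`
    of transcripts is all-zero to exercise the active-expression filter.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    truth = truth or GroundTruth()
    ids = list(transcripts)
    samples = [s for ss in config.groups.values() for s in ss]
    larva = set(config.groups.get("larva", ()))
    n_t = len(ids)

    order = list(ids)
    rng.shuffle(order)
    n_silenced = int(round(config.silenced_fraction * n_t))
    silenced = set(order[:n_silenced])
    expressed = order[n_silenced:]
    n_de = int(round(config.de_fraction * n_t))
    de_ids = expressed[:n_de]
    for i, tid in enumerate(de_ids):
        truth.de_direction[tid] = "up_in_larva" if i % 2 == 0 else "up_in_adult"
    truth.silenced |= silenced

    base = rng.lognormal(np.log(config.depth_mean), 1.0, size=n_t)
    fc = 2.0 ** config.true_log2fc
    r = 1.0 / config.dispersion
    counts = np.zeros((n_t, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        in_larva = sample in larva
        mu = base.copy()
        for i, tid in enumerate(ids):
            d = truth.de_direction.get(tid)
            if d == "up_in_larva" and in_larva:
                mu[i] *= fc
            elif d == "up_in_adult" and not in_larva:
                mu[i] *= fc
            if tid in silenced:
                mu[i] = 0.0
        p = r / (r + np.maximum(mu, 1e-12))
        col = rng.negative_binomial(r, p)
        col[mu == 0] = 0
        counts[:, j] = col
    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    lengths = pd.Series({t: len(s) for t, s in transcripts.items()})
    lib = counts_df.sum(axis=0).clip(lower=1)
    fpkm = expression.compute_fpkm(counts_df, lengths, lib)
    return counts_df, fpkm, truth


def generate_evidence(
    transcripts: Mapping[str, str],
    truth: GroundTruth,
    seed: int = 0,
) -> list[classify.EvidenceRecord]:
    """Annotation evidence consistent with the planted classes.

    ORF lengths are computed from the emitted sequences (closure with the
    FASTA); votes and homology hits are synthesized to realize the
    assigned criterion pattern exactly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for tid, seq in transcripts.items():
        cls = truth.classes.get(tid, "lncRNA")
        pattern = truth.criterion_patterns.get(
            tid, (True, True, True) if cls == "mRNA" else (False, False, False)
        )
        _, want_coding, want_homology = pattern
        orf_aa = classify.find_longest_orf(seq).length_aa
        votes = {"CPC": bool(want_coding), "CNCI": bool(want_coding and rng.random() < 0.5)}
        hits: list[classify.HomologyHit] = []
        pfam = False
        if want_homology:
            if rng.random() < 0.85:
                hits.append(
                    classify.HomologyHit(
                        subject_db="swissprot",
                        identity=float(rng.uniform(80, 100)),
                        length=int(rng.integers(90, 400)),
                        evalue=float(10.0 ** rng.uniform(-60, -6)),
                    )
                )
            else:
                pfam = True
        elif rng.random() < 0.3:  # sub-threshold noise hit
            hits.append(
                classify.HomologyHit(
                    subject_db="swissprot",
                    identity=float(rng.uniform(30, 79)),
                    length=int(rng.integers(20, 89)),
                    evalue=float(10.0 ** rng.uniform(-4, 1)),
                )
            )
        records.append(
            classify.EvidenceRecord(
                transcript_id=tid,
                contaminant_hit=(cls == "contaminant"),
                longest_orf_aa=orf_aa,
                coding_votes=votes,
                homology_hits=hits,
                pfam_hit=pfam,
            )
        )
    return records


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    transcripts: dict[str, str]
    truth: GroundTruth
    evidence: list[classify.EvidenceRecord]
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    reference_matures: dict[str, str]


def simulate_study(config: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Full synthetic study: transcriptome, evidence, counts, matures.

    When `outdir` is given, writes transcripts.fasta, counts.tsv, fpkm.tsv,
    evidence.tsv, matures.fasta and ground_truth.json there.
    """
    transcripts, truth = generate_transcriptome(config)
    counts, fpkm, truth = generate_counts(config, transcripts, truth)
    evidence = generate_evidence(transcripts, truth, seed=config.seed + 2)
    matures = planted_matures(truth, transcripts)
    bundle = SimBundle(config, transcripts, truth, evidence, counts, fpkm, matures)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.write_fasta(transcripts, outdir / "transcripts.fasta")
        report.write_matrix_tsv(counts, outdir / "counts.tsv")
        report.write_matrix_tsv(fpkm, outdir / "fpkm.tsv")
        classify.write_evidence_tsv(evidence, outdir / "evidence.tsv")
        if matures:
            report.write_fasta(matures, outdir / "matures.fasta")
        (outdir / "ground_truth.json").write_text(truth.to_json())
    return bundle
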