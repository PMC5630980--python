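"""mRNA / lncRNA / unknown classification of assembled transcripts.

The annotation procedure is a four-step decision tree over per-transcript
evidence:

1. contaminant screen — homology to a small-ncRNA reference eliminates the
   transcript outright;
2. ORF size — the longest six-frame ATG-to-stop ORF must exceed 100 aa
   (strictly);
3. coding potential — OR over external predictor verdicts (any tool calling
   "coding" suffices);
4. homology — any protein/mRNA hit passing e-value <= 1e-5, alignment
   length >= 90 and identity >= 80, or a predicted Pfam domain.

A transcript passing all of 2-4 is an mRNA; failing all three is a lncRNA
(the > 200 bp length floor is upstream, at assembly); anything mixed is
"unknown".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

CONTAMINANT = "contaminant"
MRNA = "mRNA"
LNCRNA = "lncRNA"
UNKNOWN = "unknown"

ORF_MIN_AA = 100  # strict: longest ORF must be > 100 aa
HOMOLOGY_E_MAX = 1e-5
HOMOLOGY_MIN_LEN = 90
HOMOLOGY_MIN_IDENTITY = 80.0

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfResult:
    """Longest ORF over six frames; coordinates are 0-based half-open on
    the forward strand and include the start codon but not the stop."""

    length_aa: int
    strand: str = "+"
    frame: int = 0
    start: int = 0
    end: int = 0


@dataclass
class HomologyHit:
    subject_db: str
    identity: float
    length: int
    evalue: float


@dataclass
class EvidenceRecord:
    transcript_id: str
    contaminant_hit: bool = False
    longest_orf_aa: int = 0
    coding_votes: dict[str, bool] = field(default_factory=dict)
    homology_hits: list[HomologyHit] = field(default_factory=list)
    pfam_hit: bool = False


@dataclass
class TranscriptClass:
    label: str
    orf_pass: bool
    coding_pass: bool
    homology_pass: bool


def find_longest_orf(sequence: str) -> OrfResult:
    """Longest ATG-to-stop ORF across all six reading frames.

    The reported length excludes the stop codon; an ORF must terminate at a
    stop within the sequence. Ties go to the forward strand, then the lower
    frame, then the leftmost start. A sequence without any ORF yields
    length 0.
    """
    seq = sequence.upper().replace("U", "T")
    best = OrfResult(length_aa=0)
    n = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            start = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    if start is not None:
                        aa = (pos - start) // 3
                        if aa > best.length_aa:
                            if strand == "+":
                                fstart, fend = start, pos
                            else:  # map back onto forward coordinates
                                fstart, fend = n - pos, n - start
                            best = OrfResult(aa, strand, frame, fstart, fend)
                        start = None
                elif codon == "ATG" and start is None:
                    start = pos
    return best


def orf_criterion(longest_orf_aa: int) -> bool:
    """True iff the longest ORF is longer than 100 amino acids (strict)."""
    if longest_orf_aa < 0:
        raise ValueError("ORF length cannot be negative")
    return longest_orf_aa > ORF_MIN_AA


def coding_potential_criterion(coding_votes: Mapping[str, bool]) -> bool:
    """OR over predictor verdicts; no votes means no coding evidence."""
    return any(bool(v) for v in coding_votes.values())


def fallback_coding_vote(sequence: str, orf: OrfResult | None = None) -> bool:
    """Internal stand-in coding predictor for runs without external tools.

    Votes "coding" when the longest ORF covers at least half the
    transcript. Never used when real predictor votes are supplied.
    """
    if orf is None:
        orf = find_longest_orf(sequence)
    if not sequence:
        return False
    return (3 * orf.length_aa) / len(sequence) >= 0.5


def homology_criterion(
    homology_hits: Sequence[HomologyHit],
    pfam_hit: bool = False,
    e_max: float = HOMOLOGY_E_MAX,
    min_len: int = HOMOLOGY_MIN_LEN,
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
) -> bool:
    """Any hit with e <= e_max, length >= min_len, identity >= min_identity,
    or a Pfam domain."""
    if e_max <= 0 or min_len <= 0 or min_identity <= 0:
        raise ValueError("homology thresholds must be positive")
    for hit in homology_hits:
        if not (0 <= hit.identity <= 100) or hit.evalue < 0 or hit.length < 0:
            raise ValueError(f"malformed homology hit: {hit}")
        if hit.evalue <= e_max and hit.length >= min_len and hit.identity >= min_identity:
            return True
    return bool(pfam_hit)


def classify(evidence: EvidenceRecord) -> TranscriptClass:
    """Apply the decision tree to one transcript's evidence."""
    orf_pass = orf_criterion(evidence.longest_orf_aa)
    coding_pass = coding_potential_criterion(evidence.coding_votes)
    homology_pass = homology_criterion(evidence.homology_hits, evidence.pfam_hit)
    if evidence.contaminant_hit:
        label = CONTAMINANT
    elif orf_pass and coding_pass and homology_pass:
        label = MRNA
    elif not (orf_pass or coding_pass or homology_pass):
        label = LNCRNA
    else:
        label = UNKNOWN
    return TranscriptClass(label, orf_pass, coding_pass, homology_pass)


def classify_all(records: Sequence[EvidenceRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        cls = classify(rec)
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "class": cls.label,
                "orf_pass": cls.orf_pass,
                "coding_pass": cls.coding_pass,
                "homology_pass": cls.homology_pass,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# evidence IO
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "transcript_id", "contaminant_hit", "longest_orf_aa", "votes", "hits", "pfam_hit",
]


def evidence_to_frame(records: Sequence[EvidenceRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "contaminant_hit": rec.contaminant_hit,
                "longest_orf_aa": rec.longest_orf_aa,
                "votes": json.dumps(rec.coding_votes, sort_keys=True),
                "hits": json.dumps(
                    [
                        [h.subject_db, h.identity, h.length, h.evalue]
                        for h in rec.homology_hits
                    ]
                ),
                "pfam_hit": rec.pfam_hit,
            }
        )
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def write_evidence_tsv(records: Sequence[EvidenceRecord], path) -> None:
    evidence_to_frame(records).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence TSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        hits = [
            HomologyHit(subject_db=h[0], identity=float(h[1]), length=int(h[2]), evalue=float(h[3]))
            for h in json.loads(row.hits)
        ]
        records.append(
            EvidenceRecord(
                transcript_id=str(row.transcript_id),
                contaminant_hit=bool(row.contaminant_hit),
                longest_orf_aa=int(row.longest_orf_aa),
                coding_votes=json.loads(row.votes),
                homology_hits=hits,
                pfam_hit=bool(row.pfam_hit),
            )
        )
    return records


def homology_hits_from_blast6(blast6: pd.DataFrame, subject_db: str = "blast") -> dict[str, list[HomologyHit]]:
    """Group a BLAST outfmt-6 table into per-query homology hit lists."""
    out: dict[str, list[HomologyHit]] = {}
    for row in blast6.itertuples(index=False):
        out.setdefault(str(row.qseqid), []).append(
            HomologyHit(
                subject_db=subject_db,
                identity=float(row.pident),
                length=int(row.length),
                evalue=float(row.evalue),
            )
        )
    return out
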