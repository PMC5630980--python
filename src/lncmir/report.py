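"""Summary statistics, set arithmetic and shared readers/writers.

This module houses the bookkeeping side of the pipeline: assembly summary
statistics (N50, length/GC profiles), Venn-region counts over labeled
transcript sets, top-k expression unions, novel-set subtraction, per-gene
isoform tallies, tRNAscan-SE tallies, and the plain-text formats (FASTA,
TSV, BLAST outfmt 6, dot-bracket TSV) the other modules share.

Percentages are always recomputed from integer counts with half-up
rounding; nothing is cached as a float.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lncmir")

# Trinity-style isoform id, e.g. c49416_g1_i23 -> gene c49416_g1, isoform 23
_TRINITY_ID = re.compile(r"^(?P<gene>.+_g\d+)_i(?P<isoform>\d+)$")


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------

def percent(part: int, whole: int, digits: int = 2) -> float:
    """100*part/whole rounded half-up to `digits` decimal places."""
    if whole == 0:
        raise ValueError("percentage of an empty whole is undefined")
    frac = Decimal(100 * part) / Decimal(whole)
    q = Decimal(1).scaleb(-digits)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def n50(lengths: Iterable[int]) -> int:
    """N50: the largest length L such that contigs >= L hold half the bases.

    Computed by descending cumulative sum; invariant under permutation of
    the input. Raises on empty input.
    """
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def gc_percent(sequence: str) -> float:
    """GC content of a sequence as a percentage (N and gaps excluded)."""
    s = sequence.upper()
    acgt = sum(s.count(b) for b in "ACGTU")
    if acgt == 0:
        return 0.0
    return 100.0 * (s.count("G") + s.count("C")) / acgt


# ---------------------------------------------------------------------------
# set arithmetic
# ---------------------------------------------------------------------------

@dataclass
class VennCounts:
    """Region counts over up to three labeled sets.

    `regions` maps a frozenset of labels (the exact membership pattern) to
    the number of elements showing exactly that pattern. Region counts sum
    to the size of the union and satisfy inclusion-exclusion by
    construction.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, int] = field(default_factory=dict)

    def region(self, *labels: str) -> int:
        return self.regions.get(frozenset(labels), 0)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def set_size(self, label: str) -> int:
        """Cardinality of one input set, reconstructed from the regions."""
        return sum(n for pat, n in self.regions.items() if label in pat)


def venn_counts(sets: Mapping[str, set]) -> VennCounts:
    """Exact membership-pattern counts over up to three labeled sets."""
    if not 1 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 1-3 sets")
    labels = tuple(sets)
    regions: dict[frozenset, int] = {}
    universe = set().union(*sets.values())
    for element in universe:
        pattern = frozenset(lbl for lbl in labels if element in sets[lbl])
        regions[pattern] = regions.get(pattern, 0) + 1
    return VennCounts(labels=labels, regions=regions)


def novel_set(candidates: Iterable, known_hits: Iterable) -> set:
    """Candidates without a known-homology hit (plain set difference)."""
    return set(candidates) - set(known_hits)


def top_k_union(
    group_expression: Mapping[str, Mapping[str, float]],
    k: int = 10,
    low_expression_threshold: float | None = 2.0,
) -> pd.DataFrame:
    """Union of each group's top-k transcripts by group expression.

    `group_expression` maps group -> {transcript_id: expression}. Ties are
    broken lexically on the transcript id so the output is deterministic.
    Returns one row per transcript in the union with boolean membership
    flags per group and, when `low_expression_threshold` is set, a
    `low_in_<group>` flag marking expression strictly below the threshold.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    tops: dict[str, list[str]] = {}
    for group, expr in group_expression.items():
        ranked = sorted(expr.items(), key=lambda kv: (-kv[1], kv[0]))
        tops[group] = [tid for tid, _ in ranked[:k]]
    union = sorted(set(itertools.chain.from_iterable(tops.values())))
    rows = []
    for tid in union:
        row: dict[str, object] = {"transcript_id": tid}
        for group in group_expression:
            row[f"in_{group}"] = tid in tops[group]
            if low_expression_threshold is not None:
                val = group_expression[group].get(tid, 0.0)
                row[f"low_in_{group}"] = val < low_expression_threshold
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-class profiles
# ---------------------------------------------------------------------------

def parse_isoform_id(transcript_id: str) -> tuple[str, int]:
    """Split a Trinity-style id into (gene_id, isoform_number)."""
    m = _TRINITY_ID.match(transcript_id)
    if not m:
        raise ValueError(f"id not parseable as gene/isoform: {transcript_id!r}")
    return m.group("gene"), int(m.group("isoform"))


def isoform_tally(
    transcript_classes: Mapping[str, str],
    min_isoforms: Sequence[int] = (2, 4, 12),
) -> pd.DataFrame:
    """Per-class alternative-splicing tallies from gene/isoform ids.

    For every class, counts transcripts whose gene carries >= N isoforms of
    that class, for each N in `min_isoforms` (N=2 is the conventional
    "spliced" criterion), plus the maximum isoform count observed.
    """
    per_class_gene: dict[str, dict[str, int]] = {}
    for tid, cls in transcript_classes.items():
        gene, _ = parse_isoform_id(tid)
        per_class_gene.setdefault(cls, {}).setdefault(gene, 0)
        per_class_gene[cls][gene] += 1
    rows = []
    for cls, genes in sorted(per_class_gene.items()):
        counts = np.array(list(genes.values()))
        row: dict[str, object] = {
            "class": cls,
            "n_transcripts": int(counts.sum()),
            "n_genes": len(genes),
            "max_isoforms_per_gene": int(counts.max()),
        }
        for n in min_isoforms:
            row[f"transcripts_in_genes_ge{n}"] = int(counts[counts >= n].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def length_gc_profile(
    sequences: Mapping[str, str],
    transcript_classes: Mapping[str, str],
    length_cutoff: int = 1000,
) -> pd.DataFrame:
    """Per-class length and GC summaries.

    Reports min/max/mean/median length, mean GC percent and the fraction of
    transcripts shorter than `length_cutoff` (1 kb by default, the
    conventional short/long split for lncRNA profiles).
    """
    per_class: dict[str, list[tuple[int, float]]] = {}
    for tid, seq in sequences.items():
        cls = transcript_classes.get(tid, "unclassified")
        per_class.setdefault(cls, []).append((len(seq), gc_percent(seq)))
    rows = []
    for cls, vals in sorted(per_class.items()):
        lengths = np.array([v[0] for v in vals], dtype=float)
        gcs = np.array([v[1] for v in vals])
        rows.append(
            {
                "class": cls,
                "n": len(vals),
                "min_length": int(lengths.min()),
                "max_length": int(lengths.max()),
                "mean_length": float(lengths.mean()),
                "median_length": float(np.median(lengths)),
                "mean_gc": float(gcs.mean()),
                f"fraction_under_{length_cutoff}bp": float(
                    (lengths < length_cutoff).mean()
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SummaryReport:
    n_transcripts: int
    n_genes: int
    n50_bp: int
    median_length: float
    mean_length: float
    total_bases: int
    gc: float
    class_counts: dict[str, int] = field(default_factory=dict)
    active_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_transcripts": self.n_transcripts,
            "n_genes": self.n_genes,
            "n50_bp": self.n50_bp,
            "median_length": self.median_length,
            "mean_length": self.mean_length,
            "total_bases": self.total_bases,
            "gc_percent": self.gc,
            "class_counts": dict(self.class_counts),
            "active_counts": dict(self.active_counts),
        }
        if self.n_transcripts:
            out["class_percent"] = {
                cls: percent(n, self.n_transcripts)
                for cls, n in self.class_counts.items()
            }
        return out


def summarize_assembly(
    sequences: Mapping[str, str],
    transcript_classes: Mapping[str, str] | None = None,
    active_ids: set | None = None,
) -> SummaryReport:
    """Assembly-level summary: counts, N50, contig stats, GC, class splits."""
    if not sequences:
        raise ValueError("empty transcript set")
    lengths = [len(s) for s in sequences.values()]
    genes = {parse_isoform_id(t)[0] for t in sequences}
    pooled_gc = percent(
        sum(s.upper().count("G") + s.upper().count("C") for s in sequences.values()),
        sum(lengths),
    )
    class_counts: dict[str, int] = {}
    active_counts: dict[str, int] = {}
    if transcript_classes:
        for tid in sequences:
            cls = transcript_classes.get(tid, "unclassified")
            class_counts[cls] = class_counts.get(cls, 0) + 1
            if active_ids is not None and tid in active_ids:
                active_counts[cls] = active_counts.get(cls, 0) + 1
    return SummaryReport(
        n_transcripts=len(sequences),
        n_genes=len(genes),
        n50_bp=n50(lengths),
        median_length=float(np.median(lengths)),
        mean_length=float(np.mean(lengths)),
        total_bases=int(sum(lengths)),
        gc=pooled_gc,
        class_counts=class_counts,
        active_counts=active_counts,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence} (id = first header token)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Transcript x sample matrix with a header row and id index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast6(path: str | Path) -> pd.DataFrame:
    """BLAST tabular (-outfmt 6) with the default 12 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise ValueError(
            f"expected {len(BLAST6_COLUMNS)} outfmt-6 columns, got {df.shape[1]}"
        )
    df.columns = BLAST6_COLUMNS
    return df


def read_structure_tsv(path: str | Path) -> dict[str, tuple[str, float]]:
    """Precomputed folding results: id, dot-bracket, mfe (tab-separated)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "structure", "mfe"])
    out = {}
    for row in df.itertuples(index=False):
        if len(row.structure) == 0 or row.mfe > 0:
            raise ValueError(f"malformed structure row for {row.id}")
        out[str(row.id)] = (row.structure, float(row.mfe))
    return out


def read_trnascan(path: str | Path) -> pd.DataFrame:
    """tRNAscan-SE tabular output -> DataFrame (malformed rows skipped).

    The format is whitespace-delimited with three header lines; columns of
    interest are the sequence name (1), tRNA isotype (5) and anticodon (6).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            # header block: name line, column line, dashed underline
            if line.startswith(("Sequence", "Name", "--")):
                continue
            parts = line.split()
            if len(parts) < 6:
                logger.warning("skipping malformed tRNAscan row %d: %r", lineno, line)
                continue
            try:
                rows.append(
                    {
                        "transcript_id": parts[0],
                        "isotype": parts[4],
                        "anticodon": parts[5],
                    }
                )
            except (ValueError, IndexError):
                logger.warning("skipping malformed tRNAscan row %d: %r", lineno, line)
    return pd.DataFrame(rows, columns=["transcript_id", "isotype", "anticodon"])


def trna_tally(
    trnascan: pd.DataFrame,
    transcript_classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts per (isotype, anticodon), overall and split by transcript class."""
    if trnascan.empty:
        return pd.DataFrame(columns=["isotype", "anticodon", "class", "count"])
    df = trnascan.copy()
    if transcript_classes is not None:
        df["class"] = df["transcript_id"].map(
            lambda t: transcript_classes.get(t, "other")
        )
    else:
        df["class"] = "all"
    tally = (
        df.groupby(["isotype", "anticodon", "class"])
        .size()
        .reset_index(name="count")
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return tally


def most_abundant_trna(tally: pd.DataFrame) -> tuple[str, str, int] | None:
    """The (isotype, anticodon, total count) with the highest overall count."""
    if tally.empty:
        return None
    total = (
        tally.groupby(["isotype", "anticodon"])["count"].sum().sort_values(
            ascending=False, kind="stable"
        )
    )
    isotype, anticodon = total.index[0]
    return isotype, anticodon, int(total.iloc[0])


def write_json_summary(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
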