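"""FPKM computation, active-expression filtering and DE calling.

Expression is handled on pandas matrices (transcripts x samples). FPKM is
count / ((length/1e3) * (library_size/1e6)). A transcript is "active" when
its FPKM is strictly greater than the threshold (0.5 by default) in at
least one sample.

Differential expression between two sample groups is called with the
package's own count test: a two-sided exact negative-binomial test
conditioned on the pooled count, with a method-of-moments common
dispersion estimated across transcripts (Fisher's exact test on pooled
counts when the data are not overdispersed). A transcript is DE when
p <= 0.001 AND |log2FC| >= 2 (inclusive), with log2FC taken on
library-size-normalized group means with a pseudo-count of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FPKM_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_LFC_THRESHOLD = 2.0

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
NOT_DE = "not_de"


# ---------------------------------------------------------------------------
# FPKM and activity
# ---------------------------------------------------------------------------

def compute_fpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (library_size/1e6)).

    `library_sizes` defaults to the per-sample column sums (total mapped
    fragments). Zero counts map to zero FPKM exactly.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing transcript lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    kb = lengths.to_numpy(dtype=float) / 1e3
    millions = library_sizes.to_numpy(dtype=float) / 1e6
    fpkm = counts.to_numpy(dtype=float) / (kb[:, None] * millions[None, :])
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def active_filter(
    fpkm: pd.DataFrame, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> set[str]:
    """Transcripts with FPKM strictly above `threshold` in >= 1 sample."""
    if fpkm.empty:
        raise ValueError("empty FPKM matrix")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = (fpkm > threshold).any(axis=1)
    return set(fpkm.index[mask])


def sample_specific_sets(
    fpkm: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> tuple[dict[str, set[str]], dict[str, frozenset]]:
    """Per-group active sets and the membership pattern of each transcript.

    `groups` maps group label -> sample columns; the same strict > rule is
    applied within each group's samples. Returns (per-group active set,
    transcript -> frozenset of groups it is active in); transcripts
    inactive everywhere are omitted from the pattern map.
    """
    listed = [s for samples in groups.values() for s in samples]
    if len(listed) != len(set(listed)) or set(listed) != set(fpkm.columns):
        raise ValueError("groups must partition the sample columns")
    active: dict[str, set[str]] = {}
    for group, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {group!r} has no samples")
        active[group] = active_filter(fpkm[list(samples)], threshold)
    patterns: dict[str, frozenset] = {}
    for tid in fpkm.index:
        pat = frozenset(g for g, ids in active.items() if tid in ids)
        if pat:
            patterns[tid] = pat
    return active, patterns


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DECall:
    transcript_id: str
    log2_fold_change: float
    p_value: float
    direction: str


def _common_dispersion(adjusted: np.ndarray, group_slices: list[slice]) -> float:
    """Method-of-moments common NB dispersion across transcripts.

    For every transcript and group, phi = (var - mean) / mean^2; the common
    value is the median over finite, informative entries, floored at 0.
    """
    phis = []
    for sl in group_slices:
        block = adjusted[:, sl]
        if block.shape[1] < 2:
            continue
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        ok = m > 0
        phis.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not phis:
        return 0.0
    allphi = np.concatenate(phis)
    if allphi.size == 0:
        return 0.0
    return float(max(0.0, np.median(allphi)))


def _exact_nb_p(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact NB test of equal means, conditional on sa + sb.

    Group sums are NB with shared per-sample size r = 1/phi, so
    SA ~ NB(na*r, p0), SB ~ NB(nb*r, p0) under the null. The p-value sums
    the conditional probabilities of all splits of the total at most as
    likely as the observed one.
    """
    total = sa + sb
    if total == 0:
        return 1.0
    mu = total / (na + nb)  # per-sample null mean (adjusted scale)
    r = 1.0 / phi
    ra, rb = na * r, nb * r
    p0 = r / (r + mu)  # scipy's p parameter
    k = np.arange(total + 1)
    logp = stats.nbinom.logpmf(k, ra, p0) + stats.nbinom.logpmf(total - k, rb, p0)
    logp -= logp.max()
    prob = np.exp(logp)
    obs = prob[sa]
    # tolerance keeps the observed split in its own tail despite rounding
    pval = prob[prob <= obs * (1 + 1e-12)].sum() / prob.sum()
    return float(min(1.0, pval))


def _fisher_p(sa: int, sb: int, lib_a: int, lib_b: int) -> float:
    table = np.array([[sa, max(lib_a - sa, 0)], [sb, max(lib_b - sb, 0)]])
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def call_de(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    library_sizes_a: pd.Series | None = None,
    library_sizes_b: pd.Series | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-transcript DE calls between two sample groups.

    Returns a DataFrame indexed by transcript with columns log2fc, p and
    direction ('up_in_A' / 'up_in_B' / 'not_de'). log2FC > 0 means higher
    in group A. The fold-change gate is inclusive (|log2FC| >= 2 at the
    default), matching a fold-change-of-four threshold.
    """
    if counts_a.shape[1] == 0 or counts_b.shape[1] == 0:
        raise ValueError("each group needs at least one sample")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("group matrices must share the transcript index")

    lib_a = (counts_a.sum(axis=0) if library_sizes_a is None else pd.Series(library_sizes_a))
    lib_b = (counts_b.sum(axis=0) if library_sizes_b is None else pd.Series(library_sizes_b))
    if (lib_a <= 0).any() or (lib_b <= 0).any():
        raise ValueError("library sizes must be positive")

    # per-million normalization for the fold change
    norm_a = counts_a.to_numpy(float) / lib_a.to_numpy(float)[None, :] * 1e6
    norm_b = counts_b.to_numpy(float) / lib_b.to_numpy(float)[None, :] * 1e6
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    lfc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    # counts rescaled to the mean library size so group sums are comparable
    all_libs = np.concatenate([lib_a.to_numpy(float), lib_b.to_numpy(float)])
    ref = all_libs.mean()
    adj_a = np.rint(counts_a.to_numpy(float) * (ref / lib_a.to_numpy(float))[None, :])
    adj_b = np.rint(counts_b.to_numpy(float) * (ref / lib_b.to_numpy(float))[None, :])
    adjusted = np.concatenate([adj_a, adj_b], axis=1).astype(np.int64)
    na, nb = counts_a.shape[1], counts_b.shape[1]

    if dispersion is None:
        phi = _common_dispersion(
            adjusted.astype(float), [slice(0, na), slice(na, na + nb)]
        )
    else:
        if dispersion <= 0:
            raise ValueError("dispersion must be positive when supplied")
        phi = dispersion

    sums_a = adj_a.sum(axis=1).astype(np.int64)
    sums_b = adj_b.sum(axis=1).astype(np.int64)
    tot_a = int(round(ref)) * na
    tot_b = int(round(ref)) * nb

    pvals = np.empty(len(counts_a), dtype=float)
    for i, (sa, sb) in enumerate(zip(sums_a, sums_b)):
        if phi > 1e-8:
            pvals[i] = _exact_nb_p(int(sa), int(sb), na, nb, phi)
        else:
            pvals[i] = _fisher_p(int(sa), int(sb), tot_a, tot_b)

    direction = np.where(
        (pvals <= p_threshold) & (np.abs(lfc) >= lfc_threshold),
        np.where(lfc > 0, UP_IN_A, UP_IN_B),
        NOT_DE,
    )
    return pd.DataFrame(
        {"log2fc": lfc, "p": pvals, "direction": direction}, index=counts_a.index
    )


def read_groups_yaml(path) -> dict[str, list[str]]:
    """groups.yaml: mapping of group label -> list of sample columns."""
    import yaml

    with open(path) as fh:
        groups = yaml.safe_load(fh)
    if not isinstance(groups, dict):
        raise ValueError("groups file must map group -> [samples]")
    return {str(g): [str(s) for s in samples] for g, samples in groups.items()}
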