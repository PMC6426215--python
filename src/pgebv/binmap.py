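"""GBS quality control and bin-map construction.

Implements the five-step reduction of a noisy biparental SNP matrix to
recombination-bin markers:

1. drop SNPs with minor allele frequency <= ``maf_min`` or missing rate
   >= ``missing_max`` (thresholds strict, "greater than 0.05" / "less than
   20%");
2. drop DH lines with heterozygosity > ``het_max`` or missing rate >
   ``missing_max``;
3. drop SNPs not similar (>= ``threshold``) to any neighbour inside a
   centered window of 8 SNPs on the same chromosome (one pass, removals do
   not cascade);
4. merge consecutive similar SNPs into bins by a greedy left-to-right scan
   against the bin's running consensus;
5. treat bins as genetic markers, re-estimating inter-bin distances from
   recombinant fractions with the Haldane map function.

Similarity between two SNP columns is orientation-free: over lines where
both calls are homozygous, ``max(p_match, 1 - p_match)``.  Pairs with
fewer than ``MIN_COMPARABLE`` informative lines are treated as
non-informative (they never support retention or merging).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, BinMap, PARENT_A, PARENT_B, HET, MISSING

log = logging.getLogger(__name__)

#: minimum number of lines with homozygous calls in both columns for a
#: defined similarity
MIN_COMPARABLE = 10


@dataclass
class SnpQcStats:
    """Per-SNP and per-line quality statistics."""

    maf: np.ndarray  # per SNP; NaN when no called allele
    missing_rate_snp: np.ndarray
    het_rate_line: np.ndarray  # het / called
    missing_rate_line: np.ndarray

    def frame_snp(self, marker_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": marker_ids, "maf": self.maf,
             "missing_rate": self.missing_rate_snp}
        )

    def frame_line(self, line_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"line": line_ids, "het_rate": self.het_rate_line,
             "missing_rate": self.missing_rate_line}
        )


def compute_qc_stats(geno: GenotypeMatrix) -> SnpQcStats:
    """MAF (hets count half for each allele), missing rate per SNP, and
    het / missing rates per line."""
    if geno.n_lines == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    calls = geno.calls
    n_a = (calls == PARENT_A).sum(axis=0).astype(float)
    n_b = (calls == PARENT_B).sum(axis=0).astype(float)
    n_h = (calls == HET).sum(axis=0).astype(float)
    n_m = (calls == MISSING).sum(axis=0).astype(float)
    called = n_a + n_b + n_h
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = (n_b + 0.5 * n_h) / called
    maf = np.minimum(freq_b, 1.0 - freq_b)
    maf[called == 0] = np.nan
    missing_snp = n_m / geno.n_lines

    l_h = (calls == HET).sum(axis=1).astype(float)
    l_m = (calls == MISSING).sum(axis=1).astype(float)
    l_called = geno.n_snps - l_m
    with np.errstate(invalid="ignore", divide="ignore"):
        het_line = np.where(l_called > 0, l_h / l_called, np.nan)
    return SnpQcStats(
        maf=maf,
        missing_rate_snp=missing_snp,
        het_rate_line=het_line,
        missing_rate_line=l_m / geno.n_snps,
    )


def filter_snps(geno: GenotypeMatrix, maf_min: float = 0.05,
                missing_max: float = 0.20) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly greater than ``maf_min`` and missing rate
    strictly less than ``missing_max``; SNPs with undefined MAF are dropped."""
    stats = compute_qc_stats(geno)
    with np.errstate(invalid="ignore"):
        keep = (stats.maf > maf_min) & (stats.missing_rate_snp < missing_max)
    keep &= ~np.isnan(stats.maf)
    if not keep.any():
        raise ValueError("all SNPs removed by MAF/missing filter")
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_snps: removed %d of %d SNPs", dropped, geno.n_snps)
    return geno.subset(snps=np.flatnonzero(keep))


def filter_lines(geno: GenotypeMatrix, het_max: float = 0.05,
                 missing_max: float = 0.20) -> GenotypeMatrix:
    """Remove lines with heterozygosity strictly greater than ``het_max``
    and/or missing rate strictly greater than ``missing_max``."""
    if geno.n_lines < 1:
        raise ValueError("no lines")
    stats = compute_qc_stats(geno)
    with np.errstate(invalid="ignore"):
        drop = (stats.het_rate_line > het_max) | (stats.missing_rate_line
                                                  > missing_max)
    drop |= np.isnan(stats.het_rate_line)
    if drop.all():
        raise ValueError("all lines removed by het/missing filter")
    removed = [geno.line_ids[i] for i in np.flatnonzero(drop)]
    if removed:
        log.info("filter_lines: removed %d lines: %s", len(removed), removed)
    out = geno.subset(lines=np.flatnonzero(~drop))
    out.marker_map.attrs["removed_lines"] = removed
    return out


def pairwise_similarity(calls_i: np.ndarray, calls_j: np.ndarray,
                        min_comparable: int = MIN_COMPARABLE) -> float:
    """Orientation-free similarity of two SNP columns over lines where both
    are homozygous: ``max(p_match, 1 - p_match)``; NaN when fewer than
    ``min_comparable`` comparable lines."""
    a = np.asarray(calls_i)
    b = np.asarray(calls_j)
    if a.shape != b.shape:
        raise ValueError("columns must have the same length")
    hom_a = (a == PARENT_A) | (a == PARENT_B)
    hom_b = (b == PARENT_A) | (b == PARENT_B)
    both = hom_a & hom_b
    n = int(both.sum())
    if n < min_comparable:
        return float("nan")
    p = float((a[both] == b[both]).sum()) / n
    return max(p, 1.0 - p)


def _offset_similarities(calls: np.ndarray, max_offset: int,
                         min_comparable: int) -> np.ndarray:
    """Similarity between column i and column i+d for d = 1..max_offset.

    Returns an array sim[d-1, i] (NaN where undefined or out of range),
    vectorized over the whole chromosome.
    """
    n_lines, m = calls.shape
    hom = (calls == PARENT_A) | (calls == PARENT_B)
    sims = np.full((max_offset, m), np.nan)
    for d in range(1, max_offset + 1):
        if m <= d:
            break
        both = hom[:, :-d] & hom[:, d:]
        comp = both.sum(axis=0)
        match = (both & (calls[:, :-d] == calls[:, d:])).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = match / comp
        s = np.maximum(p, 1.0 - p)
        s[comp < min_comparable] = np.nan
        sims[d - 1, : m - d] = s
    return sims


def remove_unlinked_snps(geno: GenotypeMatrix, window: int = 8,
                         threshold: float = 0.95) -> GenotypeMatrix:
    """Drop SNPs whose maximum similarity to any other SNP within a centered
    window of ``window`` SNPs on the same chromosome is below ``threshold``.

    One pass on the original matrix: removals do not cascade.  A chromosome
    with fewer than 2 SNPs keeps its SNPs (with a warning).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    half = window // 2
    keep = np.ones(geno.n_snps, dtype=bool)
    for chrom, sl in geno.chrom_slices().items():
        m = sl.stop - sl.start
        if m < 2:
            warnings.warn(
                f"chromosome {chrom} has {m} SNP(s); retained without "
                "linkage check"
            )
            continue
        calls = geno.calls[:, sl]
        sims = _offset_similarities(calls, half, MIN_COMPARABLE)
        best = np.full(m, -np.inf)
        for d in range(1, half + 1):
            s = sims[d - 1]
            # i vs i+d supports both endpoints
            valid = ~np.isnan(s[: m - d]) if m > d else np.zeros(0, bool)
            if valid.any():
                idx = np.flatnonzero(valid)
                np.maximum.at(best, idx, s[idx])
                np.maximum.at(best, idx + d, s[idx])
        keep[sl] = best >= threshold
    removed = int((~keep).sum())
    if removed:
        log.info("remove_unlinked_snps: removed %d of %d SNPs", removed,
                 geno.n_snps)
    if not keep.any():
        raise ValueError("all SNPs removed as unlinked")
    return geno.subset(snps=np.flatnonzero(keep))


def _consensus_from_counts(counts: np.ndarray) -> np.ndarray:
    """Majority call per line from per-state counts (A, het, B); ties and
    all-missing lines give MISSING."""
    total = counts.sum(axis=1)
    top = counts.max(axis=1)
    arg = counts.argmax(axis=1)
    n_at_top = (counts == top[:, None]).sum(axis=1)
    state = np.array([PARENT_A, HET, PARENT_B], dtype=np.int8)[arg]
    out = np.where((total == 0) | (n_at_top > 1), MISSING, state)
    return out.astype(np.int8)


_STATE_IDX = {int(PARENT_A): 0, int(HET): 1, int(PARENT_B): 2}


def _add_to_counts(counts: np.ndarray, col: np.ndarray) -> None:
    for state, k in _STATE_IDX.items():
        counts[col == state, k] += 1


def merge_bins(geno: GenotypeMatrix, threshold: float = 0.95) -> BinMap:
    """Greedy left-to-right merge of consecutive similar SNPs into bins.

    A SNP joins the current bin iff its orientation-free similarity to the
    bin's running consensus is >= ``threshold``; otherwise it starts a new
    bin.  A SNP anti-correlated with the consensus is flipped before its
    calls enter the consensus vote.  The bin's consensus call per line is
    the majority non-missing call (ties -> missing); the bin position is
    the midpoint of its first and last member SNP.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    bins_rows = []
    bin_cols = []
    members_all = []
    chrom_arr = geno.marker_map["chrom"].to_numpy()
    pos_arr = geno.marker_map["pos_cM"].to_numpy(float)
    markers = geno.marker_map["marker"].to_numpy()

    for chrom, sl in geno.chrom_slices().items():
        cols = range(sl.start, sl.stop)
        counts = None
        members: list[int] = []

        def close_bin():
            cons = _consensus_from_counts(counts)
            first, last = members[0], members[-1]
            bins_rows.append(
                {
                    "bin": f"{chrom}_bin{sum(1 for r in bins_rows if r['chrom'] == chrom) + 1}",
                    "chrom": chrom,
                    "first_marker": markers[first],
                    "last_marker": markers[last],
                    "n_snps": len(members),
                    "pos_cM": 0.5 * (pos_arr[first] + pos_arr[last]),
                }
            )
            bin_cols.append(cons)
            members_all.append(list(members))

        for j in cols:
            col = geno.calls[:, j]
            if counts is None:
                counts = np.zeros((geno.n_lines, 3), dtype=np.int32)
                _add_to_counts(counts, col)
                members = [j]
                continue
            cons = _consensus_from_counts(counts)
            hom_c = (cons == PARENT_A) | (cons == PARENT_B)
            hom_j = (col == PARENT_A) | (col == PARENT_B)
            both = hom_c & hom_j
            n = int(both.sum())
            if n >= MIN_COMPARABLE:
                p = float((cons[both] == col[both]).sum()) / n
                sim = max(p, 1.0 - p)
            else:
                p, sim = np.nan, np.nan
            if np.isnan(sim) or sim < threshold:
                close_bin()
                counts = np.zeros((geno.n_lines, 3), dtype=np.int32)
                _add_to_counts(counts, col)
                members = [j]
            else:
                add = col if p >= 0.5 else _flip(col)
                _add_to_counts(counts, add)
                members.append(j)
        if counts is not None:
            close_bin()

    bins = pd.DataFrame(bins_rows)
    bin_calls = np.stack(bin_cols, axis=1) if bin_cols else np.zeros(
        (geno.n_lines, 0), dtype=np.int8)
    return BinMap(bins=bins, bin_calls=bin_calls,
                  line_ids=list(geno.line_ids), members=members_all)


def _flip(col: np.ndarray) -> np.ndarray:
    out = col.copy()
    a = col == PARENT_A
    b = col == PARENT_B
    out[a] = PARENT_B
    out[b] = PARENT_A
    return out


def haldane_cM(r: float) -> float:
    """Haldane map function d = -50 ln(1 - 2r); NaN for r >= 0.5."""
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5:
        return float("nan")
    return -50.0 * np.log(1.0 - 2.0 * r)


def estimate_map_distances(binmap: BinMap, min_comparable: int = MIN_COMPARABLE
                           ) -> BinMap:
    """Re-estimate inter-bin distances from adjacent-bin recombinant
    fractions via the Haldane map function.

    Adds columns ``rhat`` and ``d_cM`` (distance to the previous bin on the
    same chromosome; NaN and flagged unresolved when rhat >= 0.5 or too few
    comparable lines) plus cumulative ``pos_est_cM`` per chromosome.
    """
    bins = binmap.bins.copy()
    rhat = np.full(len(bins), np.nan)
    d = np.full(len(bins), np.nan)
    pos = np.full(len(bins), np.nan)
    unresolved = np.zeros(len(bins), dtype=bool)
    for chrom in dict.fromkeys(bins["chrom"]):
        idx = np.flatnonzero(bins["chrom"].to_numpy() == chrom)
        pos[idx[0]] = 0.0
        for prev, cur in zip(idx[:-1], idx[1:]):
            a = binmap.bin_calls[:, prev]
            b = binmap.bin_calls[:, cur]
            hom = ((a == PARENT_A) | (a == PARENT_B)) & \
                  ((b == PARENT_A) | (b == PARENT_B))
            n = int(hom.sum())
            if n < min_comparable:
                unresolved[cur] = True
                continue
            r = float((a[hom] != b[hom]).sum()) / n
            rhat[cur] = r
            if r >= 0.5:
                unresolved[cur] = True
                continue
            d[cur] = haldane_cM(r)
            if not np.isnan(pos[prev]):
                pos[cur] = pos[prev] + d[cur]
    bins["rhat"] = rhat
    bins["d_cM"] = d
    bins["unresolved"] = unresolved
    bins["pos_est_cM"] = pos
    n_unres = int(unresolved.sum())
    if n_unres:
        log.warning("estimate_map_distances: %d unresolved adjacencies", n_unres)
    return BinMap(bins=bins, bin_calls=binmap.bin_calls,
                  line_ids=list(binmap.line_ids), members=list(binmap.members))


def estimated_map_length(binmap: BinMap) -> float:
    """Total estimated map length (cM), summing resolved distances."""
    if "d_cM" not in binmap.bins.columns:
        raise ValueError("run estimate_map_distances first")
    return float(np.nansum(binmap.bins["d_cM"].to_numpy()))


def build_binmap(geno: GenotypeMatrix, maf_min: float = 0.05,
                 missing_max: float = 0.20, het_max: float = 0.05,
                 window: int = 8, threshold: float = 0.95) -> tuple:
    """Run QC steps 1-5 in order; returns (binmap, qc_report dict)."""
    report = {"n_snps_in": geno.n_snps, "n_lines_in": geno.n_lines}
    g1 = filter_snps(geno, maf_min=maf_min, missing_max=missing_max)
    report["n_snps_after_maf_missing"] = g1.n_snps
    g2 = filter_lines(g1, het_max=het_max, missing_max=missing_max)
    report["n_lines_after_filter"] = g2.n_lines
    report["removed_lines"] = g2.marker_map.attrs.get("removed_lines", [])
    g3 = remove_unlinked_snps(g2, window=window, threshold=threshold)
    report["n_snps_after_linkage"] = g3.n_snps
    bm = merge_bins(g3, threshold=threshold)
    bm = estimate_map_distances(bm)
    report["n_bins"] = bm.n_bins
    report["estimated_map_length_cM"] = estimated_map_length(bm)
    return bm, report
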