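"""Trans-eQTL hotspot detection.

The genome is tiled in 50-kb bins; each significant distant eQTL (a
transcript on a different chromosome than its peak) is assigned to the
bin containing its peak-marker coordinate.  Bins with more distant
eQTLs than a genome-wide Poisson null predicts (Bonferroni-adjusted
p < 0.05) are hotspots; adjacent significant bins merge into regions,
and each region gets a confidence interval from the CIs of its most
significant member eQTLs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("onepot")

BIN_SIZE = 50_000


def bin_genome(chrom_lengths: dict[str, int],
               bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Half-open [start, end) tiling of each chromosome; last bin truncated."""
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"{chrom}: non-positive length")
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        for s, e in zip(starts, ends):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(rows)


def count_distant(peaks: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Distant-eQTL count per bin.

    ``peaks`` must carry ``scan_chrom``, ``peak_pos`` and
    ``transcript_chrom`` (pre-filtered to the significant set).  A peak
    lands in the bin containing its peak-marker coordinate and counts
    only when the transcript lies on a different chromosome than the
    bin.  A peak with no containing bin is a coordinate error.
    """
    counts = np.zeros(len(bins), dtype=int)
    member_lists: list[list[int]] = [[] for _ in range(len(bins))]
    for i, pk in peaks.reset_index(drop=True).iterrows():
        on_chrom = bins[bins["chrom"] == pk["scan_chrom"]]
        sub = on_chrom[(on_chrom["start"] <= pk["peak_pos"])
                       & (pk["peak_pos"] < on_chrom["end"])]
        if len(sub) == 1:
            b = sub.index[0]
        elif (len(on_chrom) and pk["peak_pos"] == on_chrom["end"].max()):
            # a marker at the very last base belongs to the final bin
            b = on_chrom.index[-1]
        else:
            raise ValueError(
                f"peak at {pk['scan_chrom']}:{pk['peak_pos']} maps to "
                f"{len(sub)} bins")
        if pk["transcript_chrom"] != pk["scan_chrom"]:
            counts[b] += 1
            member_lists[b].append(i)
    counts_df = bins.copy()
    counts_df["count"] = counts
    counts_df["members"] = member_lists
    return counts_df


def poisson_hotspot_test(counts_df: pd.DataFrame,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Poisson upper-tail test per bin with Bonferroni adjustment.

    The null mean is the average number of distant eQTLs per bin; the
    p-value is P(Poisson(lambda) >= observed).  Adjacent significant
    bins (adjusted p < alpha, same chromosome, touching intervals) merge
    into hotspot regions labelled by ``region``.
    """
    n_bins = len(counts_df)
    total = int(counts_df["count"].sum())
    out = counts_df.copy()
    if total == 0:
        logger.info("no distant eQTLs; no hotspots")
        out["p"] = 1.0
        out["p_adj"] = 1.0
        out["significant"] = False
        out["region"] = -1
        return out
    lam = total / n_bins
    p = stats.poisson.sf(out["count"].to_numpy() - 1, lam)
    p_adj = np.minimum(1.0, p * n_bins)
    sig = p_adj < alpha
    region = np.full(n_bins, -1)
    rid = -1
    prev_sig = False
    prev_chrom = None
    prev_end = None
    for i in range(n_bins):
        if sig[i]:
            adjacent = (prev_sig and out["chrom"].iat[i] == prev_chrom
                        and out["start"].iat[i] == prev_end)
            if not adjacent:
                rid += 1
            region[i] = rid
        prev_sig = bool(sig[i])
        prev_chrom = out["chrom"].iat[i]
        prev_end = out["end"].iat[i]
    out["p"] = p
    out["p_adj"] = p_adj
    out["significant"] = sig
    out["region"] = region
    return out


def hotspot_ci(member_peaks: pd.DataFrame, markers: pd.DataFrame,
               chrom: str, n_top: int = 20,
               extend_markers: int = 2) -> tuple[int, int]:
    """Confidence interval for one hotspot region.

    Takes the up-to-``n_top`` highest-LOD member eQTLs; the left bound
    is the 10th percentile of their CI left ends and the right bound
    the 90th percentile of their CI right ends (linear-interpolation
    percentiles).  The interval is then extended ``extend_markers``
    markers outward on the pruned grid, clipped at the chromosome ends.
    """
    if member_peaks.empty:
        raise ValueError("hotspot has no member peaks")
    top = member_peaks.nlargest(min(n_top, len(member_peaks)), "lod")
    left = float(np.percentile(top["ci_left_pos"], 10))
    right = float(np.percentile(top["ci_right_pos"], 90))
    pos = markers.loc[markers["chrom"] == chrom, "pos"].to_numpy()
    pos = np.sort(pos)
    li = int(np.searchsorted(pos, left, side="left"))
    ri = int(np.searchsorted(pos, right, side="right")) - 1
    li = max(0, li - extend_markers)
    ri = min(len(pos) - 1, ri + extend_markers)
    return int(pos[li]), int(pos[ri])


def find_hotspots(peaks: pd.DataFrame, chrom_lengths: dict[str, int],
                  markers: pd.DataFrame, fdr: float = 0.05,
                  bin_size: int = BIN_SIZE, alpha: float = 0.05
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end hotspot analysis from a peak table.

    Filters peaks to FDR < ``fdr``, bins the genome, counts distant
    eQTLs, runs the Poisson test, merges adjacent significant bins and
    attaches a CI per merged hotspot.  Returns (hotspot table, per-bin
    table).
    """
    sig_peaks = peaks[peaks["p_fdr"] < fdr].reset_index(drop=True)
    bins = bin_genome(chrom_lengths, bin_size)
    counts_df = count_distant(sig_peaks, bins)
    tested = poisson_hotspot_test(counts_df, alpha=alpha)
    hotspots = []
    for rid in sorted(r for r in tested["region"].unique() if r >= 0):
        sub = tested[tested["region"] == rid]
        chrom = sub["chrom"].iat[0]
        members = sorted({m for lst in sub["members"] for m in lst})
        mp = sig_peaks.iloc[members]
        mp_distant = mp[mp["transcript_chrom"] != chrom]
        ci_lo, ci_hi = hotspot_ci(mp_distant, markers, chrom)
        hotspots.append({
            "region": rid, "chrom": chrom,
            "start": int(sub["start"].min()), "end": int(sub["end"].max()),
            "n_distant": int(sub["count"].sum()),
            "ci_left": ci_lo, "ci_right": ci_hi,
            "transcripts": sorted(mp_distant["transcript"].unique().tolist()),
        })
    return pd.DataFrame(hotspots), tested
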