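"""Flat-array interval arithmetic on 0-based half-open intervals.

All helpers operate on (starts, ends) int64 arrays per chromosome;
callers keep the per-chromosome bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals as sorted disjoint arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract_intervals(starts, ends, sub_starts, sub_ends):
    """Set difference A \\ B; A must be disjoint sorted, B arbitrary."""
    sub_starts, sub_ends = merge_intervals(sub_starts, sub_ends)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(starts, ends):
        cur = s
        while j < len(sub_starts) and sub_ends[j] <= cur:
            j += 1
        k = j
        while k < len(sub_starts) and sub_starts[k] < e:
            if sub_starts[k] > cur:
                out_s.append(cur)
                out_e.append(min(e, sub_starts[k]))
            cur = max(cur, sub_ends[k])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return (np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64))


def points_in_intervals(pos, starts, ends) -> np.ndarray:
    """Boolean mask: which positions fall inside the merged intervals."""
    pos = np.asarray(pos, dtype=np.int64)
    starts, ends = merge_intervals(starts, ends)
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < ends[idx[ok]]
    return ok


def mask_sites(df: pd.DataFrame, intervals: pd.DataFrame,
               pos_col: str = "pos") -> np.ndarray:
    """Mask of rows of ``df`` whose position lies in ``intervals``.

    Both frames carry a ``chrom`` column; intervals have start/end.
    """
    mask = np.zeros(len(df), dtype=bool)
    if len(df) == 0 or len(intervals) == 0:
        return mask
    by_chrom = {c: g for c, g in intervals.groupby("chrom")}
    for chrom, grp in df.groupby("chrom"):
        iv = by_chrom.get(chrom)
        if iv is None:
            continue
        mask[grp.index.to_numpy()] = points_in_intervals(
            grp[pos_col].to_numpy(), iv["start"].to_numpy(),
            iv["end"].to_numpy())
    return mask


def overlap_join(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """All pairs (i, j) where left interval i overlaps right interval j >= 1 bp.

    Returns a frame with columns ``left_index``/``right_index`` holding
    positional indices into the (reset) inputs.
    """
    left = left.reset_index(drop=True)
    right = right.reset_index(drop=True)
    pairs_l, pairs_r = [], []
    r_by_chrom = {c: g for c, g in right.groupby("chrom")}
    for chrom, lg in left.groupby("chrom"):
        rg = r_by_chrom.get(chrom)
        if rg is None:
            continue
        ls = lg["start"].to_numpy()[:, None]
        le = lg["end"].to_numpy()[:, None]
        rs = rg["start"].to_numpy()[None, :]
        re_ = rg["end"].to_numpy()[None, :]
        hit = (ls < re_) & (rs < le)
        li, ri = np.nonzero(hit)
        pairs_l.append(lg.index.to_numpy()[li])
        pairs_r.append(rg.index.to_numpy()[ri])
    if not pairs_l:
        return pd.DataFrame({"left_index": [], "right_index": []}, dtype=int)
    return pd.DataFrame({
        "left_index": np.concatenate(pairs_l),
        "right_index": np.concatenate(pairs_r),
    })
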