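"""Interval arithmetic on 0-based half-open genomic intervals.

Intervals are represented as pandas DataFrames with at least the columns
``chrom`` (str), ``start`` (int) and ``end`` (int); extra columns (sample,
haplotype, name, carrier counts) ride along.  All coordinates are 0-based
half-open, matching BED.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def empty_intervals(extra: tuple[str, ...] = ()) -> pd.DataFrame:
    cols = INTERVAL_COLUMNS + list(extra)
    return pd.DataFrame({c: pd.Series(dtype=int if c in ("start", "end") else object) for c in cols})


def _check(df: pd.DataFrame) -> None:
    if len(df) and (df["end"] <= df["start"]).any():
        raise ValueError("intervals must satisfy start < end")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Union of intervals; overlapping or bookended intervals are merged.

    ``by`` adds grouping keys (e.g. sample, haplotype) within which the
    merge happens independently.
    """
    _check(df)
    if df.empty:
        return sort_intervals(df[INTERVAL_COLUMNS + (by or [])].copy())
    keys = ["chrom"] + (by or [])
    out = []
    for key, g in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        g = g.sort_values("start")
        starts, ends = g["start"].to_numpy(), g["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(key + (cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(key + (cur_s, cur_e))
    res = pd.DataFrame(out, columns=keys + ["start", "end"])
    return sort_intervals(res[INTERVAL_COLUMNS + (by or [])])


def total_bp(df: pd.DataFrame) -> int:
    if df.empty:
        return 0
    return int((df["end"] - df["start"]).sum())


def overlap_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total bp of intersection between the unions of ``a`` and ``b``."""
    a, b = merge_intervals(a), merge_intervals(b)
    tot = 0
    for chrom, ga in a.groupby("chrom"):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        # sweep: for each interval in a, clip against all b (fixtures are small)
        for s, e in zip(sa, ea):
            lo = np.maximum(sb, s)
            hi = np.minimum(eb, e)
            tot += int(np.maximum(hi - lo, 0).sum())
    return tot


def precision_recall_bp(called: pd.DataFrame, truth: pd.DataFrame) -> tuple[float, float]:
    """Base-pair precision and recall of ``called`` against ``truth``."""
    inter = overlap_bp(called, truth)
    cbp = total_bp(merge_intervals(called)) if len(called) else 0
    tbp = total_bp(merge_intervals(truth)) if len(truth) else 0
    precision = inter / cbp if cbp else float("nan")
    recall = inter / tbp if tbp else float("nan")
    return precision, recall


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"c{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        cols[3] = "name"
    df.columns = cols[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    out = sort_intervals(df)
    cols = INTERVAL_COLUMNS + ([name_col] if name_col and name_col in out else [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)
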