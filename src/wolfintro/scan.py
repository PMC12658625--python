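"""Windowed introgression statistics: D, f_d, f_dM and Fst scans with
percentile-outlier flags, and the candidate-region validation cascade.

Window statistics are returned as pandas DataFrames with columns
chrom/start/end (0-based half-open), per-statistic values, the number of
informative sites, and a ``masked`` flag for windows below the minimum
informative-site count.  Outlier flags are added as ``<stat>_outlier``
boolean columns by :func:`percentile_outliers`, computed within each
chromosome with ties at the cut included.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .fst import ratio_of_averages, wc_components
from .panel import PopulationRef, VariantPanel


def _window_grid(chrom_sites: np.ndarray, pos: np.ndarray, length: int,
                 window_bp: int, step_bp: int):
    starts = np.arange(0, max(length - window_bp, 0) + step_bp, step_bp, dtype=np.int64)
    if len(starts) == 0:
        starts = np.array([0], dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    return starts, ends


def _chrom_lengths_from(refs_chrom, refs_pos, chrom_lengths: dict | None):
    lens = {}
    for chrom in sorted(set(map(str, refs_chrom))):
        m = refs_chrom == chrom
        lens[chrom] = (chrom_lengths or {}).get(chrom, int(refs_pos[m].max()) + 1)
    return lens


def _dstat_terms(p1, p2, p3, p4):
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num_d = (p1 - p2) * (p3 - p4)
    den_d = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    return abba, baba, num_d, den_d


def window_dstats(
    refs: PopulationRef,
    p1: str = "WEU",
    p2: str = "WIT",
    p3: str = "DOG",
    p4: str = "OUT",
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    min_sites: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window D, f_d and f_dM on derived allele frequencies.

    f_d (dynamic-donor estimator, reported as ``df`` for continuity with
    window-scan vocabulary) uses the ABBA-BABA numerator with denominator
    frequencies p2 and p3 replaced by max(p2, p3); f_dM extends it to
    signed values: when p1 > p2 at a site, the denominator uses
    -S(pD, p2, pD, p4) with pD = max(p1, p3).  Windows with fewer than
    ``min_sites`` informative sites are masked.
    """
    f1, f2, f3, f4 = (refs.freq(g) for g in (p1, p2, p3, p4))
    ok = ~(np.isnan(f1) | np.isnan(f2) | np.isnan(f3) | np.isnan(f4))
    abba, baba, num_d, den_d = _dstat_terms(f1, f2, f3, f4)
    num = abba - baba
    # f_d denominator
    pd23 = np.maximum(f2, f3)
    abba_dd, baba_dd, _, _ = _dstat_terms(f1, pd23, pd23, f4)
    den_fd = abba_dd - baba_dd
    # f_dM denominator (signed)
    pd13 = np.maximum(f1, f3)
    abba_dm, baba_dm, _, _ = _dstat_terms(pd13, f2, pd13, f4)
    den_fdm = np.where(f2 >= f1, den_fd, -(abba_dm - baba_dm))
    informative = ok & ((abba + baba) > 0)

    lens = _chrom_lengths_from(refs.chrom, refs.pos, chrom_lengths)
    rows = []
    for chrom, L in lens.items():
        m = (refs.chrom == chrom) & ok
        pos = refs.pos[m]
        starts, ends = _window_grid(None, pos, L, window_bp, step_bp)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        for s, e, i0, i1 in zip(starts, ends, lo, hi):
            sl = slice(i0, i1)
            inf = informative[m][sl]
            n_inf = int(inf.sum())
            masked = n_inf < min_sites
            if masked:
                rows.append((chrom, int(s), int(e), n_inf, np.nan, np.nan, np.nan, True))
                continue
            sden = den_d[m][sl].sum()
            d = num_d[m][sl].sum() / sden if sden != 0 else np.nan
            snum = num[m][sl].sum()
            sfd = den_fd[m][sl].sum()
            sfdm = den_fdm[m][sl].sum()
            fd = snum / sfd if sfd != 0 else np.nan
            fdm = snum / sfdm if sfdm != 0 else np.nan
            rows.append((chrom, int(s), int(e), n_inf, d, fd, fdm, False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "D", "f_d", "f_dM", "masked"])


def window_fst(
    panel: VariantPanel,
    group_a: str = "WIT",
    group_b: str = "DOG",
    group_c: str | None = None,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Sliding-window Weir-Cockerham Fst(group_a, group_b) as ratio of averages.

    When ``group_c`` is given, also emits Fst(group_c, group_b) and the
    differential ``delta_fst`` = Fst(c,b) - Fst(a,b) per window (e.g. how
    much closer Italian wolves are to dogs than European wolves are).
    """
    a1, b1, c1, v1 = wc_components(panel, group_a, group_b)
    if group_c is not None:
        a2, b2, c2, v2 = wc_components(panel, group_c, group_b)
    lens = _chrom_lengths_from(panel.chrom, panel.pos, panel.chrom_lengths)
    rows = []
    for chrom, L in lens.items():
        m = panel.chrom == chrom
        pos = panel.pos[m]
        starts, ends = _window_grid(None, pos, L, window_bp, step_bp)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        for s, e, i0, i1 in zip(starts, ends, lo, hi):
            idx = np.flatnonzero(m)[i0:i1]
            va = v1[idx]
            n_inf = int(va.sum())
            if n_inf < min_sites:
                rows.append((chrom, int(s), int(e), n_inf, np.nan, np.nan, np.nan, True))
                continue
            fst_ab = ratio_of_averages(a1[idx], b1[idx], c1[idx], va)
            fst_cb = dl = np.nan
            if group_c is not None:
                vb = v2[idx]
                fst_cb = ratio_of_averages(a2[idx], b2[idx], c2[idx], vb)
                dl = fst_cb - fst_ab
            rows.append((chrom, int(s), int(e), n_inf, fst_ab, fst_cb, dl, False))
    cols = ["chrom", "start", "end", "n_sites", "fst", "fst_ref", "delta_fst", "masked"]
    return pd.DataFrame(rows, columns=cols)


def percentile_outliers(
    windows: pd.DataFrame,
    statistic: str,
    pct: float,
    tail: str = "upper",
    scope: str = "chromosome",
) -> pd.DataFrame:
    """Flag windows in the requested percentile tail (ties at the cut included).

    ``tail='upper'`` with pct=1 flags the top 1 percentile; ``tail='lower'``
    flags the bottom.  The baseline excludes masked/NaN windows; the cut is
    computed per chromosome (``scope='chromosome'``) or globally
    (``scope='global'``).  Adds a boolean ``<statistic>_outlier`` column.
    """
    if statistic not in windows.columns:
        raise ValueError(f"unknown statistic {statistic!r}")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    out = windows.copy()
    flag = np.zeros(len(out), dtype=bool)
    groups = out.groupby("chrom").indices if scope == "chromosome" else {"all": np.arange(len(out))}
    for _, idx in groups.items():
        vals = out[statistic].to_numpy()[idx]
        usable = ~np.isnan(vals)
        if "masked" in out.columns:
            usable &= ~out["masked"].to_numpy()[idx]
        if not usable.any():
            continue
        base = vals[usable]
        if tail == "upper":
            cut = np.percentile(base, 100.0 - pct)
            hit = usable & (vals >= cut)
        else:
            cut = np.percentile(base, pct)
            hit = usable & (vals <= cut)
        flag[idx[hit]] = True
    out[f"{statistic}_outlier"] = flag
    return out


def validate_candidates(
    candidates: pd.DataFrame,
    dwindows: pd.DataFrame,
    fstwindows: pd.DataFrame,
    d_pct: float = 0.1,
    fst_pct: float = 1.0,
    require_same_window: bool = True,
) -> pd.DataFrame:
    """Validation cascade for candidate regions.

    A candidate is D-validated when at least one overlapping window is in
    the top ``d_pct`` percentile for BOTH f_d and f_dM (same window by
    default; set ``require_same_window=False`` to accept hits in different
    windows of the same region), and Fst-validated when at least one
    overlapping window is in the lowest ``fst_pct`` percentile of
    Fst(Italian wolves, dogs).
    """
    dw = percentile_outliers(dwindows, "f_d", d_pct, "upper")
    dw = percentile_outliers(dw, "f_dM", d_pct, "upper")
    fw = percentile_outliers(fstwindows, "fst", fst_pct, "lower")
    out = candidates.copy()
    d_ok, fst_ok = [], []
    for _, reg in out.iterrows():
        mw = ((dw["chrom"] == reg["chrom"]) & (dw["start"] < reg["end"])
              & (reg["start"] < dw["end"]))
        sub = dw[mw]
        if require_same_window:
            dv = bool((sub["f_d_outlier"] & sub["f_dM_outlier"]).any())
        else:
            dv = bool(sub["f_d_outlier"].any() and sub["f_dM_outlier"].any())
        mf = ((fw["chrom"] == reg["chrom"]) & (fw["start"] < reg["end"])
              & (reg["start"] < fw["end"]))
        fv = bool(fw[mf]["fst_outlier"].any())
        d_ok.append(dv)
        fst_ok.append(fv)
    out["d_validated"] = d_ok
    out["fst_validated"] = fst_ok
    return out
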