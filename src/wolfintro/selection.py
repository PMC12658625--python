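"""Selection statistics over candidate regions: Tajima's D, NCD2,
extended haplotype homozygosity (EHH) and the integrated haplotype score
(iHS).

Window statistics are emitted per non-overlapping window (default 50 kb)
as DataFrames compatible with :func:`wolfintro.scan.percentile_outliers`.
Undefined statistics are carried as NaN, never coerced to 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genmap import GeneticMap
from .panel import MISSING, VariantPanel
from .scan import percentile_outliers


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima constants for n haplotypes."""
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_value(alt_counts: np.ndarray, n: int) -> float:
    """Tajima's D from per-site alternate-allele counts among n haplotypes.

    Only segregating sites (0 < count < n) contribute; returns NaN when
    there are none.
    """
    k = np.asarray(alt_counts, dtype=float)
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    npairs = n * (n - 1) / 2.0
    pi = float(np.sum(k[seg] * (n - k[seg])) / npairs)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    return float((pi - S / c["a1"]) / np.sqrt(var))


def tajimas_d(panel: VariantPanel, group: str, window_bp: int = 50_000) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows for one group.

    Sites with missing genotypes in the group are dropped so the haplotype
    count n stays constant within the scan.
    """
    m = panel.pop_mask(group)
    if not m.any():
        raise ValueError(f"group {group!r} empty")
    g = panel.genotypes[:, m]
    n = 2 * int(m.sum())
    if n < 4:
        raise ValueError("need >= 4 haplotypes (2 diploids) in group")
    complete = (g != MISSING).all(axis=1)
    counts = g.sum(axis=1).astype(float)
    rows = []
    for chrom in sorted(set(map(str, panel.chrom))):
        cm = (panel.chrom == chrom) & complete
        pos = panel.pos[cm]
        k = counts[cm]
        L = panel.chrom_lengths.get(chrom, int(panel.pos[panel.chrom == chrom].max()) + 1)
        starts = np.arange(0, L, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, L)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        for s, e, i0, i1 in zip(starts, ends, lo, hi):
            kk = k[i0:i1]
            seg = int(((kk > 0) & (kk < n)).sum())
            d = tajimas_d_value(kk, n) if seg > 0 else float("nan")
            rows.append((chrom, int(s), int(e), seg, d, seg == 0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "tajima_d", "masked"])


# ---------------------------------------------------------------------------
# NCD2
# ---------------------------------------------------------------------------

def ncd2(
    panel: VariantPanel,
    group: str,
    outgroup: str = "OUT",
    tf: float = 0.5,
    window_bp: int = 50_000,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Non-central deviation statistic NCD2(tf) in non-overlapping windows.

    Informative sites are SNPs segregating in the group (folded minor
    allele frequency) plus fixed differences against the outgroup, which
    enter with MAF = 0.  NCD2 = sqrt(mean (MAF_i - tf)^2); LOW values
    indicate allele frequencies pinned near tf, the balancing-selection
    signal, so outliers are flagged from the lower tail.
    """
    if not 0.0 < tf <= 0.5:
        raise ValueError("tf must be in (0, 0.5]")
    gm = panel.pop_mask(group)
    om = panel.pop_mask(outgroup)
    if not gm.any() or not om.any():
        raise ValueError("empty group or outgroup")
    g = panel.genotypes[:, gm]
    o = panel.genotypes[:, om]
    gc = g != MISSING
    oc = o != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(gc, g, 0).sum(axis=1) / (2.0 * gc.sum(axis=1))
        po = np.where(oc, o, 0).sum(axis=1) / (2.0 * oc.sum(axis=1))
    is_snp = (p > 0) & (p < 1)
    fixed_diff = ((p == 0) | (p == 1)) & ((po == 0) | (po == 1)) & (p != po)
    informative = (is_snp | fixed_diff) & ~np.isnan(p) & ~np.isnan(po)
    maf = np.where(is_snp, np.minimum(p, 1 - p), 0.0)

    rows = []
    for chrom in sorted(set(map(str, panel.chrom))):
        cm = (panel.chrom == chrom) & informative
        pos = panel.pos[cm]
        mafs = maf[cm]
        L = panel.chrom_lengths.get(chrom, int(panel.pos[panel.chrom == chrom].max()) + 1)
        starts = np.arange(0, L, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, L)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        for s, e, i0, i1 in zip(starts, ends, lo, hi):
            mm = mafs[i0:i1]
            n_is = len(mm)
            if n_is < min_sites:
                rows.append((chrom, int(s), int(e), n_is, float("nan"), True))
                continue
            val = float(np.sqrt(np.mean((mm - tf) ** 2)))
            rows.append((chrom, int(s), int(e), n_is, val, False))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "ncd2", "masked"])
    out.attrs["tf"] = tf
    return out


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------

def ehh_decay(haps: np.ndarray, core_index: int, core_allele: int) -> np.ndarray:
    """EHH at every marker for carriers of ``core_allele`` at the core SNP.

    ``haps`` is (n_snps, n_haps) with 0/1 alleles.  EHH(x) is the
    probability that two randomly drawn carrier haplotypes are identical
    at every marker between the core and x (inclusive); EHH(core) = 1 by
    construction for >= 2 carriers.  Returned as an array over all SNP
    indices (monotone non-increasing away from the core).
    """
    carriers = np.flatnonzero(haps[core_index] == core_allele)
    nc = len(carriers)
    if nc < 2:
        raise ValueError("core allele carried by fewer than 2 haplotypes")
    n_snps = haps.shape[0]
    denom = nc * (nc - 1) / 2.0
    out = np.zeros(n_snps)
    out[core_index] = 1.0
    for direction in (1, -1):
        groups = [carriers]
        j = core_index
        while True:
            j += direction
            if j < 0 or j >= n_snps:
                break
            new_groups = []
            for grp in groups:
                al = haps[j, grp]
                for val in (0, 1):
                    sub = grp[al == val]
                    if len(sub) > 1:
                        new_groups.append(sub)
            groups = new_groups
            out[j] = sum(len(g) * (len(g) - 1) / 2.0 for g in groups) / denom
            if not groups:
                break
    return out


@dataclass
class IhsOptions:
    maf_range: tuple[float, float] = (0.05, 0.95)
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    n_freq_bins: int = 50
    min_bin_snps: int = 10
    alpha: float = 0.01
    log_p_pct: float = 1.0


def _ihh_one_side(ehh: np.ndarray, pos_m: np.ndarray, core: int, direction: int,
                  pos_bp: np.ndarray, cutoff: float, max_gap_bp: int) -> float:
    """Trapezoid integral of the EHH curve away from the core (Morgans)."""
    total = 0.0
    j = core
    while True:
        k = j + direction
        if k < 0 or k >= len(ehh):
            break
        if abs(int(pos_bp[k]) - int(pos_bp[j])) > max_gap_bp:
            break
        total += 0.5 * (ehh[j] + ehh[k]) * abs(pos_m[k] - pos_m[j])
        if ehh[k] < cutoff:
            break
        j = k
    return total


def ihs(
    panel: VariantPanel,
    gmap: GeneticMap,
    group: str,
    options: IhsOptions | None = None,
) -> pd.DataFrame:
    """Integrated haplotype score per SNP with within-frequency-bin
    standardization and normal two-sided p-values.

    Requires a phased, polarized panel.  SNPs monomorphic in the group or
    with derived frequency outside ``maf_range`` are skipped.  Outliers are
    flagged when |z| exceeds the alpha = 0.01 two-sided normal quantile AND
    -log10 p falls in the chromosome's top 1 percentile.
    """
    opt = options or IhsOptions()
    if panel.haplotypes is None:
        raise ValueError("iHS requires a phased panel")
    if panel.ancestral is None:
        raise ValueError("iHS requires a polarized panel")
    m = panel.pop_mask(group)
    hap_idx = np.flatnonzero(np.repeat(m, 2))
    haps = panel.haplotypes[:, hap_idx].astype(np.int8).copy()
    # derived coding
    flip = panel.ancestral == 1
    haps[flip] = 1 - haps[flip]
    n_hap = haps.shape[1]

    rows = []
    for chrom in sorted(set(map(str, panel.chrom))):
        cm = panel.chrom == chrom
        h = haps[cm]
        pos_bp = panel.pos[cm]
        pos_m = gmap.morgans_at(chrom, pos_bp)
        dfreq = h.mean(axis=1)
        for i in range(h.shape[0]):
            f = dfreq[i]
            if not (opt.maf_range[0] <= f <= opt.maf_range[1]):
                continue
            ihh = {}
            skip = False
            for allele in (1, 0):
                if (h[i] == allele).sum() < 2:
                    skip = True
                    break
                e = ehh_decay(h, i, allele)
                val = (_ihh_one_side(e, pos_m, i, +1, pos_bp, opt.ehh_cutoff, opt.max_gap_bp)
                       + _ihh_one_side(e, pos_m, i, -1, pos_bp, opt.ehh_cutoff, opt.max_gap_bp))
                ihh[allele] = val
            if skip or ihh[0] <= 0 or ihh[1] <= 0:
                continue
            raw = float(np.log(ihh[0] / ihh[1]))   # ln(iHH_A / iHH_D)
            rows.append((chrom, int(pos_bp[i]), float(f), ihh[0], ihh[1], raw))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "derived_freq", "ihh_a", "ihh_d", "raw"])
    if df.empty:
        for col in ("ihs", "p_value", "outlier"):
            df[col] = []
        return df

    # bin standardization on derived frequency
    edges = np.linspace(0.0, 1.0, opt.n_freq_bins + 1)
    bin_id = np.clip(np.digitize(df["derived_freq"], edges) - 1, 0, opt.n_freq_bins - 1)
    # merge sparse bins with neighbors (forward sweep)
    merged = bin_id.copy()
    uniq = np.unique(merged)
    for b in uniq:
        if (merged == b).sum() < opt.min_bin_snps:
            larger = uniq[uniq > b]
            merged[merged == b] = larger.min() if len(larger) else merged[merged != b].max()
    z = np.full(len(df), np.nan)
    for b in np.unique(merged):
        sel = merged == b
        vals = df["raw"].to_numpy()[sel]
        sd = vals.std(ddof=0)
        z[sel] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    df["ihs"] = z
    df["p_value"] = 2.0 * norm.sf(np.abs(z))
    df["neg_log_p"] = -np.log10(np.clip(df["p_value"], 1e-300, None))
    zcrit = norm.ppf(1.0 - opt.alpha / 2.0)
    flags = np.zeros(len(df), dtype=bool)
    for chrom, idx in df.groupby("chrom").indices.items():
        nl = df["neg_log_p"].to_numpy()[idx]
        cut = np.percentile(nl, 100.0 - opt.log_p_pct)
        flags[idx] = (np.abs(z[idx]) > zcrit) & (nl >= cut)
    df["outlier"] = flags
    return df


def haplotype_matrix(panel: VariantPanel, groups: list[str], chrom: str,
                     start: int, end: int) -> pd.DataFrame:
    """R/A-coded haplotype painting matrix (haplotypes x SNPs) for a region."""
    if panel.haplotypes is None:
        raise ValueError("painting requires a phased panel")
    sm = (panel.chrom == str(chrom)) & (panel.pos >= start) & (panel.pos < end)
    cols = [f"{chrom}:{p + 1}" for p in panel.pos[sm]]
    rows, names = [], []
    for grp in groups:
        for sid in panel.samples_in(grp):
            hp = panel.sample_haplotypes(sid)[sm]
            for h in (0, 1):
                names.append(f"{grp}|{sid}|{h}")
                rows.append(["A" if a else "R" for a in hp[:, h]])
    return pd.DataFrame(rows, index=names, columns=cols)


def flag_selection_outliers(tajima: pd.DataFrame, ncd: pd.DataFrame, pct: float = 1.0):
    """Percentile flags used by the historical pipeline: both Tajima tails,
    lowest NCD2 tail."""
    t = percentile_outliers(tajima, "tajima_d", pct, "upper")
    t = percentile_outliers(t.rename(columns={"tajima_d_outlier": "tajima_pos_outlier"}),
                            "tajima_d", pct, "lower")
    t = t.rename(columns={"tajima_d_outlier": "tajima_neg_outlier"})
    n = percentile_outliers(ncd, "ncd2", pct, "lower").rename(columns={"ncd2_outlier": "ncd2_low_outlier"})
    return t, n
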